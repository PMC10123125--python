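import numpy as np
import pytest

from dnabow.constants import DS_PERSISTENCE, DS_RISE, SS_CONTOUR_PER_NT, SS_PERSISTENCE
from dnabow.kinetics import RateLawParams, SEQUENCE_AVERAGED_PARAMS
from dnabow.polymer import WLCModel


@pytest.fixture(scope="session")
def arc_74() -> WLCModel:
    """The smallest dsDNA arc of the assay (74 bp)."""
    return WLCModel(74 * DS_RISE, DS_PERSISTENCE)


@pytest.fixture(scope="session")
def averaged_law() -> RateLawParams:
    """Sequence-averaged per-nucleotide rate law (9-nt probe)."""
    return RateLawParams(kon0=1.0e7, koff0=0.2, n=9, **SEQUENCE_AVERAGED_PARAMS)


@pytest.fixture(scope="session")
def ss_15nt() -> WLCModel:
    return WLCModel(15 * SS_CONTOUR_PER_NT, SS_PERSISTENCE)


@pytest.fixture(scope="session")
def ds_15bp() -> WLCModel:
    return WLCModel(15 * DS_RISE, DS_PERSISTENCE)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
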