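"""Two-state smFRET trajectory analysis.

Donor/acceptor intensity traces are converted to FRET efficiency
E = I_A/(I_A + I_D), smoothed with a centered moving average, segmented
into bound (high-FRET) and unbound (low-FRET) states by hysteresis
thresholding, and reduced to dwell times and rate constants:

    k_off = 1 / <tau_on>,      k_on = 1 / ([c] <tau_off>),

with [c] the probe concentration.  Censored first/last dwells are dropped
by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FretTrace",
    "DwellSet",
    "RateMeasurement",
    "fret_efficiency",
    "call_states",
    "dwell_times",
    "rates_from_dwells",
    "pool_dwells",
    "analyze_traces",
]


@dataclass
class FretTrace:
    """A donor/acceptor intensity time series with frame time dt (s)."""

    dt: float
    donor: np.ndarray
    acceptor: np.ndarray
    background_subtracted: bool = True

    def __post_init__(self) -> None:
        self.donor = np.asarray(self.donor, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if self.donor.shape != self.acceptor.shape or self.donor.ndim != 1:
            raise ValueError("donor and acceptor must be matching 1-D arrays")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return self.donor.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt


@dataclass
class DwellSet:
    """On/off dwell times (s) pooled from one or more trajectories.

    Under the ``kaplan_meier`` edge policy the censored boundary runs are
    carried separately in ``censored_on``/``censored_off`` so that rates
    can be estimated with the censoring-corrected (exponential MLE)
    estimator, complete-dwell count over total state time.
    """

    on: np.ndarray
    off: np.ndarray
    edge_policy: str = "drop_partial"
    dt: float | None = None
    censored_on: np.ndarray | None = None
    censored_off: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.on = np.asarray(self.on, dtype=float)
        self.off = np.asarray(self.off, dtype=float)
        if np.any(self.on <= 0) or np.any(self.off <= 0):
            raise ValueError("dwells must be positive")
        self.censored_on = np.asarray(
            [] if self.censored_on is None else self.censored_on, dtype=float
        )
        self.censored_off = np.asarray(
            [] if self.censored_off is None else self.censored_off, dtype=float
        )


@dataclass
class RateMeasurement:
    """A (k_on, k_off) measurement at one force for one sequence."""

    kon: float
    kon_sem: float
    koff: float
    koff_sem: float
    concentration: float
    sequence: str = ""
    force: float = np.nan
    force_err: float = 0.0
    n_molecules: int = 0
    n_on: int = 0
    n_off: int = 0


def fret_efficiency(trace: FretTrace) -> np.ndarray:
    """Framewise FRET efficiency E = I_A/(I_A + I_D).

    Frames with non-positive total intensity are invalid and returned as
    NaN; downstream state calling carries the previous state across them.
    """
    total = trace.donor + trace.acceptor
    E = np.full(trace.n_frames, np.nan)
    valid = total > 0
    E[valid] = trace.acceptor[valid] / total[valid]
    return E


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average, NaN-aware, shrinking at the edges."""
    if window % 2 != 1:
        raise ValueError("window must be odd")
    if window == 1:
        return x.copy()
    half = window // 2
    vals = np.nan_to_num(x, nan=0.0)
    good = (~np.isnan(x)).astype(float)
    kernel = np.ones(window)
    num = np.convolve(vals, kernel, mode="same")
    den = np.convolve(good, kernel, mode="same")
    out = np.full_like(vals, np.nan)
    nz = den > 0
    out[nz] = num[nz] / den[nz]
    return out


def call_states(
    efficiency: np.ndarray,
    window: int = 5,
    low_thr: float = 0.4,
    high_thr: float = 0.6,
) -> np.ndarray:
    """Two-state calling via moving-average smoothing + hysteresis.

    The smoothed trace enters the high (bound) state when it exceeds
    ``high_thr`` and leaves it when it drops below ``low_thr``; values in
    between keep the previous state.  Invalid (NaN) frames carry the
    previous state.  Returns an int8 array (1 = bound).
    """
    E = np.asarray(efficiency, dtype=float)
    if not (0 <= low_thr <= high_thr <= 1):
        raise ValueError("need 0 <= low_thr <= high_thr <= 1")
    if window >= E.size:
        raise ValueError("window must be shorter than the trace")
    sm = moving_average(E, window)
    # hysteresis as a forward fill of decisive frames: above high -> 1,
    # below low -> 0, in between (or invalid) -> carry the previous state
    marks = np.full(E.size, -1, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        marks[sm > high_thr] = 1
        marks[sm < low_thr] = 0
    decisive = marks >= 0
    idx = np.where(decisive, np.arange(E.size), -1)
    idx = np.maximum.accumulate(idx)
    # initial state (before any decisive frame) from the first valid frame
    first = np.flatnonzero(~np.isnan(sm))
    init = int(sm[first[0]] > 0.5 * (low_thr + high_thr)) if first.size else 0
    states = np.where(idx >= 0, marks[np.maximum(idx, 0)], init)
    return states.astype(np.int8)


def auto_thresholds(efficiency: np.ndarray, margin: float = 0.1) -> tuple[float, float]:
    """Hysteresis thresholds at the two efficiency-histogram modes' midpoint +/- margin."""
    E = np.asarray(efficiency, dtype=float)
    E = E[~np.isnan(E)]
    hist, edges = np.histogram(np.clip(E, 0, 1), bins=50, range=(0, 1))
    centers = 0.5 * (edges[:-1] + edges[1:])
    lo_mode = centers[: 25][np.argmax(hist[:25])]
    hi_mode = centers[25:][np.argmax(hist[25:])]
    mid = 0.5 * (lo_mode + hi_mode)
    return max(mid - margin, 0.0), min(mid + margin, 1.0)


def dwell_times(
    states: np.ndarray, dt: float, edge_policy: str = "drop_partial"
) -> DwellSet:
    """Run lengths of a binary state series, converted to seconds.

    Under ``drop_partial`` (default) the first and last runs are censored
    and excluded; ``keep`` retains them as ordinary dwells;
    ``kaplan_meier`` records them separately as right-censored
    observations for the censoring-corrected rate estimator.
    """
    s = np.asarray(states).astype(np.int8)
    if s.size == 0:
        return DwellSet(on=np.array([]), off=np.array([]), edge_policy=edge_policy, dt=dt)
    change = np.flatnonzero(np.diff(s)) + 1
    bounds = np.concatenate([[0], change, [s.size]])
    lengths = np.diff(bounds)
    values = s[bounds[:-1]]
    cens_on = cens_off = None
    if edge_policy == "drop_partial":
        lengths, values = lengths[1:-1], values[1:-1]
    elif edge_policy == "kaplan_meier":
        # the first run ends in an observed transition and is exponential
        # by memorylessness; only the final run is right-censored
        ev, el = values[-1:], lengths[-1:]
        cens_on = el[ev == 1] * dt
        cens_off = el[ev == 0] * dt
        lengths, values = lengths[:-1], values[:-1]
    elif edge_policy != "keep":
        raise ValueError(f"unknown edge policy {edge_policy!r}")
    on = lengths[values == 1] * dt
    off = lengths[values == 0] * dt
    return DwellSet(
        on=on, off=off, edge_policy=edge_policy, dt=dt,
        censored_on=cens_on, censored_off=cens_off,
    )


def pool_dwells(dwell_sets: list[DwellSet]) -> DwellSet:
    """Pool dwells across trajectories of one condition."""
    if not dwell_sets:
        raise ValueError("nothing to pool")
    policy = dwell_sets[0].edge_policy
    return DwellSet(
        on=np.concatenate([d.on for d in dwell_sets]),
        off=np.concatenate([d.off for d in dwell_sets]),
        edge_policy=policy,
        dt=dwell_sets[0].dt,
        censored_on=np.concatenate([d.censored_on for d in dwell_sets]),
        censored_off=np.concatenate([d.censored_off for d in dwell_sets]),
    )


def rates_from_dwells(
    dwells: DwellSet,
    concentration: float,
    min_dwells: int = 5,
    n_bootstrap: int = 1000,
    seed: int = 0,
    sem: str = "bootstrap",
) -> RateMeasurement:
    """Rate constants from mean dwell times.

    k_off = 1/<tau_on> (1/s) and k_on = 1/([c]<tau_off>) (1/M/s).  The
    analytic SEM rate/sqrt(N) follows from exponential dwells; a seeded
    bootstrap SEM over dwell resamples is reported by default.
    """
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    n_on, n_off = dwells.on.size, dwells.off.size
    if n_on < min_dwells or n_off < min_dwells:
        raise ValueError(
            f"insufficient dwells (on={n_on}, off={n_off}, need {min_dwells})"
        )
    km = dwells.edge_policy == "kaplan_meier"
    if km:
        # censoring-corrected (exponential MLE): complete-dwell count over
        # total state time including the right-censored boundary runs
        t_on = dwells.on.sum() + dwells.censored_on.sum()
        t_off = dwells.off.sum() + dwells.censored_off.sum()
        koff = n_on / t_on
        kon = n_off / (concentration * t_off)
    else:
        koff = 1.0 / dwells.on.mean()
        kon = 1.0 / (concentration * dwells.off.mean())
    if sem == "analytic" or n_bootstrap <= 0:
        koff_sem = koff / np.sqrt(n_on)
        kon_sem = kon / np.sqrt(n_off)
    else:
        rng = np.random.default_rng(seed)

        def boot(complete, censored, nb):
            idx = rng.integers(0, complete.size, (nb, complete.size))
            tot = complete[idx].sum(axis=1)
            if km and censored.size:
                jdx = rng.integers(0, censored.size, (nb, censored.size))
                tot = tot + censored[jdx].sum(axis=1)
            return complete.size / tot

        koff_sem = float(np.std(boot(dwells.on, dwells.censored_on, n_bootstrap), ddof=1))
        kon_sem = float(
            np.std(boot(dwells.off, dwells.censored_off, n_bootstrap), ddof=1)
            / concentration
        )
    return RateMeasurement(
        kon=float(kon),
        kon_sem=float(kon_sem),
        koff=float(koff),
        koff_sem=float(koff_sem),
        concentration=concentration,
        n_on=n_on,
        n_off=n_off,
    )


def analyze_traces(
    traces: list[FretTrace],
    concentration: float,
    window: int = 5,
    thresholds: tuple[float, float] | None = None,
    edge_policy: str = "drop_partial",
    **rate_kwargs,
) -> RateMeasurement:
    """Full condition analysis: efficiency -> states -> dwells -> rates.

    If thresholds are not given they are placed at the midpoint of the
    pooled efficiency histogram modes +/- 0.1.
    """
    effs = [fret_efficiency(t) for t in traces]
    if thresholds is None:
        thresholds = auto_thresholds(np.concatenate(effs))
    low, high = thresholds
    sets = [
        dwell_times(call_states(E, window, low, high), t.dt, edge_policy)
        for E, t in zip(effs, traces)
    ]
    pooled = pool_dwells(sets)
    meas = rates_from_dwells(pooled, concentration, **rate_kwargs)
    meas.n_molecules = len(traces)
    return meas
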