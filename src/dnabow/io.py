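"""Readers and writers for the pipeline's delimited-text interfaces.

Traces are one CSV per molecule (``time_s, donor, acceptor``) with a TOML
sidecar describing the condition (force, sequence, concentration, frame
time).  Rates, force-extension samples, landscape samples and fitted
parameters travel as CSV/JSON; bias tables as TOML.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .fret import FretTrace
from .landscape import LandscapeSampleSet
from .polymer import LinearFER

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_condition_toml",
    "read_trace_dir",
    "write_rates_csv",
    "read_rates_csv",
    "read_force_extension_csv",
    "read_extension_samples",
    "fer_to_json",
    "fer_from_json",
    "read_bias_toml",
    "read_landscape_samples_csv",
    "write_surface_csv",
]


def read_trace_csv(path) -> FretTrace:
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    t = df[cols["time_s"]].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError(f"{path}: trace too short")
    dt = float(np.median(np.diff(t)))
    return FretTrace(
        dt=dt,
        donor=df[cols["donor"]].to_numpy(dtype=float),
        acceptor=df[cols["acceptor"]].to_numpy(dtype=float),
    )


def write_trace_csv(path, trace: FretTrace) -> None:
    pd.DataFrame(
        {"time_s": trace.time, "donor": trace.donor, "acceptor": trace.acceptor}
    ).to_csv(path, index=False)


def read_condition_toml(path) -> dict:
    with open(path, "rb") as fh:
        cond = tomllib.load(fh)
    required = {"concentration_M"}
    missing = required - cond.keys()
    if missing:
        raise ValueError(f"{path}: missing condition keys {sorted(missing)}")
    return cond


def read_trace_dir(directory) -> tuple[list[FretTrace], dict]:
    """All trace CSVs in a condition directory plus its TOML sidecar."""
    directory = Path(directory)
    tomls = sorted(directory.glob("*.toml"))
    if not tomls:
        raise FileNotFoundError(f"no condition TOML in {directory}")
    cond = read_condition_toml(tomls[0])
    traces = [read_trace_csv(p) for p in sorted(directory.glob("*.csv"))]
    if not traces:
        raise FileNotFoundError(f"no trace CSVs in {directory}")
    return traces, cond


RATES_COLUMNS = [
    "sequence", "force_pN", "force_err",
    "kon", "kon_sem", "koff", "koff_sem", "n_molecules",
]


def write_rates_csv(path, rows) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)


def read_rates_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"force_pN", "kon", "koff"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_force_extension_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"force_pN", "extension_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_extension_samples(path) -> np.ndarray:
    """One-column extension samples (CSV with header or bare series)."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
        if "extension_nm" in df.columns:
            return df["extension_nm"].to_numpy(dtype=float)
        return df.iloc[:, 0].to_numpy(dtype=float)
    except (ValueError, pd.errors.ParserError):
        return np.loadtxt(path, dtype=float).ravel()


def fer_to_json(path, fers: dict[str, LinearFER]) -> None:
    payload = {
        state: dict(
            state=state, a_pN_per_nm=f.a, b_nm=f.b,
            kappa=f.kappa, x0=f.x0, n=f.n,
        )
        for state, f in fers.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def fer_from_json(path) -> dict[str, LinearFER]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for state, rec in payload.items():
        out[state] = LinearFER(
            a=rec["a_pN_per_nm"], b=rec["b_nm"],
            kappa=rec.get("kappa"), x0=rec.get("x0"), n=rec.get("n"),
        )
    return out


def read_bias_toml(path) -> dict[int, float]:
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    table = data.get("W", data)
    return {int(k): float(v) for k, v in table.items()}


def read_landscape_samples_csv(
    path, weights: dict[int, float], force: float, **kwargs
) -> LandscapeSampleSet:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"x_nm", "n_bp"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return LandscapeSampleSet(
        x=df["x_nm"].to_numpy(dtype=float),
        n_bp=df["n_bp"].to_numpy(dtype=int),
        force=force,
        weights=weights,
        **kwargs,
    )


def write_surface_csv(path, surface) -> None:
    """Long-form CSV x_bin, n_bp, G_kBT (finite bins only)."""
    rows = []
    for j, nb in enumerate(surface.n_bp_values):
        for i, xc in enumerate(surface.x_centers):
            g = surface.G[i, j]
            if np.isfinite(g):
                rows.append((xc, int(nb), g))
    pd.DataFrame(rows, columns=["x_bin", "n_bp", "G_kBT"]).to_csv(path, index=False)
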