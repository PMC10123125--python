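"""Force-dependent rate laws and their fits.

The central model: a two-state hybridization reaction whose rates depend
on tension through the extension of the transition state relative to the
initial state,

    k_a(f) = k_a(0) exp( int_0^f dx_ts(f') df' / kBT ),

with dx_ts(f) = x_ts(f) - x_u(f) for binding and x_ts(f) - x_b(f) for
unbinding.  With linear force-extension relations per nucleotide,
x = n (f/kappa + x0), the integral closes to quadratic-in-f expressions
for k_on(f) and k_off(f); those closed forms, the quadrature route, the
six-parameter simultaneous fit, the Marko-Siggia variant fit, duplex
thermodynamics, and the nearest-neighbor comparison all live here.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import quad
from scipy.optimize import least_squares

from .constants import DEFAULT_TEMPERATURE, KBT, R_KCAL, kbt
from .polymer import LinearFER, MarkoSiggiaFER, WLCModel

__all__ = [
    "RateLawParams",
    "KineticRateLaw",
    "RateFitResult",
    "ThermoResult",
    "rate_vs_force",
    "kon_closed_form",
    "koff_closed_form",
    "delta_g",
    "delta_g_vs_force",
    "fit_rate_model",
    "sequence_average_fer",
    "dynamic_range",
    "nn_duplex_dg",
    "SEQUENCE_AVERAGED_PARAMS",
]


@dataclass(frozen=True)
class RateLawParams:
    """Per-nucleotide linear-FER rate-law parameters.

    kappa in pN/nm per nucleotide, x0 in nm per nucleotide; ``n`` is the
    number of nucleotides in the probe-binding region.  The bound state
    is inextensible with extension n*x0_b.
    """

    kon0: float
    koff0: float
    kappa_ts: float
    x0_ts: float
    kappa_u: float
    x0_u: float
    x0_b: float = 0.34
    n: int = 9
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kon0 <= 0 or self.koff0 <= 0:
            raise ValueError("zero-force rates must be positive")
        if self.kappa_ts <= 0 or self.kappa_u <= 0:
            raise ValueError("kappa values must be positive")

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)

    def fer(self, state: str) -> LinearFER:
        if state == "u":
            return LinearFER.from_per_nt(self.kappa_u, self.x0_u, self.n)
        if state == "ts":
            return LinearFER.from_per_nt(self.kappa_ts, self.x0_ts, self.n)
        if state == "b":
            return LinearFER.from_per_nt(1e12, self.x0_b, self.n)
        raise ValueError(f"unknown state {state!r}")


#: Sequence-averaged per-nucleotide parameters of the assay
#: (kappa in pN/nm, x0 in nm): transition state, unbound ssDNA, bound duplex.
SEQUENCE_AVERAGED_PARAMS = dict(
    kappa_ts=355.3, x0_ts=0.39, kappa_u=30.7, x0_u=0.21, x0_b=0.34
)


@dataclass
class KineticRateLaw:
    """General force-dependent rate law built on arbitrary state FERs.

    ``fer_u``, ``fer_b``, ``fer_ts`` must expose ``extension(f)``.
    """

    kon0: float
    koff0: float
    fer_u: object
    fer_b: object
    fer_ts: object
    temperature: float = DEFAULT_TEMPERATURE

    @property
    def kbt(self) -> float:
        return kbt(self.temperature)


def rate_vs_force(
    law: KineticRateLaw, direction: str, f: float
) -> tuple[float, float]:
    """Rate at force f by adaptive quadrature of the extension gap.

    Returns (rate, slope) where slope = d log k/df = dx_ts(f)/kBT is the
    local force sensitivity.
    """
    if f < 0:
        raise ValueError("force must be non-negative")
    if direction == "on":
        ref = law.fer_u
        k0 = law.kon0
    elif direction == "off":
        ref = law.fer_b
        k0 = law.koff0
    else:
        raise ValueError("direction must be 'on' or 'off'")
    gap = lambda fp: float(law.fer_ts.extension(fp)) - float(ref.extension(fp))
    integral, _ = quad(gap, 0.0, f, epsabs=1e-12, epsrel=1e-12, limit=200)
    rate = k0 * np.exp(integral / law.kbt)
    return float(rate), gap(f) / law.kbt


def kon_closed_form(params: RateLawParams, f) -> np.ndarray | float:
    """Closed-form k_on(f) for linear per-nucleotide FERs."""
    f = np.asarray(f, dtype=float)
    expo = (params.n / params.kbt) * (
        (1.0 / params.kappa_ts - 1.0 / params.kappa_u) * f**2 / 2.0
        + (params.x0_ts - params.x0_u) * f
    )
    out = params.kon0 * np.exp(expo)
    return out if out.ndim else float(out)


def koff_closed_form(params: RateLawParams, f) -> np.ndarray | float:
    """Closed-form k_off(f) for linear per-nucleotide FERs."""
    f = np.asarray(f, dtype=float)
    expo = (params.n / params.kbt) * (
        (1.0 / params.kappa_ts) * f**2 / 2.0 + (params.x0_ts - params.x0_b) * f
    )
    out = params.koff0 * np.exp(expo)
    return out if out.ndim else float(out)


def kon_plateau_force(params: RateLawParams) -> float:
    """Force at which d log k_on/df = 0 (onset of the binding plateau)."""
    inv = 1.0 / params.kappa_ts - 1.0 / params.kappa_u
    if inv >= 0:
        raise ValueError("k_on has no stationary point: slope never vanishes")
    return float(-(params.x0_ts - params.x0_u) / inv)


def rate_law_from_params(params: RateLawParams) -> KineticRateLaw:
    """Wrap per-nucleotide parameters as a general rate law (oracle route)."""
    return KineticRateLaw(
        kon0=params.kon0,
        koff0=params.koff0,
        fer_u=params.fer("u"),
        fer_b=params.fer("b"),
        fer_ts=params.fer("ts"),
        temperature=params.temperature,
    )


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------


@dataclass
class ThermoResult:
    """Standard duplex free energy in kBT (positive = more stable)."""

    dg0: float
    dg0_err: float = 0.0
    c0: float = 1.0
    force_grid: np.ndarray | None = None
    dg_of_force: np.ndarray | None = None


def delta_g(
    kon: float,
    koff: float,
    c0: float = 1.0,
    kon_sem: float = 0.0,
    koff_sem: float = 0.0,
) -> ThermoResult:
    """Duplex stability dG0 = kBT ln(k_on c0 / k_off), in units of kBT.

    The error is propagated from the relative SEMs of the two rates:
    sigma_dG = sqrt((s_on/k_on)^2 + (s_off/k_off)^2).
    """
    if kon <= 0 or koff <= 0 or c0 <= 0:
        raise ValueError("rates and c0 must be positive")
    dg = float(np.log(kon * c0 / koff))
    err = float(np.hypot(kon_sem / kon, koff_sem / koff))
    return ThermoResult(dg0=dg, dg0_err=err, c0=c0)


def delta_g_vs_force(
    dg0: float,
    fer_u,
    fer_b,
    f_grid,
    temperature: float = DEFAULT_TEMPERATURE,
) -> ThermoResult:
    """dG0(f) = dG0(0) - int_0^f (x_u - x_b) df' / kBT (dG in kBT).

    With Marko-Siggia FERs the curve is concave with its maximum at the
    ss/ds extension crossover.
    """
    f_grid = np.asarray(f_grid, dtype=float)
    kt = kbt(temperature)
    vals = np.empty_like(f_grid)
    gap = lambda fp: float(fer_u.extension(fp)) - float(fer_b.extension(fp))
    for i, f in enumerate(f_grid):
        integral, _ = quad(gap, 0.0, f, epsabs=1e-11, epsrel=1e-11, limit=200)
        vals[i] = dg0 - integral / kt
    return ThermoResult(dg0=dg0, force_grid=f_grid, dg_of_force=vals)


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------


@dataclass
class RateFitResult:
    """Joint k_on/k_off fit result."""

    model: str
    params: dict
    cov: np.ndarray
    param_names: list[str]
    residuals: np.ndarray
    n_obs: int

    @property
    def param_se(self) -> dict:
        se = np.sqrt(np.diag(self.cov))
        return dict(zip(self.param_names, se))

    def fer(self, state: str, n: int | None = None) -> LinearFER:
        p = self.params
        if self.model != "linear":
            raise ValueError("state FERs as LinearFER only for the linear model")
        if state == "u":
            return LinearFER(a=p["a_u"], b=p["b_u"])
        if state == "ts":
            return LinearFER(a=p["a_ts"], b=p["b_ts"])
        if state == "b":
            return LinearFER(a=1e12, b=p["x_b"])
        raise ValueError(f"unknown state {state!r}")


def _measurement_arrays(measurements) -> pd.DataFrame:
    if isinstance(measurements, pd.DataFrame):
        return measurements
    rows = [
        dict(
            force_pN=m.force,
            kon=m.kon,
            kon_sem=m.kon_sem,
            koff=m.koff,
            koff_sem=m.koff_sem,
        )
        for m in measurements
    ]
    return pd.DataFrame(rows)


def fit_rate_model(
    measurements,
    model: str = "linear",
    n: int = 9,
    x_b: float | None = None,
    fixed: dict | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    n_starts: int = 10,
    seed: int = 0,
) -> RateFitResult:
    """Simultaneous weighted fit of k_on(f) and k_off(f).

    ``model='linear'``: six parameters (a_u, b_u, a_ts, b_ts, k_on(0),
    k_off(0)), with the bound-state extension fixed at 0.34*n nm.  The
    model is linear in (log k(0), 1/a, b), so the weighted least-squares
    problem in log-rate space is solved exactly; weights are the inverse
    variances of the log-rates.

    ``model='marko_siggia'``: all three states follow Marko-Siggia FERs;
    the unbound and bound (P, L) are fixed (defaults from the package
    constants) while (P_ts, L_ts, k_on(0), k_off(0)) vary; solved by
    multi-start trust-region least squares.
    """
    df = _measurement_arrays(measurements)
    forces = df["force_pN"].to_numpy(dtype=float)
    if np.unique(np.round(forces, 9)).size < 4:
        raise ValueError("need at least 4 distinct forces for identifiability")
    kt = kbt(temperature)
    if x_b is None:
        x_b = 0.34 * n

    y = np.concatenate(
        [np.log(df["kon"].to_numpy(float)), np.log(df["koff"].to_numpy(float))]
    )
    s_log = np.concatenate(
        [
            (df["kon_sem"] / df["kon"]).to_numpy(float),
            (df["koff_sem"] / df["koff"]).to_numpy(float),
        ]
    )
    fallback = max(s_log[s_log > 0].max(initial=0.0), 1e-6)
    s_log = np.where(s_log > 0, s_log, fallback)
    w = 1.0 / s_log**2
    m = forces.size

    if model == "linear":
        f2 = forces**2 / (2 * kt)
        f1 = forces / kt
        X = np.zeros((2 * m, 6))
        # columns: ln kon0, ln koff0, c_ts = 1/a_ts, c_u = 1/a_u, b_ts, b_u
        X[:m, 0] = 1.0
        X[m:, 1] = 1.0
        X[:, 2] = np.concatenate([f2, f2])
        X[:m, 3] = -f2
        X[:, 4] = np.concatenate([f1, f1])
        X[:m, 5] = -f1
        y_adj = y.copy()
        y_adj[m:] += x_b * f1  # move the fixed bound-state term to the lhs
        sw = np.sqrt(w)
        theta, *_ = np.linalg.lstsq(X * sw[:, None], y_adj * sw, rcond=None)
        xtwx = X.T @ (w[:, None] * X)
        cov_theta = np.linalg.inv(xtwx)
        resid = y_adj - X @ theta
        ln_kon0, ln_koff0, c_ts, c_u, b_ts, b_u = theta
        if c_ts <= 0 or c_u <= 0:
            # compliances must be positive; refit with bounds
            res = least_squares(
                lambda th: (X @ th - y_adj) * sw,
                x0=np.where(np.arange(6) >= 2, np.maximum(theta, 1e-6), theta),
                bounds=(
                    [-np.inf, -np.inf, 1e-8, 1e-8, 0.0, 0.0],
                    [np.inf, np.inf, 1.0, 1.0, 10.0, 10.0],
                ),
            )
            theta = res.x
            ln_kon0, ln_koff0, c_ts, c_u, b_ts, b_u = theta
            resid = y_adj - X @ theta
        # delta method onto the reported parameterization
        names = ["kon0", "koff0", "a_ts", "b_ts", "a_u", "b_u"]
        J = np.zeros((6, 6))
        J[0, 0] = np.exp(ln_kon0)
        J[1, 1] = np.exp(ln_koff0)
        J[2, 2] = -1.0 / c_ts**2
        J[3, 4] = 1.0
        J[4, 3] = -1.0 / c_u**2
        J[5, 5] = 1.0
        cov = J @ cov_theta @ J.T
        params = dict(
            kon0=float(np.exp(ln_kon0)),
            koff0=float(np.exp(ln_koff0)),
            a_ts=float(1.0 / c_ts),
            b_ts=float(b_ts),
            a_u=float(1.0 / c_u),
            b_u=float(b_u),
            x_b=float(x_b),
            n=n,
        )
        return RateFitResult(
            model="linear",
            params=params,
            cov=cov,
            param_names=names,
            residuals=resid,
            n_obs=2 * m,
        )

    if model == "marko_siggia":
        fixed = dict(fixed or {})
        from .constants import (
            DS_PERSISTENCE,
            DS_RISE,
            SS_CONTOUR_PER_NT,
            SS_PERSISTENCE,
        )

        P_u = fixed.get("P_u", SS_PERSISTENCE)
        L_u = fixed.get("L_u", n * SS_CONTOUR_PER_NT)
        P_b = fixed.get("P_b", DS_PERSISTENCE)
        L_b = fixed.get("L_b", n * DS_RISE)

        fmax = forces.max()
        grid = np.linspace(0.0, fmax * 1.01, 401)
        z_grid = 1.0 - np.geomspace(1e-6, 1.0, 2001)[::-1]  # dense near z = 1

        def ms_ext_grid(L: float, P: float) -> np.ndarray:
            # invert Marko-Siggia by interpolating the monotone f(z) table
            f_of_z = (kt / P) * (0.25 / (1 - z_grid) ** 2 - 0.25 + z_grid)
            return np.interp(grid, f_of_z, z_grid * L)

        xu = ms_ext_grid(L_u, P_u)
        xb = ms_ext_grid(L_b, P_b)

        def cumint(xts_grid, x_ref_grid):
            gap = xts_grid - x_ref_grid
            c = np.concatenate(
                [[0.0], np.cumsum(0.5 * (gap[1:] + gap[:-1]) * np.diff(grid))]
            )
            return np.interp(forces, grid, c)

        def model_logs(p):
            ln_kon0, ln_koff0, log_P, log_L = p
            xts = ms_ext_grid(np.exp(log_L), np.exp(log_P))
            lk_on = ln_kon0 + cumint(xts, xu) / kt
            lk_off = ln_koff0 + cumint(xts, xb) / kt
            return np.concatenate([lk_on, lk_off])

        sw = np.sqrt(w)
        rng = np.random.default_rng(seed)
        best = None
        for _ in range(n_starts):
            p0 = np.array(
                [
                    np.log(df["kon"].iloc[0]),
                    np.log(df["koff"].iloc[0]),
                    np.log(rng.uniform(0.5, 30.0)),
                    np.log(n * rng.uniform(0.3, 0.6)),
                ]
            )
            try:
                res = least_squares(
                    lambda p: (model_logs(p) - y) * sw, p0, method="trf"
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all fit starts failed")
        Jm = best.jac
        dof = max(y.size - 4, 1)
        s2 = 2 * best.cost / dof
        cov_p = np.linalg.pinv(Jm.T @ Jm) * s2
        ln_kon0, ln_koff0, log_P, log_L = best.x
        params = dict(
            kon0=float(np.exp(ln_kon0)),
            koff0=float(np.exp(ln_koff0)),
            P_ts=float(np.exp(log_P)),
            L_ts=float(np.exp(log_L)),
            P_u=P_u,
            L_u=L_u,
            P_b=P_b,
            L_b=L_b,
        )
        return RateFitResult(
            model="marko_siggia",
            params=params,
            cov=cov_p,
            param_names=["ln_kon0", "ln_koff0", "log_P_ts", "log_L_ts"],
            residuals=best.fun,
            n_obs=y.size,
        )

    raise ValueError(f"unknown model {model!r}")


def sequence_average_fer(fers: list[LinearFER]) -> tuple[float, float]:
    """Sequence-averaged per-nucleotide (kappa, x0) from per-sequence FERs.

    Each input must carry its nucleotide count ``n``; the per-nucleotide
    parameters kappa = a*n and x0 = b/n are averaged across sequences.
    """
    if not fers:
        raise ValueError("no FERs to average")
    kappas, x0s = [], []
    for fer in fers:
        if fer.n is None:
            raise ValueError("every FER needs its nucleotide count n")
        kappas.append(fer.a * fer.n)
        x0s.append(fer.b / fer.n)
    return float(np.mean(kappas)), float(np.mean(x0s))


def dynamic_range(
    measurements, which: str = "kon"
) -> tuple[float, float]:
    """Rate at the highest force divided by the rate at the lowest force.

    The error propagates the relative SEMs of the two underlying rates.
    """
    df = _measurement_arrays(measurements).sort_values("force_pN")
    lo, hi = df.iloc[0], df.iloc[-1]
    sem = f"{which}_sem"
    ratio = hi[which] / lo[which]
    err = ratio * float(
        np.hypot(hi[sem] / hi[which], lo[sem] / lo[which])
    )
    return float(ratio), err


# ---------------------------------------------------------------------------
# nearest-neighbor duplex stability
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _load_nn_table(path=None) -> pd.DataFrame:
    if path is not None:
        return pd.read_csv(path, comment="#")
    ref = importlib.resources.files("dnabow.data").joinpath("nn_unified_dna.csv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, comment="#")


def nn_duplex_dg(
    sequence: str,
    table=None,
    dangling_end: bool = False,
    dye: bool = False,
    temperature: float = DEFAULT_TEMPERATURE,
) -> float:
    """Nearest-neighbor duplex stability in kBT (positive = more stable).

    Sums dinucleotide step free energies dG(T) = dH - T dS from the
    shipped unified DNA table plus initiation terms per terminal base.
    Optional corrections: +1 kBT per dangling-end stacking interaction
    (two ends) and +2 kBT for a 5' cyanine dye; the corrections are
    additive.
    """
    seq = sequence.upper().replace("U", "T")
    if len(seq) < 2:
        raise ValueError("sequence must have at least 2 bases")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"invalid bases in {sequence!r}")
    df = _load_nn_table(table)
    lut = {row["step"]: (row["dH_kcal"], row["dS_cal"]) for _, row in df.iterrows()}
    dH = 0.0
    dS = 0.0
    for i in range(len(seq) - 1):
        step = seq[i : i + 2]
        if step not in lut:
            # NN steps are equivalent to their reverse complement
            step_rc = step.translate(_COMPLEMENT)[::-1]
            if step_rc not in lut:
                raise KeyError(f"no parameters for dinucleotide {step!r}")
            step = step_rc
        h, s = lut[step]
        dH += h
        dS += s
    for term in (seq[0], seq[-1]):
        key = "init_GC" if term in "GC" else "init_AT"
        h, s = lut[key]
        dH += h
        dS += s
    dG_kcal = dH - temperature * dS * 1e-3
    rt = R_KCAL * temperature
    dg_kbt = -dG_kcal / rt  # positive-stable convention
    if dangling_end:
        dg_kbt += 2.0  # ~1 kBT per end interaction
    if dye:
        dg_kbt += 2.0
    return float(dg_kbt)
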