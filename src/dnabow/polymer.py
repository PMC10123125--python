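"""Force-extension relations and end-to-end distance distributions.

The mechanical heart of the bow assay: a bent dsDNA arc is modelled as a
worm-like chain (WLC), and the tension it exerts on the ssDNA bowstring is
the logarithmic derivative of its end-to-end distance distribution p(x),

    f(x0) = -kBT * d log p(x) / dx |_{x0}.

p(x) is evaluated with the Becker–Rosa–Everaers interpolation for the
radial distribution of a WLC, which is accurate from the flexible to the
stiff regime.  States of the hybridization reaction (unbound ssDNA, bound
duplex, nucleated transition state) are described either by linear
force-extension relations x(f) = f/a + b or by Marko–Siggia WLCs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.interpolate import InterpolatedUnivariateSpline
from scipy.optimize import brentq
from scipy.special import i0e

from .constants import KBT

__all__ = [
    "WLCModel",
    "LinearFER",
    "RadialDistribution",
    "HarmonicTrap",
    "MarkoSiggiaFER",
    "ShortChainFER",
    "wlc_radial_pdf",
    "entropic_force",
    "ms_force",
    "ms_extension",
    "short_chain_extension",
    "linear_fer_extension",
    "crossover_force",
    "fit_linear_fer",
    "trap_force",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WLCModel:
    """A worm-like chain with contour length and persistence length in nm."""

    contour_length: float
    persistence_length: float

    def __post_init__(self) -> None:
        if self.contour_length <= 0:
            raise ValueError("contour_length must be positive")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be positive")

    @property
    def stiffness(self) -> float:
        """Dimensionless stiffness kappa = P/L."""
        return self.persistence_length / self.contour_length

    def mean_square_extension(self) -> float:
        """Exact WLC <R^2> = 2PL - 2P^2 (1 - exp(-L/P))."""
        L, P = self.contour_length, self.persistence_length
        return 2 * P * L - 2 * P**2 * (1.0 - np.exp(-L / P))


@dataclass(frozen=True)
class LinearFER:
    """Linear force-extension relation x(f) = f/a + b.

    ``a`` is the spring stiffness in pN/nm and ``b`` the relaxed extension
    in nm.  The equivalent per-nucleotide parameterization x = n f/kappa +
    n x0 may be carried alongside; consistency (a = kappa/n, b = n x0) is a
    testable identity.
    """

    a: float
    b: float
    kappa: float | None = None
    x0: float | None = None
    n: int | None = None
    a_se: float | None = None
    b_se: float | None = None

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("stiffness a must be positive")
        if self.kappa is not None:
            if self.n is None or self.x0 is None:
                raise ValueError("per-nt form requires kappa, x0 and n")

    @classmethod
    def from_per_nt(cls, kappa: float, x0: float, n: int) -> "LinearFER":
        return cls(a=kappa / n, b=n * x0, kappa=kappa, x0=x0, n=n)

    def extension(self, f) -> np.ndarray | float:
        return linear_fer_extension(self, f)

    def tension(self, x) -> np.ndarray | float:
        """Force required to hold the state at extension x (>= 0)."""
        return self.a * (np.asarray(x, dtype=float) - self.b)


@dataclass(frozen=True)
class HarmonicTrap:
    """Harmonic restraint with stiffness k (pN/nm) and rest extension x0 (nm)."""

    k: float
    x0: float

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("trap stiffness must be positive")


@dataclass
class RadialDistribution:
    """Tabulated scalar end-to-end distance density of a chain.

    ``p`` is the density of the scalar distance x (the 4*pi*x^2 Jacobian is
    included), normalized so the trapezoid integral over the grid is 1.
    A cubic spline of log p over the region of support backs the force
    operator, avoiding noise amplification from direct differencing.
    """

    x: np.ndarray
    p: np.ndarray
    model: WLCModel | None = None
    log_p: np.ndarray | None = None
    _logspline: InterpolatedUnivariateSpline | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.x.shape != self.p.shape or self.x.ndim != 1:
            raise ValueError("x and p must be matching 1-D arrays")
        if np.any(self.p < 0):
            raise ValueError("density must be non-negative")
        area = np.trapezoid(self.p, self.x)
        if area <= 0:
            raise ValueError("density integrates to zero")
        self.p = self.p / area
        if self.log_p is not None:
            # analytic log-density supplied (avoids float underflow in the
            # tails); shift it to match the normalized p
            self.log_p = np.asarray(self.log_p, dtype=float)
            finite = np.isfinite(self.log_p) & (self.p > 0)
            if finite.any():
                shift = np.median(np.log(self.p[finite]) - self.log_p[finite])
                self.log_p = self.log_p + shift

    @property
    def support(self) -> tuple[float, float]:
        if self.log_p is not None:
            ok = self.x[np.isfinite(self.log_p)]
        else:
            ok = self.x[self.p > 0]
        return float(ok[0]), float(ok[-1])

    def log_spline(self) -> InterpolatedUnivariateSpline:
        if self._logspline is None:
            if self.log_p is not None:
                mask = np.isfinite(self.log_p)
                vals = self.log_p[mask]
            else:
                mask = self.p > 0
                vals = np.log(self.p[mask])
            self._logspline = InterpolatedUnivariateSpline(
                self.x[mask], vals, k=3, ext="raise"
            )
        return self._logspline

    @property
    def mode(self) -> float:
        """Most probable end-to-end distance (spline-refined)."""
        i = int(np.argmax(self.p))
        lo = self.x[max(i - 2, 0)]
        hi = self.x[min(i + 2, len(self.x) - 1)]
        d1 = self.log_spline().derivative()
        if d1(lo) > 0 > d1(hi):
            return float(brentq(d1, lo, hi, xtol=1e-12))
        return float(self.x[i])


# ---------------------------------------------------------------------------
# end-to-end distance distribution (Becker-type interpolation)
# ---------------------------------------------------------------------------

_BRE_A = 14.054
_BRE_B = 0.473
# coefficients c_{ij} of the flexible-regime exponent, rows i = -1, 0
_BRE_C = np.array(
    [
        [-3.0 / 4.0, 23.0 / 64.0, -7.0 / 64.0],
        [-1.0 / 2.0, 17.0 / 16.0, -9.0 / 16.0],
    ]
)


def _bre_log_shape(r: np.ndarray, kappa: float) -> np.ndarray:
    """Unnormalized log of the vector end-to-end density Q(r), r = x/L."""
    r = np.asarray(r, dtype=float)
    c = 1.0 - (1.0 + (0.38 * kappa**-0.95) ** -5.0) ** (-1.0 / 5.0)
    if kappa < 0.125:
        d = 0.0
    else:
        d = 1.0 - 1.0 / (
            0.177 / (kappa - 0.111) + 6.40 * (kappa - 0.111) ** 0.783
        )
    r2 = r * r
    one_m_r2 = 1.0 - r2
    log_pref = 2.5 * (np.log1p(-c * r2) - np.log(one_m_r2))
    powers = np.array([kappa**-1.0, 1.0])
    poly = sum(
        _BRE_C[i, j - 1] * powers[i] * r2**j
        for i in range(2)
        for j in (1, 2, 3)
    )
    out = log_pref + poly / one_m_r2
    if d > 0:
        denom = 1.0 - _BRE_B**2 * r2
        z = d * kappa * _BRE_A * (1.0 + _BRE_B) * r / denom
        out = out - d * kappa * _BRE_A * _BRE_B * (1.0 + _BRE_B) * r2 / denom
        out = out + z + np.log(i0e(z))
    return out


def wlc_radial_pdf(
    model: WLCModel, x_grid: Sequence[float] | np.ndarray | None = None
) -> RadialDistribution:
    """Normalized density of the scalar end-to-end distance of a free WLC.

    Uses the Becker-type interpolation of the WLC radial distribution,
    valid over the full flexible-to-stiff range of kappa = P/L.  The
    returned density includes the 4*pi*x^2 radial Jacobian and integrates
    to 1 over [0, L] by the trapezoid rule.
    """
    L = model.contour_length
    if x_grid is None:
        x_grid = np.linspace(0.0, L, 4001)
    x = np.asarray(x_grid, dtype=float)
    if np.any(x < 0) or np.any(x > L):
        raise ValueError("x grid must lie within [0, L]")
    r = x / L
    p = np.zeros_like(r)
    log_p = np.full_like(r, -np.inf)
    interior = (r > 0) & (r < 1)
    logq = _bre_log_shape(r[interior], model.stiffness)
    log_p[interior] = logq + 2.0 * np.log(r[interior])
    shifted = log_p[interior] - np.max(log_p[interior])
    p[interior] = np.exp(shifted)
    return RadialDistribution(x=x, p=p, model=model, log_p=log_p)


def entropic_force(dist: RadialDistribution, x0: float) -> float:
    """Signed entropic force -kBT d log p/dx at x0 (pN).

    Positive values mean the chain resists further extension (pulls its
    ends together); negative values mean the chain pushes its ends apart,
    i.e. exerts tension on a bowstring bridging them.  The bow tension is
    the negative of this quantity.
    """
    lo, hi = dist.support
    if not (lo < x0 < hi):
        raise ValueError(f"x0={x0} outside the distribution support ({lo}, {hi})")
    kbt = KBT
    return float(-kbt * dist.log_spline().derivative()(x0))


def bow_tension(dist: RadialDistribution, x0: float) -> float:
    """Tension (pN) the chain exerts on a string holding its ends at x0.

    Positive when the chain pushes its ends apart (x0 below the mode of
    p), which is the operating regime of the DNA bow.
    """
    return -entropic_force(dist, x0)


# ---------------------------------------------------------------------------
# Marko–Siggia and short-chain force-extension relations
# ---------------------------------------------------------------------------


def ms_force(model: WLCModel, x) -> np.ndarray | float:
    """Marko–Siggia interpolated WLC force at extension x (pN)."""
    x_arr = np.asarray(x, dtype=float)
    z = x_arr / model.contour_length
    if np.any(z < 0) or np.any(z >= 1):
        raise ValueError("extension must satisfy 0 <= x < L")
    f = (KBT / model.persistence_length) * (
        0.25 / (1.0 - z) ** 2 - 0.25 + z
    )
    return f if np.ndim(x) else float(f)


def ms_extension(model: WLCModel, f) -> np.ndarray | float:
    """Extension at force f >= 0, the unique root of the Marko–Siggia relation."""

    def solve_one(fi: float) -> float:
        if fi < 0:
            raise ValueError("force must be non-negative")
        if fi == 0:
            return 0.0
        L = model.contour_length
        g = lambda x: ms_force(model, x) - fi
        return brentq(g, 0.0, L * (1.0 - 1e-12), xtol=1e-14, rtol=1e-15)

    if np.ndim(f):
        return np.array([solve_one(fi) for fi in np.asarray(f, dtype=float)])
    return solve_one(float(f))


@dataclass(frozen=True)
class MarkoSiggiaFER:
    """Marko–Siggia force-extension relation of a WLC state."""

    model: WLCModel

    def extension(self, f) -> np.ndarray | float:
        return ms_extension(self.model, f)

    def tension(self, x) -> np.ndarray | float:
        return ms_force(self.model, x)


def short_chain_extension(model: WLCModel, f, grid_size: int = 4001) -> float:
    """Fixed-force extension of a finite chain from its tilted p(x).

    Short chains do not reach the thermodynamic limit assumed by the
    Marko–Siggia interpolation.  Here the extension at constant force is
    the maximum-term estimate from the finite-chain end-to-end density:
    the x that maximizes log p(x) + f x / kBT, i.e. the root of
    -kBT d log p/dx = -f.  At f = 0 this is the (finite, positive) mode
    of p; for long chains it converges to the Marko–Siggia curve by
    ensemble equivalence.
    """
    dist = wlc_radial_pdf(model, np.linspace(0, model.contour_length, grid_size))
    return _short_chain_from_dist(dist, f)


def _short_chain_from_dist(dist: RadialDistribution, f) -> np.ndarray | float:
    d1 = dist.log_spline().derivative()
    lo, hi = dist.support
    eps = (hi - lo) * 1e-6

    mode = dist.mode

    def solve_one(fi: float) -> float:
        if fi < 0:
            raise ValueError("force must be non-negative")
        if fi == 0:
            return mode
        g = lambda x: KBT * d1(x) + fi
        b = hi - eps
        if g(b) > 0:  # tilt pushes the maximum to the edge of support
            return float(b)
        return float(brentq(g, mode, b, xtol=1e-12))

    if np.ndim(f):
        return np.array([solve_one(fi) for fi in np.asarray(f, dtype=float)])
    return solve_one(float(f))


@dataclass(frozen=True)
class ShortChainFER:
    """Finite-chain force-extension relation based on the tilted p(x)."""

    model: WLCModel
    grid_size: int = 4001

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "_dist",
            wlc_radial_pdf(
                self.model,
                np.linspace(0, self.model.contour_length, self.grid_size),
            ),
        )

    def extension(self, f) -> np.ndarray | float:
        return _short_chain_from_dist(self._dist, f)


# ---------------------------------------------------------------------------
# linear FERs, crossover, fitting
# ---------------------------------------------------------------------------


def linear_fer_extension(fer: LinearFER, f) -> np.ndarray | float:
    """Extension x = f/a + b of a linear force-extension relation."""
    x = np.asarray(f, dtype=float) / fer.a + fer.b
    return x if np.ndim(f) else float(x)


def crossover_force(
    fer_a,
    fer_b,
    bracket: tuple[float, float] = (1e-3, 20.0),
) -> float:
    """Force at which two states have identical extension.

    Accepts any objects exposing ``extension(f)`` (LinearFER,
    MarkoSiggiaFER, ShortChainFER, ...).  The curves must cross exactly
    once within the bracket.
    """
    if isinstance(fer_a, LinearFER) and isinstance(fer_b, LinearFER):
        inv = 1.0 / fer_a.a - 1.0 / fer_b.a
        if inv == 0:
            raise ValueError("parallel linear FERs never cross")
        f_star = (fer_b.b - fer_a.b) / inv
        if not (bracket[0] <= f_star <= bracket[1]):
            raise ValueError("no crossover inside the bracket")
        return float(f_star)

    g = lambda f: float(fer_a.extension(f)) - float(fer_b.extension(f))
    lo, hi = bracket
    if g(lo) * g(hi) > 0:
        raise ValueError("extension curves do not cross inside the bracket")
    return float(brentq(g, lo, hi, xtol=1e-10))


def fit_linear_fer(
    forces: Sequence[float] | np.ndarray,
    extensions: Sequence[float] | np.ndarray,
) -> LinearFER:
    """Ordinary least squares of extension on force.

    The fitted slope is 1/a and the intercept b; standard errors are
    propagated onto a and b.  Requires at least 3 samples spanning at
    least 1 pN of force.
    """
    f = np.asarray(forces, dtype=float)
    x = np.asarray(extensions, dtype=float)
    if f.size < 3:
        raise ValueError("need at least 3 force-extension samples")
    if np.ptp(f) < 1.0:
        raise ValueError("force samples must span at least 1 pN")
    A = np.column_stack([f, np.ones_like(f)])
    coef, res, rank, _ = np.linalg.lstsq(A, x, rcond=None)
    if rank < 2:
        raise ValueError("rank-deficient design (a single force value?)")
    slope, intercept = coef
    if slope <= 0:
        raise ValueError("non-positive compliance: not a spring-like FER")
    resid = x - A @ coef
    dof = max(f.size - 2, 1)
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.inv(A.T @ A)
    slope_se = np.sqrt(cov[0, 0])
    b_se = np.sqrt(cov[1, 1])
    a = 1.0 / slope
    a_se = slope_se / slope**2  # delta method on a = 1/slope
    return LinearFER(a=float(a), b=float(intercept), a_se=float(a_se), b_se=float(b_se))


def trap_force(trap: HarmonicTrap, mean_extension: float) -> float:
    """Tension from a harmonic restraint, f = -k (x_mean - x0)."""
    return float(-trap.k * (mean_extension - trap.x0))
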