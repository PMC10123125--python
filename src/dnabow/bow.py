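"""Tension calibration for DNA bows.

Two routes estimate the force a bent dsDNA arc exerts on its ssDNA
bowstring:

* the entropic route: the arc is a worm-like chain and the tension at the
  observed (or self-consistently determined) extension is the logarithmic
  derivative of its end-to-end distribution, with error propagation from
  the extension spread;
* the elastic route: a rigid base-pair chain with intrinsic roll/tilt
  (sequence-dependent curvature) is relaxed under a harmonic end-to-end
  restraint, and the force read off the restraint spring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import DS_RISE, KBT
from .polymer import (
    LinearFER,
    RadialDistribution,
    WLCModel,
    wlc_radial_pdf,
)

__all__ = [
    "ExtensionStats",
    "BowDesign",
    "RigidBasePairChain",
    "RestrainedMinimizationResult",
    "bow_force_estimate",
    "bow_self_consistent",
    "rbp_ground_state",
    "rbp_restrained_minimize",
    "register_scan",
]

DEFAULT_ARC_LENGTHS_BP = (74, 84, 105, 126, 158, 210, 252)


@dataclass(frozen=True)
class ExtensionStats:
    """Mean and spread of an arc end-to-end extension sample."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need at least 2 samples")

    @classmethod
    def from_samples(cls, samples) -> "ExtensionStats":
        arr = np.asarray(samples, dtype=float)
        return cls(mean=float(arr.mean()), sd=float(arr.std(ddof=1)), n=arr.size)


@dataclass(frozen=True)
class BowDesign:
    """Geometry of a DNA bow construct."""

    arc_length_bp: int
    string_length_nt: int = 15
    state: str = "unbound"
    target_sequence: str = "TGAAATTAC"

    def __post_init__(self) -> None:
        if self.arc_length_bp < 10:
            raise ValueError("arc too short")
        if self.state not in ("bound", "unbound"):
            raise ValueError("state must be 'bound' or 'unbound'")

    def arc_model(self, persistence_length: float = 50.0) -> WLCModel:
        return WLCModel(self.arc_length_bp * DS_RISE, persistence_length)


def bow_force_estimate(
    arc: WLCModel | RadialDistribution, stats: ExtensionStats
) -> tuple[float, float]:
    """Tension on the bowstring and its uncertainty from extension stats.

    The force is the bow tension (positive = arc pushes its ends apart)
    at the mean extension; the uncertainty is |df/dx| * sd(x), evaluated
    on the log-density spline.
    """
    dist = arc if isinstance(arc, RadialDistribution) else wlc_radial_pdf(arc)
    lo, hi = dist.support
    if not (lo < stats.mean - 3 * stats.sd and stats.mean + 3 * stats.sd < hi):
        raise ValueError("mean extension +/- 3 sd must lie inside the support")
    spline = dist.log_spline()
    f = float(KBT * spline.derivative()(stats.mean))
    dfdx = float(KBT * spline.derivative(2)(stats.mean))
    return f, abs(dfdx) * stats.sd


def bow_self_consistent(
    arc: WLCModel | RadialDistribution,
    string_fer,
    grid_size: int = 8001,
) -> tuple[float, float]:
    """Equilibrium extension and tension of an arc loaded by a string.

    Solves tension_arc(x) = tension_string(x): the arc tension is the
    (decreasing) bow tension from the arc's end-to-end distribution; the
    string tension is the (increasing) force needed to stretch the
    bowstring to x.  ``string_fer`` must expose ``tension(x)`` (a
    LinearFER, for instance); negative string tensions are clamped to
    zero since a slack strand cannot push.
    """
    from scipy.optimize import brentq

    if isinstance(arc, RadialDistribution):
        dist = arc
    else:
        dist = wlc_radial_pdf(arc, np.linspace(0, arc.contour_length, grid_size))
    spline_d1 = dist.log_spline().derivative()
    arc_tension = lambda x: float(KBT * spline_d1(x))

    def gap(x: float) -> float:
        return arc_tension(x) - max(float(string_fer.tension(x)), 0.0)

    lo, _ = dist.support
    mode = dist.mode
    a = max(lo * 1.001, getattr(string_fer, "b", lo) + 1e-9)
    if a >= mode or gap(a) < 0 or gap(mode) > 0:
        raise ValueError("no equilibrium: curves do not cross in bracket")
    x_star = float(brentq(gap, a, mode, xtol=1e-10))
    return x_star, arc_tension(x_star)


# ---------------------------------------------------------------------------
# rigid base-pair chain with intrinsic curvature
# ---------------------------------------------------------------------------


@dataclass
class RigidBasePairChain:
    """Per-step ground-state angles and stiffnesses of a dsDNA segment.

    Angles are in degrees (roll, tilt, twist per base-pair step),
    stiffnesses in kBT/deg^2, rise in nm/step.  A sequence-independent
    B-DNA default (straight, twist 34.3 deg) is provided by
    :meth:`straight`.
    """

    roll0: np.ndarray
    tilt0: np.ndarray
    twist0: np.ndarray
    beta_roll: np.ndarray
    beta_tilt: np.ndarray
    beta_twist: np.ndarray
    rise: float = DS_RISE

    def __post_init__(self) -> None:
        arrays = [
            np.asarray(a, dtype=float)
            for a in (
                self.roll0, self.tilt0, self.twist0,
                self.beta_roll, self.beta_tilt, self.beta_twist,
            )
        ]
        n = arrays[0].size
        if any(a.size != n for a in arrays):
            raise ValueError("all per-step arrays must share one length")
        if any(np.any(a <= 0) for a in arrays[3:]):
            raise ValueError("stiffnesses must be positive")
        (self.roll0, self.tilt0, self.twist0,
         self.beta_roll, self.beta_tilt, self.beta_twist) = arrays

    @property
    def n_steps(self) -> int:
        return self.roll0.size

    @classmethod
    def straight(
        cls,
        n_steps: int,
        twist: float = 34.3,
        beta: float = 0.02,
        rise: float = DS_RISE,
    ) -> "RigidBasePairChain":
        z = np.zeros(n_steps)
        b = np.full(n_steps, beta)
        return cls(z, z.copy(), np.full(n_steps, twist), b, b.copy(), b.copy(), rise)

    def angles0(self) -> np.ndarray:
        return np.stack([self.roll0, self.tilt0, self.twist0], axis=1)

    def betas(self) -> np.ndarray:
        return np.stack([self.beta_roll, self.beta_tilt, self.beta_twist], axis=1)


def _rotation(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    x, y, z = axis
    K = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) * c + s * K + (1 - c) * np.outer(axis, axis)


def rbp_path(chain: RigidBasePairChain, angles: np.ndarray) -> np.ndarray:
    """Base-pair center coordinates for a given set of step angles (deg).

    Step i rotates frame i into frame i+1: tilt about the local e1 axis,
    roll about e2, twist about the helical axis e3, followed by a rise
    translation along the new e3.
    """
    ang = np.deg2rad(np.asarray(angles, dtype=float).reshape(chain.n_steps, 3))
    frame = np.eye(3)  # columns e1, e2, e3
    pos = np.zeros((chain.n_steps + 1, 3))
    for i in range(chain.n_steps):
        roll, tilt, twist = ang[i]
        R = (
            _rotation(frame[:, 0], tilt)
            @ _rotation(frame[:, 1], roll)
            @ _rotation(frame[:, 2], twist)
        )
        frame = R @ frame
        pos[i + 1] = pos[i] + chain.rise * frame[:, 2]
    return pos


def rbp_ground_state(chain: RigidBasePairChain) -> np.ndarray:
    """3-D path of base-pair centers in the intrinsic (ground) state."""
    return rbp_path(chain, chain.angles0())


def _end_to_end_and_grad(chain: RigidBasePairChain, angles: np.ndarray):
    """End-to-end distance r and its analytic gradient dr/dangle (per deg).

    Each step angle is a rotation about a lab-frame axis applied to all
    downstream material; the derivative of the end position with respect
    to that angle is axis x (end - pivot).
    """
    ang = np.deg2rad(angles.reshape(chain.n_steps, 3))
    frame = np.eye(3)
    pos = np.zeros(3)
    pivots = np.zeros((chain.n_steps, 3))
    axes = np.zeros((chain.n_steps, 3, 3))  # per step: roll, tilt, twist axes
    for i in range(chain.n_steps):
        roll, tilt, twist = ang[i]
        a_tilt = frame[:, 0].copy()
        Rt = _rotation(a_tilt, tilt)
        a_roll = Rt @ frame[:, 1]
        Rr = _rotation(a_roll, roll)
        a_twist = Rr @ Rt @ frame[:, 2]
        Rw = _rotation(a_twist, twist)
        frame = Rw @ Rr @ Rt @ frame
        pivots[i] = pos
        axes[i, 0] = a_roll
        axes[i, 1] = a_tilt
        axes[i, 2] = a_twist
        pos = pos + chain.rise * frame[:, 2]
    r_vec = pos
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        return r, np.zeros((chain.n_steps, 3))
    r_hat = r_vec / r
    # d(end)/d(theta_i) = axis x (end - pivot_i); project on r_hat
    lever = r_vec[None, :] - pivots  # (n, 3)
    grad = np.empty((chain.n_steps, 3))
    for k in range(3):
        grad[:, k] = np.cross(axes[:, k, :], lever) @ r_hat
    return r, np.deg2rad(1.0) * grad  # per degree


@dataclass
class RestrainedMinimizationResult:
    """Outcome of the restrained rigid base-pair minimization."""

    angles: np.ndarray
    energy: float
    r: float
    force: float
    iterations: int
    converged: bool
    energy_trace: np.ndarray = field(repr=False, default=None)


def rbp_restrained_minimize(
    chain: RigidBasePairChain,
    kappa: float,
    r0: float,
    start_register: float = 0.0,
    max_iter: int = 2000,
    tol: float = 1e-8,
) -> RestrainedMinimizationResult:
    """Gradient descent on E = sum beta_i (x_i - x_i0)^2 + kappa (r - r0)^2.

    ``kappa`` is in pN/nm, ``r0`` in nm; angle stiffnesses are in kBT/deg^2
    and the total energy is expressed in kBT.  Descent uses the analytic
    gradient (the end-to-end gradient follows from the rotation-axis lever
    rule) with backtracking line search; the restraint force is read off
    the spring as f = 2 kappa (r - r0).

    Starts from a conformation uniformly curved toward the rotational
    register angle ``start_register`` (degrees), bent just enough to bring
    the ends to r0.
    """
    if kappa <= 0 or r0 < 0:
        raise ValueError("kappa must be positive and r0 non-negative")
    betas = chain.betas()  # kBT/deg^2
    x0 = chain.angles0()
    kappa_kbt = kappa / KBT  # kBT/nm^2

    x = _uniformly_curved_start(chain, r0, start_register)

    def energy_grad(ang: np.ndarray):
        r, dr = _end_to_end_and_grad(chain, ang)
        d = ang - x0
        e = float(np.sum(betas * d * d)) + kappa_kbt * (r - r0) ** 2
        g = 2.0 * betas * d + 2.0 * kappa_kbt * (r - r0) * dr
        return e, g, r

    e, g, r = energy_grad(x)
    trace = [e]
    step = 1.0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        gnorm2 = float(np.sum(g * g))
        if gnorm2 < 1e-20:
            converged = True
            break
        # backtracking line search (Armijo)
        accepted = False
        for _ in range(60):
            x_new = x - step * g
            e_new, g_new, r_new = energy_grad(x_new)
            if e_new <= e - 0.5 * step * gnorm2 * 1e-4:
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        de = e - e_new
        x, g, r = x_new, g_new, r_new
        e = e_new
        trace.append(e)
        step = min(step * 1.5, 1e3)
        if de < tol:
            converged = True
            break
    return RestrainedMinimizationResult(
        angles=x,
        energy=e,
        r=r,
        force=2.0 * kappa * (r - r0),
        iterations=it,
        converged=converged,
        energy_trace=np.asarray(trace),
    )


def _uniformly_curved_start(
    chain: RigidBasePairChain, r0: float, register_deg: float
) -> np.ndarray:
    """Ground-state angles plus a uniform bend toward a register angle.

    The bend is distributed as roll/tilt components that rotate with the
    accumulated twist, so the curvature plane is fixed in space; its
    magnitude closes the chain ends to approximately r0.
    """
    n = chain.n_steps
    L = n * chain.rise
    # total turning angle theta for a circular arc with chord r0
    from scipy.optimize import brentq

    chord = lambda th: L * np.sin(th / 2) / (th / 2)
    if r0 >= L:
        per_step = 0.0
    else:
        theta = brentq(
            lambda th: chord(th) - max(r0, 1e-6), 1e-6, 2 * np.pi - 1e-9
        )
        per_step = np.rad2deg(theta / n)
    psi = np.deg2rad(np.cumsum(chain.twist0) - chain.twist0 / 2) + np.deg2rad(register_deg)
    x = chain.angles0().copy()
    x[:, 0] += per_step * np.cos(psi)  # roll
    x[:, 1] += per_step * np.sin(psi)  # tilt
    return x


def register_scan(
    chain: RigidBasePairChain,
    kappa: float,
    r0: float,
    n_registers: int = 36,
    seed: int | None = None,
    **kwargs,
) -> tuple[float, float, np.ndarray]:
    """Restraint forces over initial rotational registers.

    Registers are uniform on [0, 360) by default; with ``seed`` given
    they are drawn uniformly at random (reproducibly).  Returns
    (mean force, sd force, per-register forces).
    """
    if seed is None:
        regs = np.linspace(0.0, 360.0, n_registers, endpoint=False)
    else:
        regs = np.random.default_rng(seed).uniform(0.0, 360.0, n_registers)
    forces = np.array(
        [
            rbp_restrained_minimize(chain, kappa, r0, start_register=reg, **kwargs).force
            for reg in regs
        ]
    )
    return float(forces.mean()), float(forces.std(ddof=1)), forces
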