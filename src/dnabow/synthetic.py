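"""Seeded generators for every input class the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and its
output passes the corresponding analysis stage unmodified:

* two-state telegraph FRET traces with shot-like Gaussian intensity noise,
  emulating probe binding/unbinding on a surface-tethered bow;
* rate-versus-force tables drawn log-normally around the closed-form
  force-dependent rate laws;
* discrete worm-like chain ensembles of end-to-end distances;
* biased (extension, base-pair-count) samples from a toy two-dimensional
  zipper free-energy surface with per-stratum umbrella weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KBT

__all__ = [
    "TelegraphParams",
    "ZipperSurfaceParams",
    "gen_fret_telegraph",
    "gen_rate_dataset",
    "gen_landscape_samples",
    "gen_wlc_chains",
    "DEFAULT_FORCES_PN",
]

#: Default force grid, spanning the calibrated bound-state range of the assay.
DEFAULT_FORCES_PN = (1.6, 2.4, 3.2, 4.0, 4.8, 5.6, 6.25)


# ---------------------------------------------------------------------------
# two-state telegraph FRET traces
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TelegraphParams:
    """Parameters of a simulated two-state FRET trace.

    ``kon_c`` is the pseudo-first-order binding rate k_on*[c] in 1/s,
    ``koff`` the unbinding rate in 1/s.  Per-state FRET means default to
    0.2 (unbound) and 0.8 (bound), approximating the low/high FRET modes
    of the assay; ``sigma_E`` is the framewise efficiency noise.
    """

    kon_c: float
    koff: float
    dt: float = 0.05
    duration: float = 100.0
    e_off: float = 0.2
    e_on: float = 0.8
    sigma_E: float = 0.05
    intensity: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kon_c <= 0 or self.koff < 0:
            raise ValueError("rates must be positive (koff may be 0)")
        if not (0 <= self.e_off < self.e_on <= 1):
            raise ValueError("need 0 <= e_off < e_on <= 1")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")


def gen_fret_telegraph(params: TelegraphParams, start_state: int | None = None):
    """Simulate a telegraph FRET trace.

    A continuous-time two-state Markov chain with exact exponential waiting
    times is sampled; the framewise state is the state at each frame
    midpoint, and donor/acceptor intensities are drawn with Gaussian noise
    around the per-state means.  Returns ``(trace, states)`` where
    ``trace`` is a :class:`~dnabow.fret.FretTrace` and ``states`` the
    ground-truth binary state per frame (1 = bound).
    """
    from .fret import FretTrace

    rng = np.random.default_rng(params.seed)
    n_frames = int(round(params.duration / params.dt))
    t_end = n_frames * params.dt

    if start_state is None:
        p_bound = (
            params.kon_c / (params.kon_c + params.koff)
            if params.koff > 0
            else 1.0
        )
        state = int(rng.random() < p_bound)
    else:
        state = int(start_state)

    # event-driven simulation of switching times
    switch_times = []
    switch_states = [state]
    t = 0.0
    s = state
    while t < t_end:
        rate = params.koff if s == 1 else params.kon_c
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= t_end:
            break
        s = 1 - s
        switch_times.append(t)
        switch_states.append(s)

    midpoints = (np.arange(n_frames) + 0.5) * params.dt
    idx = np.searchsorted(switch_times, midpoints, side="right")
    states = np.asarray(switch_states, dtype=np.int8)[idx]

    e_mean = np.where(states == 1, params.e_on, params.e_off)
    e_noisy = e_mean + rng.normal(0.0, params.sigma_E, size=n_frames)
    total = params.intensity
    acceptor = np.clip(e_noisy, 0.0, 1.0) * total
    donor = total - acceptor
    trace = FretTrace(
        dt=params.dt,
        donor=donor,
        acceptor=acceptor,
        background_subtracted=True,
    )
    return trace, states


# ---------------------------------------------------------------------------
# rate-versus-force tables
# ---------------------------------------------------------------------------


def gen_rate_dataset(
    kon0: float,
    koff0: float,
    kappa_ts: float,
    x0_ts: float,
    kappa_u: float,
    x0_u: float,
    x0_b: float,
    n: int,
    forces=DEFAULT_FORCES_PN,
    sigma_log: float = 0.05,
    replicates: int = 3,
    concentration: float = 20e-9,
    sequence: str = "GTAAATTCA",
    seed: int = 0,
) -> pd.DataFrame:
    """Rate-versus-force table drawn around the closed-form rate laws.

    Log-rates are perturbed with Gaussian noise of sd ``sigma_log``; the
    reported SEM is rate * sigma_log / sqrt(replicates), mimicking the
    pooling of replicate trials at each force.
    """
    from .kinetics import kon_closed_form, koff_closed_form, RateLawParams

    rng = np.random.default_rng(seed)
    params = RateLawParams(
        kon0=kon0, koff0=koff0, kappa_ts=kappa_ts, x0_ts=x0_ts,
        kappa_u=kappa_u, x0_u=x0_u, x0_b=x0_b, n=n,
    )
    rows = []
    for f in forces:
        kon_true = kon_closed_form(params, f)
        koff_true = koff_closed_form(params, f)
        lk_on = np.log(kon_true) + rng.normal(0, sigma_log, size=replicates)
        lk_off = np.log(koff_true) + rng.normal(0, sigma_log, size=replicates)
        kon = float(np.exp(lk_on).mean())
        koff = float(np.exp(lk_off).mean())
        sem_scale = sigma_log / np.sqrt(replicates) if sigma_log > 0 else 1e-3
        rows.append(
            dict(
                sequence=sequence,
                force_pN=float(f),
                force_err=0.0,
                kon=kon,
                kon_sem=kon * sem_scale,
                koff=koff,
                koff_sem=koff * sem_scale,
                concentration_M=concentration,
                n_molecules=replicates * 150,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# toy zipper free-energy surface and biased samples
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZipperSurfaceParams:
    """Toy free-energy surface of a 9-bp duplex melting under tension.

    Columns are base-pair counts n_bp in [0, n_max]; the free energy along
    extension within a column is harmonic around a center x_c(n_bp; f)
    placed by the state force-extension relations: the fully bound column
    follows the bound FER, the fully melted column the unbound (ssDNA)
    FER, and the nucleated n_bp = 1 column the transition-state FER, which
    is the most extended of the three at the assay forces.  Intermediate
    columns interpolate.  The nucleated column sits ``barrier`` kBT above
    the melted reference, making n_bp = 1 the free-energy maximum along
    the melting coordinate; zipped columns lie ``bound_offset`` above the
    melted state (the duplex is destabilized in the toy's tensioned
    conditions), with ``eps_bp`` spreading the intermediate columns, so an
    exponentially increasing umbrella weight W(n_bp) can flatten the
    sampling as in the real protocol.
    """

    eps_bp: float = 1.0          # spread of intermediate column energies, kBT
    barrier: float = 5.0         # nucleated-column (n_bp = 1) offset, kBT
    bound_offset: float = 2.0    # fully zipped column offset, kBT
    n_max: int = 9
    sigma_x: float = 0.35        # within-column extension sd, nm
    # per-nucleotide FER triplet (kappa pN/nm, x0 nm) for u, ts, b
    kappa_u: float = 30.7
    x0_u: float = 0.21
    kappa_ts: float = 355.3
    x0_ts: float = 0.39
    x0_b: float = 0.34
    n_nt: int = 9
    x_min: float = 0.0
    x_max: float = 8.0
    bin_width: float = 0.085

    def column_center(self, n_bp: int, f: float) -> float:
        """Most probable extension of the n_bp stratum at force f (nm)."""
        n = self.n_nt
        x_u = n * (f / self.kappa_u + self.x0_u)
        x_ts = n * (f / self.kappa_ts + self.x0_ts)
        x_b = n * self.x0_b
        if n_bp == 0:
            return x_u
        if n_bp == 1:
            return x_ts
        # interpolate between nucleated and fully bound
        w = (n_bp - 1) / (self.n_max - 1)
        return (1 - w) * x_ts + w * x_b

    def column_offset(self, n_bp: int) -> float:
        """Free energy of the column minimum, kBT (melted state = 0)."""
        if n_bp == 0:
            return 0.0
        if n_bp == 1:
            return self.barrier
        # intermediates slope down from the barrier shoulder to the bound state
        frac = (self.n_max - n_bp) / max(self.n_max - 2, 1)
        return self.bound_offset + self.eps_bp * frac

    def surface_grid(self, f: float):
        """Exact toy free energy on the analysis grid (x_bins, n_bp)."""
        edges = np.arange(self.x_min, self.x_max + self.bin_width, self.bin_width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n_vals = np.arange(self.n_max + 1)
        G = np.empty((centers.size, n_vals.size))
        for j, nb in enumerate(n_vals):
            xc = self.column_center(nb, f)
            G[:, j] = (centers - xc) ** 2 / (2 * self.sigma_x**2) + self.column_offset(nb)
        return centers, n_vals, G


def gen_landscape_samples(
    params: ZipperSurfaceParams,
    weights: dict[int, float] | None = None,
    n_samples: int = 100_000,
    force: float = 4.0,
    weight_rate: float = 0.3,
    seed: int = 0,
):
    """Exact draws from the discretized biased zipper distribution.

    The biased distribution is q(x, n_bp) ∝ exp(-G_toy(x, n_bp)) * W(n_bp)
    on the analysis grid.  Returns a :class:`~dnabow.landscape.LandscapeSampleSet`.
    The default umbrella weights increase exponentially with n_bp,
    W(n_bp) = exp(weight_rate * n_bp), pushing sampling toward melted
    states.
    """
    from .landscape import LandscapeSampleSet

    rng = np.random.default_rng(seed)
    centers, n_vals, G = params.surface_grid(force)
    if weights is None:
        weights = {int(nb): float(np.exp(weight_rate * nb)) for nb in n_vals}
    w_arr = np.array([weights[int(nb)] for nb in n_vals])
    q = np.exp(-(G - G.min())) * w_arr[None, :]
    q = q / q.sum()
    flat_idx = rng.choice(q.size, size=n_samples, p=q.ravel())
    ix, inb = np.unravel_index(flat_idx, q.shape)
    # jitter within the bin so samples look like continuous extensions
    x_samp = centers[ix] + rng.uniform(
        -params.bin_width / 2, params.bin_width / 2, size=n_samples
    )
    return LandscapeSampleSet(
        x=x_samp,
        n_bp=n_vals[inb].astype(int),
        force=force,
        weights=weights,
        bin_width=params.bin_width,
        x_range=(params.x_min, params.x_max),
    )


# ---------------------------------------------------------------------------
# discrete worm-like chains
# ---------------------------------------------------------------------------


def gen_wlc_chains(
    L: float,
    P: float,
    n_segments: int = 100,
    n_chains: int = 10_000,
    seed: int = 0,
) -> np.ndarray:
    """End-to-end distances of discrete worm-like chains.

    Each chain is n_segments rigid links of length L/n_segments; at every
    joint the tangent is rotated by independent Gaussian bend angles of
    variance (segment length)/P in each of the two transverse directions.
    Returns an array of n_chains scalar end-to-end distances.
    """
    if L <= 0 or P <= 0:
        raise ValueError("L and P must be positive")
    rng = np.random.default_rng(seed)
    ds = L / n_segments
    sigma = np.sqrt(ds / P)

    # start along z; accumulate tangents by rotating in two transverse dirs
    t = np.zeros((n_chains, 3))
    t[:, 2] = 1.0
    ee = np.zeros((n_chains, 3))
    for _ in range(n_segments):
        ee += t * ds
        theta_x = rng.normal(0.0, sigma, n_chains)
        theta_y = rng.normal(0.0, sigma, n_chains)
        # build local frame (u, v, t) and tilt t by the bend angles
        ref = np.where(
            np.abs(t[:, 2:3]) < 0.9, np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])
        )
        u = np.cross(t, ref)
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v = np.cross(t, u)
        t = (
            t * np.cos(np.hypot(theta_x, theta_y))[:, None]
            + (u * theta_x[:, None] + v * theta_y[:, None])
            * np.where(
                np.hypot(theta_x, theta_y)[:, None] > 0,
                np.sin(np.hypot(theta_x, theta_y))[:, None]
                / np.maximum(np.hypot(theta_x, theta_y)[:, None], 1e-300),
                1.0,
            )
        )
        t /= np.linalg.norm(t, axis=1, keepdims=True)
    return np.linalg.norm(ee, axis=1)
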