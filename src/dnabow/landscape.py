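"""Umbrella-reweighted free-energy surfaces of duplex melting.

Biased samples along two reaction coordinates — the target-strand
extension x and the number of remaining base pairs n_bp — are inverted to
equilibrium probabilities by dividing out the per-stratum umbrella weight
W(n_bp) and renormalizing,

    p_eq(x, n_bp; f) = p_biased(x, n_bp; f) / W(n_bp),

then converted to free energies G = -kBT log p_eq + C, with C chosen so
the global minimum is 0.  The minimum-energy path x~(n_bp) traces the
most probable transition pathway; the nucleated n_bp = 1 column is the
free-energy maximum along it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LandscapeSampleSet",
    "FreeEnergySurface",
    "hbond_count",
    "umbrella_reweight",
    "build_surface",
    "min_energy_path",
    "path_offset",
    "surface_from_samples",
]

#: default extension bin width, nm (0.1 simulation units)
DEFAULT_BIN_WIDTH = 0.085

#: hydrogen-bond energy cutoff in simulation units (= 1 kBT at 22 C)
HBOND_CUTOFF_SIM = -0.1


@dataclass
class LandscapeSampleSet:
    """Biased (extension, base-pair count) samples with umbrella weights."""

    x: np.ndarray
    n_bp: np.ndarray
    force: float
    weights: dict[int, float]
    bin_width: float = DEFAULT_BIN_WIDTH
    x_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n_bp = np.asarray(self.n_bp, dtype=int)
        if self.x.shape != self.n_bp.shape:
            raise ValueError("x and n_bp must have matching shapes")
        if np.any(self.n_bp < 0):
            raise ValueError("n_bp must be non-negative")
        for nb, wv in self.weights.items():
            if wv <= 0:
                raise ValueError(f"bias weight W({nb}) must be positive")

    @property
    def n_samples(self) -> int:
        return self.x.size


@dataclass
class FreeEnergySurface:
    """Free energy G(x_bin, n_bp) in kBT on a regular extension grid.

    Unsampled bins carry +inf and are excluded from minima and paths.
    ``sparse_strata`` lists n_bp columns with fewer samples than the
    sparsity threshold; they are flagged, not dropped.
    """

    x_centers: np.ndarray
    n_bp_values: np.ndarray
    G: np.ndarray  # shape (n_x, n_nbp)
    force: float = np.nan
    offset_convention: str = "global_min_zero"
    sparse_strata: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        if self.G.shape != (self.x_centers.size, self.n_bp_values.size):
            raise ValueError("G shape must be (n_x, n_nbp)")


def hbond_count(pair_energies, cutoff: float = HBOND_CUTOFF_SIM) -> int:
    """Number of base pairs with hydrogen-bond energy below the cutoff."""
    e = np.asarray(pair_energies, dtype=float)
    return int(np.sum(e < cutoff))


def umbrella_reweight(samples: LandscapeSampleSet):
    """Invert the per-stratum umbrella bias into equilibrium probabilities.

    Bins the samples on the (x, n_bp) grid, divides each n_bp stratum by
    its weight W(n_bp), and renormalizes so the grid sums to 1.  Returns
    (x_centers, n_bp_values, p_eq).  Observed strata without a weight
    raise a missing-bias error.
    """
    observed = np.unique(samples.n_bp)
    missing = [int(nb) for nb in observed if int(nb) not in samples.weights]
    if missing:
        raise KeyError(f"no umbrella weight for observed strata {missing}")
    if samples.x_range is not None:
        lo, hi = samples.x_range
    else:
        lo, hi = samples.x.min(), samples.x.max() + samples.bin_width
    edges = np.arange(lo, hi + samples.bin_width, samples.bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_vals = np.arange(observed.max() + 1)
    counts = np.zeros((centers.size, n_vals.size))
    for j, nb in enumerate(n_vals):
        sel = samples.n_bp == nb
        if sel.any():
            counts[:, j], _ = np.histogram(samples.x[sel], bins=edges)
    w = np.array([samples.weights.get(int(nb), 1.0) for nb in n_vals])
    p = counts / w[None, :]
    p /= p.sum()
    return centers, n_vals, p


def build_surface(
    x_centers,
    n_bp_values,
    p_eq,
    force: float = np.nan,
    sparse_threshold: int = 50,
    counts=None,
) -> FreeEnergySurface:
    """G = -log p_eq (kBT), offset so the global minimum is 0.

    Empty bins get +inf.  When raw ``counts`` are supplied, strata with
    fewer than ``sparse_threshold`` samples are flagged in metadata.
    """
    p = np.asarray(p_eq, dtype=float)
    if np.any(p < 0):
        raise ValueError("probabilities must be non-negative")
    G = np.full_like(p, np.inf)
    pos = p > 0
    if not pos.any():
        raise ValueError("empty probability grid")
    G[pos] = -np.log(p[pos])
    G[pos] -= G[pos].min()
    sparse = []
    if counts is not None:
        col_counts = np.asarray(counts).sum(axis=0)
        sparse = [int(nb) for nb, c in zip(n_bp_values, col_counts) if c < sparse_threshold]
    return FreeEnergySurface(
        x_centers=np.asarray(x_centers, dtype=float),
        n_bp_values=np.asarray(n_bp_values, dtype=int),
        G=G,
        force=force,
        sparse_strata=sparse,
    )


def surface_from_samples(samples: LandscapeSampleSet, **kwargs) -> FreeEnergySurface:
    """Convenience: reweight then build the surface."""
    centers, n_vals, p = umbrella_reweight(samples)
    return build_surface(centers, n_vals, p, force=samples.force, **kwargs)


def min_energy_path(surface: FreeEnergySurface):
    """Lowest-energy extension per base-pair column.

    Returns (n_bp_values, x_tilde, G_path).  Ties break toward smaller x;
    columns with no finite bins yield NaN.
    """
    x_tilde = np.full(surface.n_bp_values.size, np.nan)
    g_path = np.full(surface.n_bp_values.size, np.nan)
    for j in range(surface.n_bp_values.size):
        col = surface.G[:, j]
        if np.isfinite(col).any():
            i = int(np.argmin(col))  # argmin returns the first (smallest-x) minimum
            x_tilde[j] = surface.x_centers[i]
            g_path[j] = col[i]
    return surface.n_bp_values, x_tilde, g_path


def path_offset(surface: FreeEnergySurface) -> FreeEnergySurface:
    """Offset each column so its minimum-energy path value is zero.

    Preserves within-column differences exactly; applying it twice is a
    no-op.
    """
    _, _, g_path = min_energy_path(surface)
    G = surface.G - np.where(np.isnan(g_path), 0.0, g_path)[None, :]
    return FreeEnergySurface(
        x_centers=surface.x_centers,
        n_bp_values=surface.n_bp_values,
        G=G,
        force=surface.force,
        offset_convention="per_column_path_zero",
        sparse_strata=list(surface.sparse_strata),
    )
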