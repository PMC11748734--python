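"""Single-subject morphological similarity networks.

Each cortical region contributes a sample of vertex-wise values of one
morphological feature (cortical thickness CT, fractal dimension FD,
gyrification index GI, or sulcal depth SD).  For every pair of regions the
two samples are turned into discrete probability distributions on a shared
support (Gaussian KDE evaluated on a 256-point grid, renormalized to sum
to one), and their Jensen-Shannon divergence (JSD, log base 2, hence
bounded by 1) is converted to a similarity

    similarity = 1 - sqrt(JSD)

in [0, 1].  The resulting symmetric matrix over the retained gyral +
sulcal regions (canonical order: gyral first) is the subject's
morphological network; its G-G, S-S, and G-S blocks are the gyral,
sulcal, and between-class subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import retained_indices

__all__ = [
    "DegenerateSampleError",
    "DensityGrid",
    "MorphNetwork",
    "common_grid",
    "estimate_density",
    "kld",
    "jsd",
    "similarity_from_jsd",
    "build_network",
    "extract_subcomponents",
    "mean_similarity",
]

_SUM_TOL = 1e-9


class DegenerateSampleError(ValueError):
    """A vertex sample has zero variance and admits no density estimate."""


@dataclass(frozen=True)
class DensityGrid:
    """Discrete probability distribution on an increasing support grid."""

    x: np.ndarray
    p: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "p", p)
        if x.ndim != 1 or p.shape != x.shape:
            raise ValueError("support and probabilities must be matching 1-D arrays")
        if np.any(np.diff(x) <= 0):
            raise ValueError("support must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > _SUM_TOL:
            raise ValueError(f"probabilities sum to {p.sum()!r}, expected 1")


def common_grid(
    values_a: np.ndarray, values_b: np.ndarray, n_points: int = 256
) -> np.ndarray:
    """Shared support for a pair of vertex samples.

    ``n_points`` equally spaced points spanning the pooled range of the two
    samples, padded by 10% of that range on each side.  Each sample must be
    non-degenerate (positive standard deviation).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateSampleError("constant-valued sample has no density")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    pad = 0.1 * (hi - lo)
    return np.linspace(lo - pad, hi + pad, int(n_points))


def _silverman_bandwidth(values: np.ndarray) -> float:
    # scipy.stats.gaussian_kde 'silverman' in one dimension:
    # (3n/4)^(-1/5) times the sample SD (ddof=1).
    n = values.size
    sd = values.std(ddof=1)
    return float(sd * (0.75 * n) ** (-0.2))


def _kde_on_grid(values: np.ndarray, grid: np.ndarray, bw: float) -> np.ndarray:
    z = (grid[:, None] - values[None, :]) / bw
    dens = np.exp(-0.5 * z * z).sum(axis=1)
    return dens


def estimate_density(values: np.ndarray, grid: np.ndarray) -> DensityGrid:
    """Gaussian KDE (Silverman bandwidth) on ``grid``, renormalized to a PMF.

    At least 10 values are required.  The continuous density estimate is
    treated as a discrete distribution over the grid points, so the
    returned probabilities sum to one exactly (up to float rounding).
    """
    values = np.asarray(values, dtype=float)
    grid = np.asarray(grid, dtype=float)
    if values.size < 10:
        raise ValueError(f"need at least 10 values, got {values.size}")
    bw = _silverman_bandwidth(values)
    if bw <= 0:
        raise DegenerateSampleError("zero bandwidth: sample has no spread")
    dens = _kde_on_grid(values, grid, bw)
    total = dens.sum()
    if total <= 0:
        raise DegenerateSampleError("density vanished on the supplied grid")
    return DensityGrid(x=grid, p=dens / total)


def _check_support(P: DensityGrid, Q: DensityGrid) -> None:
    if P.x.shape != Q.x.shape or not np.allclose(P.x, Q.x, rtol=0, atol=1e-12):
        raise ValueError("distributions are not on a shared support")


def _kld_arrays(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    if np.any(q[mask] == 0):
        raise ValueError("KLD undefined: Q has zero mass where P is positive")
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def kld(P: DensityGrid, Q: DensityGrid) -> float:
    """Kullback-Leibler divergence KLD(P||Q) in bits.

    Sum over grid points with P(i) > 0 of P(i) log2(P(i)/Q(i)); terms with
    P(i) = 0 contribute nothing.  Raises if Q has zero mass anywhere P is
    positive, or on a support mismatch.
    """
    _check_support(P, Q)
    return _kld_arrays(P.p, Q.p)


def jsd(P: DensityGrid, Q: DensityGrid) -> float:
    """Jensen-Shannon divergence in bits: symmetric and bounded in [0, 1].

    JSD(P||Q) = KLD(P||m)/2 + KLD(Q||m)/2 with m = (P+Q)/2.  The mixture is
    strictly positive wherever either argument is, so the divergence is
    always defined.
    """
    _check_support(P, Q)
    return _jsd_arrays(P.p, Q.p)


def _jsd_arrays(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)
    val = 0.5 * _kld_arrays(p, m) + 0.5 * _kld_arrays(q, m)
    # float rounding can leave a tiny excursion outside [0, 1]
    return float(min(max(val, 0.0), 1.0))


def similarity_from_jsd(j: float) -> float:
    """Map a divergence in [0, 1] to a similarity: 1 - sqrt(JSD)."""
    if not -1e-12 <= j <= 1 + 1e-12:
        raise ValueError(
            f"JSD {j!r} outside [0, 1]; check the divergence log base"
        )
    j = min(max(float(j), 0.0), 1.0)
    return 1.0 - float(np.sqrt(j))


@dataclass
class MorphNetwork:
    """Symmetric similarity matrix over retained regions.

    ``weights`` has unit diagonal and off-diagonal entries in [0, 1];
    ``region_ids`` and ``classes`` follow the canonical node order (gyral
    regions first, ascending id, then sulcal).
    """

    weights: np.ndarray
    region_ids: np.ndarray
    classes: np.ndarray
    feature: str = "feature"

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    @property
    def gyral_mask(self) -> np.ndarray:
        return self.classes == "gyral"

    @property
    def sulcal_mask(self) -> np.ndarray:
        return self.classes == "sulcal"


def _pair_similarity(a: np.ndarray, b: np.ndarray, n_points: int) -> float:
    grid = common_grid(a, b, n_points)
    pa = _kde_on_grid(a, grid, _silverman_bandwidth(a))
    pb = _kde_on_grid(b, grid, _silverman_bandwidth(b))
    pa /= pa.sum()
    pb /= pb.sum()
    return similarity_from_jsd(_jsd_arrays(pa, pb))


def build_network(
    feature_map: Mapping[int, np.ndarray],
    atlas: pd.DataFrame,
    n_points: int = 256,
    feature: str = "feature",
) -> MorphNetwork:
    """Build one subject's morphological network from per-region samples.

    ``feature_map`` maps region id to that region's vertex-value sample.
    Ambiguous regions in the atlas are ignored; every retained region must
    be present and non-degenerate.  For each unordered pair of retained
    regions a shared grid, two densities, and the JSD-based similarity are
    computed; the diagonal is 1 by definition (the self-divergence is zero
    analytically).
    """
    gyral_ids, sulcal_ids = retained_indices(atlas)
    ordered = list(gyral_ids) + list(sulcal_ids)
    classes = np.array(
        ["gyral"] * len(gyral_ids) + ["sulcal"] * len(sulcal_ids), dtype="U7"
    )
    samples = []
    for rid in ordered:
        if rid not in feature_map:
            raise KeyError(f"feature map is missing retained region {rid}")
        vals = np.asarray(feature_map[rid], dtype=float)
        if vals.std() == 0:
            raise DegenerateSampleError(
                f"region {rid}: constant-valued vertex sample"
            )
        samples.append(vals)

    n = len(ordered)
    w = np.ones((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            w[i, j] = w[j, i] = _pair_similarity(samples[i], samples[j], n_points)
    return MorphNetwork(
        weights=w,
        region_ids=np.asarray(ordered, dtype=int),
        classes=classes,
        feature=feature,
    )


def extract_subcomponents(
    net: MorphNetwork,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a network into its (G-G, S-S, G-S) blocks.

    The square blocks are symmetric with unit diagonal; the rectangular
    G-S block has gyral rows and sulcal columns.
    """
    g = np.flatnonzero(net.gyral_mask)
    s = np.flatnonzero(net.sulcal_mask)
    gg = net.weights[np.ix_(g, g)]
    ss = net.weights[np.ix_(s, s)]
    gs = net.weights[np.ix_(g, s)]
    return gg, ss, gs


def mean_similarity(block: np.ndarray, square: bool) -> float:
    """Mean similarity of a subnetwork block.

    For square (G-G or S-S) blocks: mean over the unique off-diagonal
    entries (upper triangle).  For the rectangular G-S block: mean over all
    entries.
    """
    block = np.asarray(block, dtype=float)
    if block.size == 0:
        raise ValueError("empty block")
    if square:
        if block.ndim != 2 or block.shape[0] != block.shape[1]:
            raise ValueError("square=True requires a square block")
        if block.shape[0] < 2:
            raise ValueError("square block needs at least 2 nodes")
        iu = np.triu_indices(block.shape[0], k=1)
        return float(block[iu].mean())
    return float(block.mean())
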