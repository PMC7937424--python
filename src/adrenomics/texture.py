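"""The 32-feature radiomic texture signature.

Five first-order histogram features, sixteen grey-level co-occurrence
matrix (GLCM, Haralick) features and eleven run-length matrix (RLM,
Galloway) features computed over a 3-D volume of interest.

Conventions
-----------
* Grey levels: uniform quantization of the VOI's own [min, max] range into
  ``Ng`` bins (default 32); levels are 1-based; a constant VOI maps to a
  single level.
* GLCM: symmetric co-occurrence at a fixed voxel offset; counts from all
  requested directions are pooled into one matrix before normalization.
  Pairs with either voxel outside the VOI are skipped.
* RLM: maximal equal-level runs along each direction; a gap in the VOI
  breaks a run; counts pooled over directions.
* Directions: ``"3d"`` uses the 13 unique nearest-neighbour offsets,
  ``"2d"`` the 4 unique in-plane offsets applied slice-wise (slices are
  indexed by the third axis).  Offsets are in voxel units; spacing
  anisotropy is deliberately ignored, as common texture tools do.
* Logarithms are base 2 and 0·log 0 := 0.  Degenerate fallbacks: GLCM
  correlation is 0 when a marginal variance vanishes; skewness/kurtosis
  are 0 for a constant VOI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateError, EmptyVOIError, ParameterError
from .volume import CTVolume, VOIMask, VOISample, extract_voi

# ---------------------------------------------------------------------------
# feature name registry

FIRST_ORDER_NAMES = (
    "histogram_mean",
    "histogram_sd",
    "histogram_skewness",
    "histogram_kurtosis",
    "histogram_entropy",
)

GLCM_NAMES = (
    "glcm_autocorrelation",
    "glcm_cluster_prominence",
    "glcm_cluster_shade",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_difference_entropy",
    "glcm_difference_variance",
    "glcm_dissimilarity",
    "glcm_energy",
    "glcm_entropy",
    "glcm_homogeneity_idm",
    "glcm_maximum_probability",
    "glcm_sum_average",
    "glcm_sum_entropy",
    "glcm_sum_variance",
    "glcm_variance",
)

RLM_NAMES = (
    "rlm_sre",
    "rlm_lre",
    "rlm_gln",
    "rlm_rln",
    "rlm_rp",
    "rlm_lgre",
    "rlm_hgre",
    "rlm_srlge",
    "rlm_srhge",
    "rlm_lrlge",
    "rlm_lrhge",
)

FEATURE_NAMES = FIRST_ORDER_NAMES + GLCM_NAMES + RLM_NAMES  # 5 + 16 + 11 = 32

# 13 unique 3-D nearest-neighbour directions (one per ± pair)
OFFSETS_3D: tuple[tuple[int, int, int], ...] = tuple(
    (di, dj, dk)
    for di in (-1, 0, 1)
    for dj in (-1, 0, 1)
    for dk in (-1, 0, 1)
    if (di, dj, dk) > (0, 0, 0)
)
# 4 unique in-plane directions, applied slice-wise (dk == 0)
OFFSETS_2D: tuple[tuple[int, int, int], ...] = ((1, 0, 0), (0, 1, 0), (1, 1, 0), (1, -1, 0))


def _directions(mode: str) -> tuple[tuple[int, int, int], ...]:
    if mode == "3d":
        return OFFSETS_3D
    if mode == "2d":
        return OFFSETS_2D
    raise ParameterError(f"direction mode must be '3d' or '2d', got {mode!r}")


@dataclass(frozen=True)
class TextureConfig:
    """Quantization and direction settings for feature extraction."""

    ng: int = 32
    mode: str = "3d"
    distance: int = 1

    def __post_init__(self) -> None:
        if self.ng < 2:
            raise ParameterError(f"Ng must be >= 2, got {self.ng}")
        if self.distance < 1:
            raise ParameterError(f"distance must be >= 1, got {self.distance}")
        _directions(self.mode)


# ---------------------------------------------------------------------------
# quantization


@dataclass(frozen=True)
class QuantizedVOI:
    """Grey levels (1..Ng) of VOI voxels, aligned to the sample's coords."""

    levels: np.ndarray
    coords: np.ndarray = field(repr=False)
    ng: int = 32
    bin_edges: np.ndarray | None = None


def quantize(sample: VOISample, ng: int = 32) -> QuantizedVOI:
    """Uniformly bin the VOI's HU range into ``ng`` grey levels.

    The maximum value maps to level ``ng``; a constant VOI maps entirely to
    level 1.  Quantization is min–max relative, so adding a constant HU
    offset leaves all levels unchanged.
    """
    if sample.voxel_count == 0:
        raise EmptyVOIError("cannot quantize an empty VOI")
    if ng < 2:
        raise ParameterError(f"Ng must be >= 2, got {ng}")
    v = np.asarray(sample.values, dtype=float)
    lo, hi = float(v.min()), float(v.max())
    edges = np.linspace(lo, hi, ng + 1)
    if hi == lo:
        levels = np.ones(v.size, dtype=np.int64)
    else:
        levels = np.floor((v - lo) / (hi - lo) * ng).astype(np.int64) + 1
        np.clip(levels, 1, ng, out=levels)
    return QuantizedVOI(levels=levels, coords=sample.coords, ng=ng, bin_edges=edges)


# ---------------------------------------------------------------------------
# first-order (histogram) features


def first_order_features(sample: VOISample, ng: int = 32) -> dict[str, float]:
    """Mean, SD, skewness, kurtosis and entropy of the VOI histogram.

    SD is the sample standard deviation (ddof=1, 0 for a single voxel);
    skewness is the standardized third central moment and kurtosis the raw
    m4/m2² (no excess-3 subtraction); entropy is −Σ q·log2 q over the
    ``ng``-bin histogram used by the quantizer.
    """
    if sample.voxel_count == 0:
        raise EmptyVOIError("empty VOI sample")
    v = np.asarray(sample.values, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    m2 = float(((v - mean) ** 2).mean())
    if m2 > 0:
        skew = float(((v - mean) ** 3).mean()) / m2**1.5
        kurt = float(((v - mean) ** 4).mean()) / m2**2
    else:
        skew = 0.0
        kurt = 0.0
    levels = quantize(sample, ng).levels
    q = np.bincount(levels, minlength=ng + 1)[1:] / v.size
    nz = q[q > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    return {
        "histogram_mean": mean,
        "histogram_sd": sd,
        "histogram_skewness": skew,
        "histogram_kurtosis": kurt,
        "histogram_entropy": entropy,
    }


# ---------------------------------------------------------------------------
# GLCM


@dataclass(frozen=True)
class GLCMatrix:
    """Symmetric, normalized grey-level co-occurrence matrix."""

    p: np.ndarray
    n_pairs: int
    ng: int

    @property
    def p_x(self) -> np.ndarray:
        return self.p.sum(axis=1)

    @property
    def p_y(self) -> np.ndarray:
        return self.p.sum(axis=0)

    @property
    def p_sum(self) -> np.ndarray:
        """p_{x+y}(k) for k = 2..2Ng (index 0 ↔ k=2)."""
        i = np.arange(1, self.ng + 1)
        k = i[:, None] + i[None, :]
        return np.bincount((k - 2).ravel(), weights=self.p.ravel(), minlength=2 * self.ng - 1)

    @property
    def p_diff(self) -> np.ndarray:
        """p_{x−y}(k) for k = 0..Ng−1."""
        i = np.arange(1, self.ng + 1)
        k = np.abs(i[:, None] - i[None, :])
        return np.bincount(k.ravel(), weights=self.p.ravel(), minlength=self.ng)


def _level_grid(q: QuantizedVOI, grid_shape: tuple[int, int, int]) -> np.ndarray:
    grid = np.zeros(grid_shape, dtype=np.int64)
    grid[tuple(q.coords.T)] = q.levels
    return grid


def _shift_views(grid: np.ndarray, offset: tuple[int, int, int]):
    """Views of ``grid`` at each voxel and at voxel+offset, aligned."""
    src, dst = [], []
    for n, d in zip(grid.shape, offset):
        if d >= 0:
            src.append(slice(0, n - d))
            dst.append(slice(d, n))
        else:
            src.append(slice(-d, n))
            dst.append(slice(0, n + d))
    return grid[tuple(src)], grid[tuple(dst)]


def compute_glcm(
    q: QuantizedVOI,
    grid_shape: tuple[int, int, int],
    mode: str = "3d",
    distance: int = 1,
    offsets: tuple[tuple[int, int, int], ...] | None = None,
) -> GLCMatrix:
    """Build the pooled symmetric GLCM over the requested directions.

    For every direction the ordered in-VOI voxel pairs separated by
    ``distance`` × offset are counted, the count matrix is symmetrized by
    adding its transpose, counts are pooled across directions, and the
    pooled matrix is normalized to probabilities.
    """
    if offsets is None:
        offsets = _directions(mode)
    grid = _level_grid(q, grid_shape)
    ng = q.ng
    counts = np.zeros((ng, ng), dtype=np.int64)
    for off in offsets:
        off = tuple(int(d) * int(distance) for d in off)
        if any(abs(d) >= n for d, n in zip(off, grid.shape)):
            continue
        a, b = _shift_views(grid, off)
        valid = (a > 0) & (b > 0)
        if valid.any():
            np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1)
    counts = counts + counts.T
    n_pairs = int(counts.sum())
    if n_pairs == 0:
        raise DegenerateError("no valid voxel pairs (VOI too small for the requested offsets)")
    return GLCMatrix(p=counts / n_pairs, n_pairs=n_pairs, ng=ng)


def glcm_features(m: GLCMatrix) -> dict[str, float]:
    """The sixteen Haralick-type features of a symmetric GLCM."""
    p = m.p
    ng = m.ng
    i = np.arange(1, ng + 1, dtype=float)
    ii = i[:, None]
    jj = i[None, :]
    px = m.p_x
    py = m.p_y
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())

    psum = m.p_sum
    ksum = np.arange(2, 2 * ng + 1, dtype=float)
    pdiff = m.p_diff
    kdiff = np.arange(0, ng, dtype=float)

    def h(prob: np.ndarray) -> float:
        nz = prob[prob > 0]
        return float(-(nz * np.log2(nz)).sum())

    sum_average = float((ksum * psum).sum())
    mu_diff = float((kdiff * pdiff).sum())
    sigma_xy = np.sqrt(var_x * var_y)
    correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / sigma_xy) if sigma_xy > 0 else 0.0

    return {
        "glcm_autocorrelation": float((ii * jj * p).sum()),
        "glcm_cluster_prominence": float(((ii + jj - mu_x - mu_y) ** 4 * p).sum()),
        "glcm_cluster_shade": float(((ii + jj - mu_x - mu_y) ** 3 * p).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * p).sum()),
        "glcm_correlation": correlation,
        "glcm_difference_entropy": h(pdiff),
        "glcm_difference_variance": float(((kdiff - mu_diff) ** 2 * pdiff).sum()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * p).sum()),
        "glcm_energy": float((p**2).sum()),
        "glcm_entropy": h(p.ravel()),
        "glcm_homogeneity_idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_maximum_probability": float(p.max()),
        "glcm_sum_average": sum_average,
        "glcm_sum_entropy": h(psum),
        "glcm_sum_variance": float(((ksum - sum_average) ** 2 * psum).sum()),
        "glcm_variance": float(((ii - mu_x) ** 2 * p).sum()),
    }


# ---------------------------------------------------------------------------
# RLM


@dataclass(frozen=True)
class RunLengthMatrix:
    """Run counts r(i, j): grey level i, run length j, pooled over directions."""

    r: np.ndarray
    n_runs: int
    n_voxels_traversed: int  # Σ over directions of in-VOI voxels on the grid


def compute_rlm(
    q: QuantizedVOI,
    grid_shape: tuple[int, int, int],
    mode: str = "3d",
    offsets: tuple[tuple[int, int, int], ...] | None = None,
) -> RunLengthMatrix:
    """Count maximal equal-level runs of in-VOI voxels along each direction.

    Every maximal collinear chain of in-VOI voxels is decomposed into
    maximal equal-level runs (out-of-VOI voxels break chains); counts are
    pooled over directions.  Per direction, Σ j·r(i,j) equals the number of
    in-VOI voxels.
    """
    if q.levels.size == 0:
        raise EmptyVOIError("empty VOI")
    if offsets is None:
        offsets = _directions(mode)
    grid = _level_grid(q, grid_shape)
    ng = q.ng
    lmax = max(grid_shape)
    r = np.zeros((ng, lmax), dtype=np.int64)
    n_voxels = int((grid > 0).sum())

    for off in offsets:
        off = tuple(int(d) for d in off)
        # same_next[v] = True if v and v+off are both in-VOI with equal level
        same_next = np.zeros(grid.shape, dtype=bool)
        if all(abs(d) < n for d, n in zip(off, grid.shape)):
            a, b = _shift_views(grid, off)
            region = (a > 0) & (a == b)
            src = tuple(
                slice(0, n - d) if d >= 0 else slice(-d, n) for n, d in zip(grid.shape, off)
            )
            same_next[src] = region
        # same_prev[v] = same_next[v - off]
        same_prev = np.zeros(grid.shape, dtype=bool)
        dst = tuple(slice(d, n) if d >= 0 else slice(0, n + d) for n, d in zip(grid.shape, off))
        srcp = tuple(slice(0, n - d) if d >= 0 else slice(-d, n) for n, d in zip(grid.shape, off))
        same_prev[dst] = same_next[srcp]

        starts = np.argwhere((grid > 0) & ~same_prev)
        if starts.size == 0:
            continue
        lengths = np.ones(starts.shape[0], dtype=np.int64)
        cur = starts.copy()
        active = np.arange(starts.shape[0])
        while active.size:
            cont = same_next[tuple(cur[active].T)]
            active = active[cont]
            if active.size == 0:
                break
            cur[active] += np.asarray(off, dtype=np.int64)
            lengths[active] += 1
        levels = grid[tuple(starts.T)]
        np.add.at(r, (levels - 1, lengths - 1), 1)

    n_runs = int(r.sum())
    if n_runs == 0:
        raise EmptyVOIError("no runs found (empty VOI)")
    return RunLengthMatrix(r=r, n_runs=n_runs, n_voxels_traversed=n_voxels * len(offsets))


def rlm_features(m: RunLengthMatrix) -> dict[str, float]:
    """The eleven Galloway-type run-length features (normalized by Nr)."""
    r = m.r.astype(float)
    nr = float(m.n_runs)
    if nr < 1:
        raise DegenerateError("run-length matrix has no runs")
    ng, lmax = r.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, lmax + 1, dtype=float)[None, :]
    return {
        "rlm_sre": float((r / j**2).sum() / nr),
        "rlm_lre": float((r * j**2).sum() / nr),
        "rlm_gln": float((r.sum(axis=1) ** 2).sum() / nr),
        "rlm_rln": float((r.sum(axis=0) ** 2).sum() / nr),
        "rlm_rp": nr / float(m.n_voxels_traversed),
        "rlm_lgre": float((r / i**2).sum() / nr),
        "rlm_hgre": float((r * i**2).sum() / nr),
        "rlm_srlge": float((r / (i**2 * j**2)).sum() / nr),
        "rlm_srhge": float((r * i**2 / j**2).sum() / nr),
        "rlm_lrlge": float((r * j**2 / i**2).sum() / nr),
        "rlm_lrhge": float((r * i**2 * j**2).sum() / nr),
    }


# ---------------------------------------------------------------------------
# the full 32-feature signature


@dataclass(frozen=True)
class FeatureVector:
    """The 32 named radiomic features of one VOI, with provenance."""

    features: dict[str, float]
    phase: str = "unenhanced"
    subject_id: str = ""
    ng: int = 32
    mode: str = "3d"
    distance: int = 1

    def __post_init__(self) -> None:
        if tuple(self.features.keys()) != FEATURE_NAMES:
            raise ParameterError("feature vector must contain exactly the 32 canonical features in order")

    def as_series(self):
        import pandas as pd

        s = pd.Series(self.features, dtype=float)
        s["phase"] = self.phase
        s["subject_id"] = self.subject_id
        return s


def extract_features(volume: CTVolume, mask: VOIMask, config: TextureConfig = TextureConfig()) -> FeatureVector:
    """Compute the full 32-feature signature for one volume/mask pair."""
    sample = extract_voi(volume, mask)
    q = quantize(sample, config.ng)
    feats: dict[str, float] = {}
    feats.update(first_order_features(sample, config.ng))
    feats.update(glcm_features(compute_glcm(q, volume.shape, config.mode, config.distance)))
    feats.update(rlm_features(compute_rlm(q, volume.shape, config.mode)))
    feats = {name: feats[name] for name in FEATURE_NAMES}
    return FeatureVector(
        features=feats,
        phase=volume.phase,
        subject_id=volume.subject_id,
        ng=config.ng,
        mode=config.mode,
        distance=config.distance,
    )
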