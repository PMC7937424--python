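"""Unsupervised lesion classification: standardize → outliers → K-means → PCA.

K-means (k = 2, best of many restarts) runs on the full standardized
feature space; PCA is computed for 2-D visualization only, though a config
switch allows clustering on the first m component scores instead.  Outlier
screening is algorithmic where the reference analysis removed subjects by
inspection: the default rule flags subjects whose distance to their 3rd
nearest neighbour exceeds median + k·1.4826·MAD of those distances, which
stays silent on multi-cluster structure; the simpler distance-from-the-
coordinate-wise-median variant is available as ``method="median"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .errors import DegenerateError, ParameterError, SchemaError
from .texture import FEATURE_NAMES

logger = logging.getLogger(__name__)

MALIGNANT_GROUP = "ACC"


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-wise z-scores (ddof=1) with the scaling used and dropped columns."""

    values: np.ndarray
    feature_names: tuple[str, ...]
    means: np.ndarray
    sds: np.ndarray
    dropped: tuple[str, ...] = ()

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]


def standardize(matrix, feature_names: tuple[str, ...] | None = None) -> StandardizedMatrix:
    """Column-wise z-scoring; constant columns are dropped with a warning."""
    if isinstance(matrix, pd.DataFrame):
        feature_names = tuple(matrix.columns)
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        if feature_names is None:
            feature_names = tuple(f"f{i}" for i in range(X.shape[1]))
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateError("need a 2-D matrix with >= 2 subjects")
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    dropped = tuple(np.asarray(feature_names)[~keep])
    if dropped:
        logger.warning("dropping constant feature columns: %s", dropped)
    if not keep.any():
        raise DegenerateError("all feature columns are constant")
    X = X[:, keep]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    return StandardizedMatrix(
        values=(X - means) / sds,
        feature_names=tuple(np.asarray(feature_names)[keep]),
        means=means,
        sds=sds,
        dropped=dropped,
    )


@dataclass(frozen=True)
class PcaResult:
    """Orthonormal loadings, per-subject scores, and variance fractions
    (non-increasing); component signs fixed so the largest-magnitude loading
    is positive."""

    loadings: np.ndarray  # features x k
    scores: np.ndarray  # subjects x k
    variance_fraction: np.ndarray


def pca(matrix: StandardizedMatrix, k: int = 2) -> PcaResult:
    X = matrix.values
    kmax = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= k <= kmax:
        raise ParameterError(f"k must be in [1, {kmax}], got {k}")
    model = PCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(X)
    loadings = model.components_.T.copy()  # features x k
    for c in range(k):
        imax = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[imax, c] < 0:
            loadings[:, c] *= -1
            scores[:, c] *= -1
    return PcaResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=model.explained_variance_ratio_.copy(),
    )


@dataclass(frozen=True)
class ClusterResult:
    """K-means (k=2) output with cluster→class mapping and detection rates."""

    assignment: np.ndarray  # values in {1, 2} per retained subject
    centers: np.ndarray
    inertia: float
    seed: int
    restarts: int
    subject_ids: tuple[str, ...] = ()
    outliers: tuple[str, ...] = ()
    cluster_to_class: dict[int, str] = field(default_factory=dict)
    detection_rate: dict[str, float] = field(default_factory=dict)
    detection_counts: dict[str, tuple[int, int]] = field(default_factory=dict)


def kmeans_two(matrix: StandardizedMatrix, seed: int = 0, restarts: int = 50) -> ClusterResult:
    """Lloyd K-means with k=2, best of ``restarts`` seeded initializations."""
    X = matrix.values
    if X.shape[0] < 2:
        raise DegenerateError("need at least 2 subjects for k=2")
    km = KMeans(n_clusters=2, n_init=restarts, max_iter=300, algorithm="lloyd", random_state=seed)
    labels = km.fit_predict(X)
    return ClusterResult(
        assignment=labels + 1,
        centers=km.cluster_centers_,
        inertia=float(km.inertia_),
        seed=seed,
        restarts=restarts,
    )


def flag_outliers(
    matrix: StandardizedMatrix,
    k_mad: float = 3.0,
    method: str = "knn",
    n_neighbors: int = 3,
) -> list[int]:
    """Single-pass robust outlier screen; returns row indices.

    ``method="knn"`` (default): distance to the ``n_neighbors``-th nearest
    neighbour, flagged when above median + k_mad·1.4826·MAD and at least
    twice the median (the scale floor keeps the rule silent on the tail of
    a single cluster; calibrated for high-dimensional z-scored feature
    tables).  ``"median"``: Euclidean distance from the coordinate-wise
    median with the plain MAD threshold — simpler, but flags any minority
    cluster once class separation is large.
    """
    X = matrix.values
    n = X.shape[0]
    if n < 4:
        raise ParameterError("need >= 4 subjects to screen for outliers")
    if method == "knn":
        k = min(n_neighbors, n - 1)
        d2 = ((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2)
        d = np.sqrt(np.sort(d2, axis=1)[:, k])  # column 0 is self-distance
    elif method == "median":
        center = np.median(X, axis=0)
        d = np.sqrt(((X - center) ** 2).sum(axis=1))
    else:
        raise ParameterError(f"unknown outlier method {method!r}")
    med = np.median(d)
    mad = np.median(np.abs(d - med))
    threshold = med + k_mad * 1.4826 * mad
    if method == "knn":
        threshold = max(threshold, 2.0 * med)
    return [int(i) for i in np.flatnonzero(d > threshold)]


def detection_rates(assignment: np.ndarray, malignant: np.ndarray) -> tuple[dict, dict, dict]:
    """Majority cluster→class mapping and per-class detection rates.

    Returns (cluster_to_class, rate per class, (correct, total) per class).
    The mapping of the two clusters to {carcinoma, benign} is the one
    maximizing total agreement; swapping cluster ids leaves rates unchanged.
    """
    assignment = np.asarray(assignment)
    malignant = np.asarray(malignant).astype(bool)
    if assignment.shape != malignant.shape:
        raise SchemaError("assignment and labels must align")
    best_map, best_correct = None, -1
    for malignant_cluster in (1, 2):
        correct = int(((assignment == malignant_cluster) == malignant).sum())
        if correct > best_correct:
            best_correct = correct
            best_map = {malignant_cluster: "carcinoma", 3 - malignant_cluster: "benign"}
    malignant_cluster = next(c for c, cls in best_map.items() if cls == "carcinoma")
    rates, counts = {}, {}
    for cls, sel in (("carcinoma", malignant), ("benign", ~malignant)):
        total = int(sel.sum())
        if total == 0:
            logger.warning("class %s absent from retained subjects", cls)
            rates[cls] = float("nan")
            counts[cls] = (0, 0)
            continue
        hit = (assignment[sel] == malignant_cluster) if cls == "carcinoma" else (
            assignment[sel] != malignant_cluster
        )
        counts[cls] = (int(hit.sum()), total)
        rates[cls] = float(hit.sum() / total)
    return best_map, rates, counts


@dataclass(frozen=True)
class ClusterConfig:
    seed: int = 0
    restarts: int = 50
    k_mad: float = 3.0
    outlier_method: str = "knn"
    pca_components: int = 2
    cluster_on_components: int | None = None  # None = full standardized space


@dataclass(frozen=True)
class UnsupervisedResult:
    pca: PcaResult
    clusters: ClusterResult
    standardized: StandardizedMatrix


def run_unsupervised(table: pd.DataFrame, phase: str, config: ClusterConfig = ClusterConfig()) -> UnsupervisedResult:
    """Full unsupervised arm for one phase of a cohort table.

    standardize → flag and remove outliers → re-standardize the retained
    subjects → K-means on the full feature space (or on leading PCA scores
    if configured) → PCA for visualization → detection rates against the
    supplied group labels (carcinoma = ACC).
    """
    for col in ("subject_id", "group", "phase"):
        if col not in table.columns:
            raise SchemaError(f"cohort table missing column {col!r}")
    sub = table[table["phase"] == phase].reset_index(drop=True)
    if len(sub) < 4:
        raise DegenerateError(f"phase {phase!r} has fewer than 4 subjects")
    features = [c for c in FEATURE_NAMES if c in sub.columns]
    if not features:
        raise SchemaError("cohort table contains no feature columns")

    sm_all = standardize(sub[features])
    out_idx = flag_outliers(sm_all, k_mad=config.k_mad, method=config.outlier_method)
    outlier_ids = tuple(sub.loc[out_idx, "subject_id"])
    if out_idx:
        logger.info("phase %s: removing outliers %s", phase, outlier_ids)
    retained = sub.drop(index=out_idx).reset_index(drop=True)

    sm = standardize(retained[features])
    pca_res = pca(sm, k=min(config.pca_components, sm.n_subjects - 1, sm.values.shape[1]))
    if config.cluster_on_components:
        m = config.cluster_on_components
        cl_matrix = StandardizedMatrix(
            values=pca_res.scores[:, :m],
            feature_names=tuple(f"pc{i + 1}" for i in range(m)),
            means=np.zeros(m),
            sds=np.ones(m),
        )
    else:
        cl_matrix = sm
    km = kmeans_two(cl_matrix, seed=config.seed, restarts=config.restarts)
    malignant = (retained["group"] == MALIGNANT_GROUP).to_numpy()
    mapping, rates, counts = detection_rates(km.assignment, malignant)
    clusters = ClusterResult(
        assignment=km.assignment,
        centers=km.centers,
        inertia=km.inertia,
        seed=km.seed,
        restarts=km.restarts,
        subject_ids=tuple(retained["subject_id"]),
        outliers=outlier_ids,
        cluster_to_class=mapping,
        detection_rate=rates,
        detection_counts=counts,
    )
    return UnsupervisedResult(pca=pca_res, clusters=clusters, standardized=sm)
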