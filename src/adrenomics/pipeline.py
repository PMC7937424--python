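"""End-to-end orchestration: simulate → extract → washout → stats → cluster.

Outputs are plain CSV tables and JSON reports, each embedding the SHA-256
hash of the canonical config so a bundle is traceable to its parameters.
No timestamps go into any payload, so two runs with identical config and
seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .clustering import ClusterConfig, run_unsupervised
from .cohort_stats import feature_roc_table
from .densitometry import WashoutResult, classify_washout
from .errors import AdrenomicsError
from .synthetic import CohortSpec, generate_cohort_table, generate_image_cohort
from .texture import TextureConfig, extract_features
from .volume import extract_voi, mean_densitometry

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a pipeline run depends on; serialized into every output."""

    simulate_mode: str = "images"  # "images" (phantoms + extraction) or "table"
    n_per_group: tuple[int, int, int] = (10, 9, 11)
    phantom_shape: tuple[int, int, int] = (32, 32, 12)
    phases: tuple[str, ...] = ("unenhanced", "arterial", "venous")
    ng: int = 32
    mode: str = "3d"
    distance: int = 1
    alpha: float = 0.05
    k_mad: float = 3.0
    outlier_method: str = "knn"
    restarts: int = 50
    seed: int = 0
    separation: float = 4.0
    n_outliers: int = 0

    def __post_init__(self) -> None:
        if self.simulate_mode not in ("images", "table"):
            raise AdrenomicsError(f"simulate_mode must be 'images' or 'table', got {self.simulate_mode!r}")
        TextureConfig(ng=self.ng, mode=self.mode, distance=self.distance)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise AdrenomicsError(f"unknown config keys: {sorted(unknown)}")
        for key in ("n_per_group", "phantom_shape", "phases"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineReport:
    out_dir: str
    config_hash: str
    files: list[str] = field(default_factory=list)
    detection_rates: dict = field(default_factory=dict)
    failed_stage: str | None = None


def _write_csv(df: pd.DataFrame, path: str, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, index=False, lineterminator="\n", float_format="%.10g")


def read_pipeline_csv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _simulate_feature_table(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Return (cohort feature table, washout table or None)."""
    tcfg = TextureConfig(ng=config.ng, mode=config.mode, distance=config.distance)
    if config.simulate_mode == "table":
        spec = CohortSpec(
            n_per_group=config.n_per_group,
            separation=config.separation,
            n_outliers=config.n_outliers,
            phases=config.phases,
            seed=config.seed,
        )
        return generate_cohort_table(spec), None

    cohort = generate_image_cohort(
        n_per_group=config.n_per_group, shape=config.phantom_shape, seed=config.seed
    )
    rows, washout_rows = [], []
    for subject in cohort:
        means = {}
        for phase, volume in subject["volumes"].items():
            means[phase] = mean_densitometry(extract_voi(volume, subject["mask"]))
            if phase in config.phases:
                fv = extract_features(volume, subject["mask"], tcfg)
                row = dict(subject_id=subject["subject_id"], group=subject["group"], phase=phase)
                row.update(fv.features)
                rows.append(row)
        wr = WashoutResult.compute(means["unenhanced"], means["venous"], means["delayed"])
        classification, _ = classify_washout(wr)
        washout_rows.append(
            dict(
                subject_id=subject["subject_id"],
                group=subject["group"],
                hu_unenhanced=wr.hu_unenhanced,
                hu_enhanced=wr.hu_enhanced,
                hu_delayed=wr.hu_delayed,
                absolute_washout=wr.absolute_washout,
                relative_washout=wr.relative_washout,
                flags=";".join(sorted(wr.flags)),
                classification=classification,
            )
        )
    return pd.DataFrame(rows), pd.DataFrame(washout_rows)


def run_pipeline(config: PipelineConfig, out_dir: str) -> PipelineReport:
    """Run the full analysis and write a report bundle under ``out_dir``.

    Stage failures abort with the failing stage named; partial outputs are
    retained and the MANIFEST records the incompleteness.
    """
    os.makedirs(out_dir, exist_ok=True)
    chash = config.config_hash()
    report = PipelineReport(out_dir=out_dir, config_hash=chash)
    manifest = dict(config=dataclasses.asdict(config), config_hash=chash, status="incomplete", files=[])

    def _manifest_flush(stage_failed: str | None = None) -> None:
        manifest["status"] = "complete" if stage_failed is None else f"failed at stage: {stage_failed}"
        with open(os.path.join(out_dir, "MANIFEST.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)

    stage = "simulate"
    try:
        table, washout = _simulate_feature_table(config)

        stage = "extract"
        for phase in config.phases:
            path = os.path.join(out_dir, f"features_{phase}.csv")
            _write_csv(table[table["phase"] == phase], path, chash)
            manifest["files"].append(os.path.basename(path))
        if washout is not None:
            path = os.path.join(out_dir, "washout.csv")
            _write_csv(washout, path, chash)
            manifest["files"].append("washout.csv")

        stage = "stats"
        stats = feature_roc_table(table, alpha=config.alpha)
        _write_csv(stats, os.path.join(out_dir, "stats.csv"), chash)
        manifest["files"].append("stats.csv")

        stage = "cluster"
        ccfg = ClusterConfig(
            seed=config.seed,
            restarts=config.restarts,
            k_mad=config.k_mad,
            outlier_method=config.outlier_method,
        )
        for phase in config.phases:
            res = run_unsupervised(table, phase, ccfg)
            payload = dict(
                config_hash=chash,
                phase=phase,
                seed=res.clusters.seed,
                restarts=res.clusters.restarts,
                assignment={s: int(a) for s, a in zip(res.clusters.subject_ids, res.clusters.assignment)},
                outliers=list(res.clusters.outliers),
                cluster_to_class={str(k): v for k, v in res.clusters.cluster_to_class.items()},
                detection_rate=res.clusters.detection_rate,
                detection_counts={k: list(v) for k, v in res.clusters.detection_counts.items()},
                pca_variance_fraction=[float(v) for v in res.pca.variance_fraction],
            )
            path = os.path.join(out_dir, f"cluster_{phase}.json")
            with open(path, "w") as fh:
                json.dump(payload, fh, indent=2, sort_keys=True)
            manifest["files"].append(os.path.basename(path))
            report.detection_rates[phase] = res.clusters.detection_rate
    except Exception as exc:
        report.failed_stage = stage
        _manifest_flush(stage)
        raise AdrenomicsError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    report.files = list(manifest["files"]) + ["MANIFEST.json"]
    _manifest_flush(None)
    return report


def scatter_plot(result, labels=None, path: str | None = None):
    """Scatter of the first two PCA component scores, colour-coded by cluster."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = result.pca.scores
    assignment = result.clusters.assignment
    vf = result.pca.variance_fraction
    fig, ax = plt.subplots(figsize=(5, 4))
    for cluster, marker in ((1, "o"), (2, "s")):
        sel = assignment == cluster
        ax.scatter(scores[sel, 0], scores[sel, 1], marker=marker, label=f"cluster {cluster}")
    centers = np.array([scores[assignment == c].mean(axis=0) for c in (1, 2)])
    ax.scatter(centers[:, 0], centers[:, 1], c="k", s=120, marker="X", label="centres")
    ax.set_xlabel(f"dim1 ({100 * vf[0]:.1f}% of variance)")
    ax.set_ylabel(f"dim2 ({100 * vf[1]:.1f}% of variance)" if len(vf) > 1 else "dim2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
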