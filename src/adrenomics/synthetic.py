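"""Synthetic phantoms and cohorts for adrenocortical-tumour radiomics.

Two generators:

* :func:`generate_phantom` — a textured ellipsoidal 3-D lesion (one CT
  volume per contrast phase plus its VOI mask).  Within-VOI intensities are
  a spatially correlated Gaussian field (smoothed white noise), moment-
  matched so the unenhanced VOI mean/SD equal the configured targets
  exactly; the carcinoma preset adds low-HU necrosis blobs and high-HU
  calcification specks.  Per-class contrast-phase offsets are derived so
  the class-mean HU trajectory reproduces the reference absolute/relative
  washout percentages (carcinoma 30.0/16.5, adenoma 32.2/23.7,
  incidentaloma 63.3/46.5).
* :func:`generate_cohort_table` — an abstract per-subject feature table
  (32 features per phase) drawn from group-specific diagonal Gaussians,
  with a configurable carcinoma/benign separation and optional injected
  carcinoma outliers, mirroring the reference cohort of 10 carcinomas,
  9 adenomas and 11 surveillance incidentalomas.

One integer seed fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import SpecError
from .texture import FEATURE_NAMES
from .volume import CTVolume, VOIMask

GROUPS = ("ACC", "adenoma", "AI")
CLASS_LABELS = ("carcinoma", "adenoma", "incidentaloma")
_LABEL_TO_GROUP = {"carcinoma": "ACC", "adenoma": "adenoma", "incidentaloma": "AI"}

#: Per-class intensity targets: unenhanced VOI mean/SD (HU) and the
#: absolute/relative washout percentages the phase offsets must reproduce.
CLASS_PRESETS: dict[str, dict] = {
    "carcinoma": dict(
        base_mean=33.4,
        base_sd=4.7,
        texture_correlation_length=1.2,
        necrosis_fraction=0.15,
        necrosis_mean=18.0,
        calcification_fraction=0.02,
        calcification_mean=50.0,
        washout_abs=30.0,
        washout_rel=16.5,
    ),
    "adenoma": dict(
        base_mean=20.2,
        base_sd=9.2,
        texture_correlation_length=3.0,
        necrosis_fraction=0.0,
        necrosis_mean=18.0,
        calcification_fraction=0.0,
        calcification_mean=50.0,
        washout_abs=32.2,
        washout_rel=23.7,
    ),
    "incidentaloma": dict(
        base_mean=2.8,
        base_sd=9.4,
        texture_correlation_length=3.0,
        necrosis_fraction=0.0,
        necrosis_mean=18.0,
        calcification_fraction=0.0,
        calcification_mean=50.0,
        washout_abs=63.3,
        washout_rel=46.5,
    ),
}

BACKGROUND_HU = 40.0  # soft-tissue surround; never inside the VOI


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic lesion; ``seed`` fully determines output."""

    class_label: str = "carcinoma"
    shape: tuple[int, int, int] = (48, 48, 16)
    spacing: tuple[float, float, float] = (0.744, 0.744, 5.0)
    base_mean: float = 33.4
    base_sd: float = 4.7
    texture_correlation_length: float = 2.0
    necrosis_fraction: float = 0.0
    necrosis_mean: float = 18.0
    calcification_fraction: float = 0.0
    calcification_mean: float = 50.0
    phase_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise SpecError(f"class_label must be one of {CLASS_LABELS}, got {self.class_label!r}")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise SpecError(f"shape must be three positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise SpecError(f"spacing must be positive, got {self.spacing}")
        if self.base_sd <= 0:
            raise SpecError("base_sd must be > 0")
        for name in ("necrosis_fraction", "calcification_fraction"):
            f = getattr(self, name)
            if not 0.0 <= f <= 1.0:
                raise SpecError(f"{name} must be in [0, 1], got {f}")
        if self.necrosis_fraction + self.calcification_fraction > 1.0:
            raise SpecError("necrosis_fraction + calcification_fraction must be <= 1")
        if self.texture_correlation_length <= 0:
            raise SpecError("texture_correlation_length must be > 0")

    @classmethod
    def for_class(cls, class_label: str, seed: int = 0, **overrides) -> "PhantomSpec":
        """Preset spec for one lesion class, intensity targets from the
        reference group means/SDs."""
        if class_label not in CLASS_PRESETS:
            raise SpecError(f"unknown class {class_label!r}")
        p = CLASS_PRESETS[class_label]
        base = dict(
            class_label=class_label,
            base_mean=p["base_mean"],
            base_sd=p["base_sd"],
            texture_correlation_length=p["texture_correlation_length"],
            necrosis_fraction=p["necrosis_fraction"],
            necrosis_mean=p["necrosis_mean"],
            calcification_fraction=p["calcification_fraction"],
            calcification_mean=p["calcification_mean"],
            seed=seed,
        )
        base.update(overrides)
        return cls(**base)


def phase_offsets(class_label: str) -> dict[str, float]:
    """Additive HU enhancement per phase, derived from the class's nominal
    unenhanced mean and washout targets.

    With U the nominal unenhanced mean and (abs, rel) the washout targets,
    the venous (enhanced) level is E = U·abs/(abs−rel) and the delayed level
    D = E·(1 − rel/100); the arterial phase sits halfway up the enhancement.
    """
    p = CLASS_PRESETS[class_label]
    u = p["base_mean"]
    wa, wr = p["washout_abs"], p["washout_rel"]
    if wa <= wr:
        raise SpecError("absolute washout target must exceed relative target")
    e_level = u * wa / (wa - wr)
    d_level = e_level * (1.0 - wr / 100.0)
    return {
        "unenhanced": 0.0,
        "arterial": 0.5 * (e_level - u),
        "venous": e_level - u,
        "delayed": d_level - u,
    }


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [max(0.42 * n, 0.5) for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    d2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return d2 <= 1.0


def _correlated_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="nearest")


def generate_phantom(spec: PhantomSpec) -> tuple[dict[str, CTVolume], VOIMask]:
    """Build one synthetic lesion: a volume per phase plus the VOI mask.

    The unenhanced masked sample is affinely moment-matched after
    heterogeneity implantation, so its mean and SD equal ``base_mean`` and
    ``base_sd`` exactly (the reference mean-densitometry semantics are
    whole-VOI statistics).  Contrast phases add the class's enhancement
    offset plus independent white noise of ``phase_noise_sd`` HU.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.shape)
    if not mask.any():
        raise SpecError(f"shape {spec.shape} yields an empty lesion mask")
    n = int(mask.sum())

    z = _correlated_field(rng, spec.shape, spec.texture_correlation_length)[mask]
    z = (z - z.mean()) / z.std() if z.std() > 0 else np.zeros_like(z)
    values = spec.base_mean + spec.base_sd * z

    # heterogeneity: thresholded independent smooth fields give blob-shaped
    # necrosis and speck-like calcifications
    taken = np.zeros(n, dtype=bool)
    if spec.necrosis_fraction > 0 and n >= 2:
        f = _correlated_field(rng, spec.shape, 2.0 * spec.texture_correlation_length)[mask]
        thr = np.quantile(f, 1.0 - spec.necrosis_fraction)
        region = f >= thr
        texture = rng.standard_normal(n)
        values[region] = spec.necrosis_mean + 2.0 * texture[region]
        taken |= region
    if spec.calcification_fraction > 0 and n >= 2:
        f = _correlated_field(rng, spec.shape, 0.8)[mask]
        f[taken] = -np.inf
        thr = np.quantile(f[~taken], 1.0 - spec.calcification_fraction / max(1.0 - spec.necrosis_fraction, 1e-9))
        region = f >= thr
        texture = rng.standard_normal(n)
        values[region] = spec.calcification_mean + 5.0 * texture[region]

    # exact whole-VOI moment match on the unenhanced phase
    sd = values.std()
    if sd > 0:
        values = (values - values.mean()) / sd * spec.base_sd + spec.base_mean
    else:
        values = np.full(n, spec.base_mean)

    offsets = phase_offsets(spec.class_label)
    volumes: dict[str, CTVolume] = {}
    for phase in ("unenhanced", "arterial", "venous", "delayed"):
        grid = np.full(spec.shape, BACKGROUND_HU, dtype=float)
        v = values + offsets[phase]
        if phase != "unenhanced" and spec.phase_noise_sd > 0:
            v = v + spec.phase_noise_sd * rng.standard_normal(n)
        grid[mask] = v
        volumes[phase] = CTVolume(
            values=grid,
            spacing=spec.spacing,
            phase=phase,
            subject_id=f"{spec.class_label}-{spec.seed}",
        )
    return volumes, VOIMask(mask=mask, spacing=spec.spacing)


def generate_image_cohort(
    n_per_group: tuple[int, int, int] = (10, 9, 11),
    shape: tuple[int, int, int] = (48, 48, 16),
    seed: int = 0,
) -> list[dict]:
    """A cohort of phantom lesions mirroring the reference study groups.

    Subject-level unenhanced means are drawn from the class mean/SD (the
    between-patient spread), while each phantom keeps its class's within-VOI
    texture SD.  Returns one record per subject with the phase volumes,
    the mask, and the group label.
    """
    rng = np.random.default_rng(seed)
    cohort = []
    for label, n in zip(CLASS_LABELS, n_per_group):
        preset = CLASS_PRESETS[label]
        for k in range(int(n)):
            subject_mean = float(rng.normal(preset["base_mean"], preset["base_sd"]))
            sub_seed = int(rng.integers(0, 2**31 - 1))
            spec = PhantomSpec.for_class(label, seed=sub_seed, shape=shape, base_mean=subject_mean)
            volumes, mask = generate_phantom(spec)
            cohort.append(
                dict(
                    subject_id=f"{_LABEL_TO_GROUP[label]}{k + 1:02d}",
                    group=_LABEL_TO_GROUP[label],
                    class_label=label,
                    volumes=volumes,
                    mask=mask,
                    spec=spec,
                )
            )
    return cohort


# ---------------------------------------------------------------------------
# abstract cohort feature tables


def _default_feature_means() -> np.ndarray:
    # varied scales across the 32 features; fixed constants, not seed-dependent
    return np.linspace(-2.0, 30.0, len(FEATURE_NAMES))


def _default_feature_sds() -> np.ndarray:
    return np.geomspace(0.5, 20.0, len(FEATURE_NAMES))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic per-subject feature table.

    ``separation`` is the Euclidean norm, in pooled within-group SD units,
    of the carcinoma-vs-benign mean shift, spread equally over the 32
    features.  ``n_outliers`` carcinomas are displaced by ``outlier_shift``
    within-group SDs per feature with random signs (far from every
    centroid), emulating outlying heavily calcified carcinomas.
    """

    n_per_group: tuple[int, int, int] = (10, 9, 11)  # (ACC, adenoma, AI)
    separation: float = 4.0
    n_outliers: int = 0
    outlier_shift: float = 12.0
    phases: tuple[str, ...] = ("unenhanced", "arterial", "venous")
    feature_means: np.ndarray | None = None
    feature_sds: np.ndarray | None = None
    clinical: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_group) != 3 or any(int(n) < 2 for n in self.n_per_group):
            raise SpecError(f"each group needs n >= 2, got {self.n_per_group}")
        if self.separation < 0:
            raise SpecError("separation must be >= 0")
        if not 0 <= self.n_outliers <= self.n_per_group[0]:
            raise SpecError("n_outliers must be between 0 and the carcinoma group size")
        means = self.feature_means if self.feature_means is not None else _default_feature_means()
        sds = self.feature_sds if self.feature_sds is not None else _default_feature_sds()
        means = np.asarray(means, dtype=float)
        sds = np.asarray(sds, dtype=float)
        if means.shape != (len(FEATURE_NAMES),) or sds.shape != (len(FEATURE_NAMES),):
            raise SpecError(f"feature_means/feature_sds must have length {len(FEATURE_NAMES)}")
        if np.any(sds <= 0):
            raise SpecError("feature SDs must be > 0")
        object.__setattr__(self, "feature_means", means)
        object.__setattr__(self, "feature_sds", sds)


_CLINICAL = {  # mean, sd of age (years) and axial diameter (mm); M:F counts
    "ACC": dict(age=(53.5, 14.4), diameter=(62.3, 35.2), sex=(4, 6)),
    "adenoma": dict(age=(66.2, 6.4), diameter=(56.6, 42.4), sex=(4, 5)),
    "AI": dict(age=(71.4, 9.4), diameter=(25.9, 1.4), sex=(5, 6)),
}


def generate_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Draw a per-subject, per-phase 32-feature table with group structure.

    Benign groups (adenoma, AI) share the baseline feature means; the ACC
    group mean is shifted by ``separation`` pooled SDs (Euclidean norm,
    equal per-feature allocation).  Returns a tidy DataFrame with one row
    per (subject, phase), columns: subject_id, group, phase, is_outlier,
    the 32 features, and optional clinical fields.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(FEATURE_NAMES)
    delta = spec.separation / np.sqrt(p) * spec.feature_sds  # per-feature ACC shift

    rows = []
    n_acc = int(spec.n_per_group[0])
    outlier_ids = {n_acc - 1 - k for k in range(spec.n_outliers)}  # last ACC subjects
    for group, n in zip(GROUPS, spec.n_per_group):
        mean = spec.feature_means + (delta if group == "ACC" else 0.0)
        clin = _CLINICAL[group]
        for k in range(int(n)):
            subject_id = f"{group}{k + 1:02d}"
            is_outlier = group == "ACC" and k in outlier_ids
            if is_outlier:
                signs = rng.choice([-1.0, 1.0], size=p)
                center = spec.feature_means + signs * spec.outlier_shift * spec.feature_sds
            else:
                center = mean
            clinical = {}
            if spec.clinical:
                m_count, f_count = clin["sex"]
                clinical = dict(
                    age=float(np.clip(rng.normal(*clin["age"]), 18, 95)),
                    sex="M" if rng.random() < m_count / (m_count + f_count) else "F",
                    side=rng.choice(["right", "left"]),
                    diameter_mm=float(np.clip(rng.normal(*clin["diameter"]), 5.0, None)),
                )
            for phase in spec.phases:
                feats = center + spec.feature_sds * rng.standard_normal(p)
                row = dict(subject_id=subject_id, group=group, phase=phase, is_outlier=is_outlier)
                row.update(zip(FEATURE_NAMES, feats))
                row.update(clinical)
                rows.append(row)
    return pd.DataFrame(rows)


def null_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """A cohort with no class structure (separation 0), for calibration."""
    return replace(CohortSpec(seed=seed), separation=0.0, clinical=False, **overrides)
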