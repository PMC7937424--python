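"""Univariate cohort statistics: t tests, χ², feature selection, ROC/Youden.

Group comparisons use the pooled-variance Student's t test by default
(Welch available behind a flag) and the Pearson χ² without continuity
correction, matching how the reference summary table's P values were
produced.  Feature selection keeps features whose carcinoma-vs-benign
two-sample t test gives P < α, with no multiplicity adjustment by default
(Benjamini–Hochberg available but off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateError, SchemaError
from .texture import FEATURE_NAMES

MALIGNANT_GROUP = "ACC"


@dataclass(frozen=True)
class GroupSummary:
    """Printed-style group summary: mean(s.d.) and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise DegenerateError(f"group summary needs n >= 2, got n={self.n}")
        if self.sd < 0:
            raise DegenerateError("sd must be >= 0")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def two_sample_t(x, y, pooled: bool = True) -> TTestResult:
    """Two-sided two-sample t test on raw samples (pooled variance by default)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DegenerateError("each sample needs n >= 2")
    if pooled:
        sp2 = ((x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)) / (x.size + y.size - 2)
        if sp2 == 0:
            raise DegenerateError("zero pooled variance")
        res = sps.ttest_ind(x, y, equal_var=True)
        df = x.size + y.size - 2
    else:
        res = sps.ttest_ind(x, y, equal_var=False)
        df = float(res.df)
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def t_from_summary(a: GroupSummary, b: GroupSummary, pooled: bool = True) -> TTestResult:
    """t test from printed mean(s.d.)/n summaries; algebraically identical to
    :func:`two_sample_t` on any raw samples with those summaries."""
    if pooled and a.sd == 0 and b.sd == 0:
        raise DegenerateError("zero pooled variance")
    res = sps.ttest_ind_from_stats(a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=pooled)
    if pooled:
        df = a.n + b.n - 2
    else:  # Welch–Satterthwaite
        va, vb = a.sd**2 / a.n, b.sd**2 / b.n
        df = (va + vb) ** 2 / (va**2 / (a.n - 1) + vb**2 / (b.n - 1))
    return TTestResult(t=float(res.statistic), df=float(df), p=float(res.pvalue))


def chi_square_2x2(table, correction: bool = False) -> tuple[float, float]:
    """Pearson χ² on a 2×2 count table (no continuity correction by default)."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2) or np.any(table < 0):
        raise DegenerateError("need a 2x2 table of non-negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise DegenerateError("zero margin in 2x2 table")
    stat, p, _, _ = sps.chi2_contingency(table, correction=correction)
    return float(stat), float(p)


def _feature_matrix(table: pd.DataFrame, phase: str) -> tuple[np.ndarray, np.ndarray]:
    missing = [c for c in FEATURE_NAMES if c not in table.columns]
    if missing:
        raise SchemaError(f"cohort table missing feature columns: {missing[:3]}...")
    for col in ("group", "phase"):
        if col not in table.columns:
            raise SchemaError(f"cohort table missing column {col!r}")
    sub = table[table["phase"] == phase]
    X = sub.loc[sub["group"] == MALIGNANT_GROUP, list(FEATURE_NAMES)].to_numpy(dtype=float)
    Y = sub.loc[sub["group"] != MALIGNANT_GROUP, list(FEATURE_NAMES)].to_numpy(dtype=float)
    return X, Y


def select_features(
    table: pd.DataFrame,
    alpha: float = 0.05,
    comparator: str = "pooled",
    adjust: str | None = None,
) -> pd.DataFrame:
    """Features separating carcinoma from the pooled benign groups at P < α.

    ``comparator="pooled"`` (default) tests ACC vs adenoma∪AI per phase;
    ``"pairwise"`` requires P < α against each benign group separately.
    ``adjust="bh"`` applies Benjamini–Hochberg within each phase (off by
    default — the reference analysis applied none).
    Returns a tidy DataFrame (feature, phase, t, p) of the selected rows.
    """
    out = []
    for phase in pd.unique(table["phase"]) if "phase" in table.columns else []:
        sub = table[table["phase"] == phase]
        if comparator == "pooled":
            X, Y = _feature_matrix(table, phase)
            if len(X) < 2 or len(Y) < 2:
                raise DegenerateError("need >= 2 subjects per side")
            res = sps.ttest_ind(X, Y, axis=0, equal_var=True)
            tvals, pvals = np.asarray(res.statistic), np.asarray(res.pvalue)
        elif comparator == "pairwise":
            acc = sub[sub["group"] == MALIGNANT_GROUP]
            pvals = np.zeros(len(FEATURE_NAMES))
            tvals = np.zeros(len(FEATURE_NAMES))
            for other in ("adenoma", "AI"):
                oth = sub[sub["group"] == other]
                res = sps.ttest_ind(
                    acc[list(FEATURE_NAMES)].to_numpy(float),
                    oth[list(FEATURE_NAMES)].to_numpy(float),
                    axis=0,
                    equal_var=True,
                )
                pvals = np.maximum(pvals, np.asarray(res.pvalue))
                tvals = np.asarray(res.statistic)
        else:
            raise DegenerateError(f"unknown comparator {comparator!r}")
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        if adjust == "bh":
            pvals = _benjamini_hochberg(pvals)
        for name, t, p in zip(FEATURE_NAMES, tvals, pvals):
            if p < alpha:
                out.append(dict(feature=name, phase=phase, t=float(t), p=float(p)))
    return pd.DataFrame(out, columns=["feature", "phase", "t", "p"])


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    m = p.size
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(ranked, 1.0)
    return out


@dataclass(frozen=True)
class RocResult:
    """Empirical ROC with the Youden-optimal operating point.

    ``thresholds`` are midpoints between adjacent distinct scores (ascending);
    ``positive_direction`` records whether the positive class lies above
    (">") or below ("<") the cut-off, chosen so AUC >= 0.5.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_sensitivity: float
    youden_specificity: float
    positive_direction: str = ">"


def roc_with_youden(scores, labels) -> RocResult:
    """Empirical ROC over all distinct thresholds, with Youden's optimum.

    AUC is the trapezoidal area (equal to the Mann–Whitney probability with
    ½ credit for ties).  The Youden cut-off is the midpoint between the
    adjacent distinct scores bracketing the maximizing threshold; ties on J
    break toward the lowest cut-off.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateError("both classes must be present for a ROC curve")

    # orientation: pick the direction giving AUC >= 0.5 (rank shortcut)
    ranks = sps.rankdata(scores)
    auc_mw = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    direction = ">"
    s = scores
    if auc_mw < 0.5:
        direction = "<"
        s = -scores

    distinct = np.unique(s)
    if distinct.size == 1:
        thresholds = np.array([distinct[0]])
        sens = np.array([0.0])
        spec = np.array([1.0])
        j_best = 0
    else:
        thresholds = (distinct[:-1] + distinct[1:]) / 2.0
        pos = s[labels]
        neg = s[~labels]
        sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
        spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
        j = sens + spec - 1.0
        j_max = j.max()
        tied = np.flatnonzero(j >= j_max - 1e-12)
        # lowest cut-off in *original* units among J-ties
        j_best = int(tied[0]) if direction == ">" else int(tied[-1])

    # trapezoidal area under the empirical step curve, endpoints included
    fpr = np.concatenate(([0.0], (1.0 - spec)[::-1], [1.0]))
    tpr = np.concatenate(([0.0], sens[::-1], [1.0]))
    auc = float(np.trapezoid(tpr, fpr))

    cutoff = thresholds[j_best]
    out_thresholds = thresholds if direction == ">" else -thresholds[::-1]
    out_sens = sens if direction == ">" else sens[::-1]
    out_spec = spec if direction == ">" else spec[::-1]
    return RocResult(
        thresholds=out_thresholds,
        sensitivity=out_sens,
        specificity=out_spec,
        auc=float(auc),
        youden_cutoff=float(cutoff if direction == ">" else -cutoff),
        youden_sensitivity=float(sens[j_best]),
        youden_specificity=float(spec[j_best]),
        positive_direction=direction,
    )


def feature_roc_table(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Per-feature, per-phase summary: group means, t, p, AUC, Youden point.

    One row per (phase, feature); ``selected`` marks P < α.  The ROC treats
    carcinoma as the positive class.
    """
    rows = []
    for phase in pd.unique(table["phase"]):
        sub = table[table["phase"] == phase]
        labels = (sub["group"] == MALIGNANT_GROUP).to_numpy()
        X, Y = _feature_matrix(table, phase)
        res = sps.ttest_ind(X, Y, axis=0, equal_var=True)
        for idx, name in enumerate(FEATURE_NAMES):
            scores = sub[name].to_numpy(float)
            p = float(res.pvalue[idx]) if np.isfinite(res.pvalue[idx]) else 1.0
            roc = roc_with_youden(scores, labels)
            rows.append(
                dict(
                    phase=phase,
                    feature=name,
                    mean_acc=float(X[:, idx].mean()),
                    mean_benign=float(Y[:, idx].mean()),
                    t=float(res.statistic[idx]),
                    p=p,
                    selected=p < alpha,
                    auc=roc.auc,
                    youden_cutoff=roc.youden_cutoff,
                    youden_sensitivity=roc.youden_sensitivity,
                    youden_specificity=roc.youden_specificity,
                    positive_direction=roc.positive_direction,
                )
            )
    return pd.DataFrame(rows)
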