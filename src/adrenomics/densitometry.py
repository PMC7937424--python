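"""Conventional adrenal CT densitometry: phase means and washout.

Absolute washout = 100·(enhanced − delayed)/(enhanced − unenhanced)
Relative washout = 100·(enhanced − delayed)/enhanced

"Enhanced" and "delayed" are caller-designated phases; the formulas are the
standard adrenal-washout definitions.  The benign decision rule uses the
conventional strict thresholds: unenhanced attenuation < 10 HU (lipid-rich),
absolute washout > 60% and relative washout > 40%.  Lesion size ≥ 40 mm is
reported as an advisory flag only and never changes the class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import UndefinedWashoutError

LIPID_RICH_HU = 10.0
ABSOLUTE_WASHOUT_PCT = 60.0
RELATIVE_WASHOUT_PCT = 40.0
SIZE_ADVISORY_MM = 40.0

_EPS = 1e-12


def absolute_washout(hu_enhanced: float, hu_delayed: float, hu_unenhanced: float) -> float:
    """Percentage of enhancement lost between the enhanced and delayed phases."""
    denom = hu_enhanced - hu_unenhanced
    if abs(denom) < _EPS:
        raise UndefinedWashoutError("enhanced and unenhanced HU are equal; absolute washout undefined")
    return 100.0 * (hu_enhanced - hu_delayed) / denom


def relative_washout(hu_enhanced: float, hu_delayed: float) -> float:
    """De-enhancement as a percentage of the enhanced-phase attenuation."""
    if abs(hu_enhanced) < _EPS:
        raise UndefinedWashoutError("enhanced HU is zero; relative washout undefined")
    return 100.0 * (hu_enhanced - hu_delayed) / hu_enhanced


@dataclass(frozen=True)
class WashoutResult:
    """Washout summary for one lesion; flags are pure functions of the HUs."""

    hu_unenhanced: float
    hu_enhanced: float
    hu_delayed: float
    absolute_washout: float
    relative_washout: float
    flags: frozenset[str] = field(default_factory=frozenset)

    @classmethod
    def compute(cls, hu_unenhanced: float, hu_enhanced: float, hu_delayed: float) -> "WashoutResult":
        aw = absolute_washout(hu_enhanced, hu_delayed, hu_unenhanced)
        rw = relative_washout(hu_enhanced, hu_delayed)
        flags = set()
        if hu_unenhanced < LIPID_RICH_HU:
            flags.add("lipid_rich")
        if aw > ABSOLUTE_WASHOUT_PCT:
            flags.add("high_absolute_washout")
        if rw > RELATIVE_WASHOUT_PCT:
            flags.add("high_relative_washout")
        return cls(
            hu_unenhanced=float(hu_unenhanced),
            hu_enhanced=float(hu_enhanced),
            hu_delayed=float(hu_delayed),
            absolute_washout=aw,
            relative_washout=rw,
            flags=frozenset(flags),
        )


def classify_washout(result: WashoutResult, size_mm: float | None = None) -> tuple[str, frozenset[str]]:
    """Apply the conventional benign/indeterminate rule.

    benign_pattern iff unenhanced < 10 HU, or absolute washout > 60% and
    relative washout > 40%.  Returns (classification, advisory flags);
    size ≥ 40 mm adds a ``large_size`` advisory without changing the class.
    """
    benign = ("lipid_rich" in result.flags) or (
        "high_absolute_washout" in result.flags and "high_relative_washout" in result.flags
    )
    advisories = set()
    if size_mm is not None and size_mm >= SIZE_ADVISORY_MM:
        advisories.add("large_size")
    return ("benign_pattern" if benign else "indeterminate", frozenset(advisories))
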