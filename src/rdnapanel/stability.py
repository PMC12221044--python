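"""Copy-number stability across propagation phases.

Given per-line haploid rDNA copy-number estimates at two sequencing phases
(before and after 20 generations of bulk propagation), this module tests
whether copy numbers drifted, reverted toward the opposite parental allele,
or stayed within their starting class, and computes the simple expectations
implied by a per-cell-division loss rate.

The drift arithmetic treats the published loss rate (about one copy lost per
67-120 cell divisions) as acting over ``divisions_per_generation`` cell
divisions per organismal generation, so the expected loss over an experiment
is ``loss_rate * divisions_per_generation * generations``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DriftParams",
    "PanelTimepoints",
    "DeltaSummary",
    "ReversionReport",
    "compute_copy_deltas",
    "test_reversion",
    "expected_drift_loss",
    "genome_burden",
    "fold_difference",
]


@dataclass(frozen=True)
class DriftParams:
    """Rates of rDNA copy gain/loss per cell division.

    Parameters
    ----------
    loss_rate : float
        Expected copies lost per cell division (e.g. 1/120).
    gain_rate : float
        Expected copies gained per cell division. Default 0: the published
        rate is a net-loss estimate.
    divisions_per_generation : int
        Germline cell divisions per organismal generation (default 15).
    generations : int
        Organismal generations the rate acts over.
    """

    loss_rate: float
    gain_rate: float = 0.0
    divisions_per_generation: int = 15
    generations: int = 20

    def __post_init__(self) -> None:
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("drift rates must be nonnegative")
        if self.divisions_per_generation < 0 or self.generations < 0:
            raise ValueError("division/generation counts must be nonnegative")

    @property
    def total_divisions(self) -> int:
        return self.divisions_per_generation * self.generations


@dataclass
class PanelTimepoints:
    """Per-line copy-number estimates at two phases with fixed class labels.

    ``table`` columns: line, phase1, phase3, allele_class (LOW/HIGH).
    Classes are assigned from the phase-1 estimates and never re-derived
    from phase 3; the reversion question is precisely whether phase-3
    values escape the phase-1 class.
    """

    table: pd.DataFrame

    REQUIRED = ("line", "phase1", "phase3", "allele_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"PanelTimepoints missing columns: {missing}")
        if self.table["line"].duplicated().any():
            raise ValueError("duplicate line ids in PanelTimepoints")

    @classmethod
    def from_estimates(cls, lines, phase1, phase3, allele_class) -> "PanelTimepoints":
        return cls(
            pd.DataFrame(
                {
                    "line": list(lines),
                    "phase1": np.asarray(phase1, dtype=float),
                    "phase3": np.asarray(phase3, dtype=float),
                    "allele_class": list(allele_class),
                }
            )
        )

    def classes(self) -> list[str]:
        return sorted(self.table["allele_class"].unique())


@dataclass
class DeltaSummary:
    """Per-class phase3 - phase1 deltas with a Shapiro-Wilk normality check."""

    deltas: dict[str, np.ndarray]
    summary: pd.DataFrame  # class, n, mean, sd, shapiro_p, normality_defined

    def delta_for(self, allele_class: str) -> np.ndarray:
        return self.deltas[allele_class]


def compute_copy_deltas(pt: PanelTimepoints, min_lines: int = 3) -> DeltaSummary:
    """Per-class copy-number change between phases.

    A class whose deltas are all identical has an undefined Shapiro-Wilk
    statistic; it is reported with ``normality_defined=False`` and a NaN
    p-value rather than raising.
    """
    deltas: dict[str, np.ndarray] = {}
    rows = []
    for cls_label, grp in pt.table.groupby("allele_class"):
        d = (grp["phase3"] - grp["phase1"]).to_numpy(dtype=float)
        if d.size < min_lines:
            raise ValueError(
                f"class {cls_label!r} has {d.size} lines; need >= {min_lines}"
            )
        deltas[cls_label] = d
        if np.ptp(d) == 0.0:
            p, defined = np.nan, False
        else:
            p, defined = float(stats.shapiro(d).pvalue), True
        rows.append(
            {
                "allele_class": cls_label,
                "n": d.size,
                "mean": float(np.mean(d)),
                "sd": float(np.std(d, ddof=1)),
                "shapiro_p": p,
                "normality_defined": defined,
            }
        )
    return DeltaSummary(deltas=deltas, summary=pd.DataFrame(rows))


@dataclass
class ReversionReport:
    flags: pd.DataFrame          # lines violating their class bound at phase 3
    class_ranges: pd.DataFrame   # class, phase, min, max
    bridging: bool               # any line entering the opposite class's range
    n_flagged: int


def test_reversion(
    pt: PanelTimepoints, low_ceiling: float = 200.0, high_floor: float = 300.0
) -> ReversionReport:
    """Flag lines whose phase-3 estimate escapes their starting class.

    A LOW-class line is flagged when its phase-3 estimate exceeds
    ``low_ceiling``; a HIGH-class line when it falls below ``high_floor``.
    ``bridging`` is True if any line's phase-3 value reaches into the
    observed phase-3 range of the opposite class.
    """
    t = pt.table
    flagged = []
    for _, row in t.iterrows():
        if row["allele_class"] == "LOW" and row["phase3"] > low_ceiling:
            flagged.append({**row, "reason": f"LOW line above {low_ceiling}"})
        elif row["allele_class"] == "HIGH" and row["phase3"] < high_floor:
            flagged.append({**row, "reason": f"HIGH line below {high_floor}"})
    flags = pd.DataFrame(flagged, columns=[*t.columns, "reason"])

    ranges = []
    for cls_label, grp in t.groupby("allele_class"):
        for phase in ("phase1", "phase3"):
            ranges.append(
                {
                    "allele_class": cls_label,
                    "phase": phase,
                    "min": float(grp[phase].min()),
                    "max": float(grp[phase].max()),
                }
            )
    class_ranges = pd.DataFrame(ranges)

    bridging = False
    by_class = {c: g for c, g in t.groupby("allele_class")}
    if "LOW" in by_class and "HIGH" in by_class:
        high_min = by_class["HIGH"]["phase3"].min()
        low_max = by_class["LOW"]["phase3"].max()
        bridging = bool(
            (by_class["LOW"]["phase3"] >= high_min).any()
            or (by_class["HIGH"]["phase3"] <= low_max).any()
        )
    return ReversionReport(
        flags=flags, class_ranges=class_ranges, bridging=bridging, n_flagged=len(flags)
    )


def expected_drift_loss(params: DriftParams) -> tuple[float, int]:
    """Expected copies lost over the experiment, and its floored integer.

    Flooring (rather than rounding) reproduces a "2-4 copies" bracket from
    expectations of 2.5 and ~4.48 at the two published rate bounds.
    """
    expected = params.loss_rate * params.divisions_per_generation * params.generations
    return expected, floor(expected)


def genome_burden(
    copies_a: float, copies_b: float, unit_length: int = 7200
) -> tuple[float, float]:
    """DNA-content difference between two array sizes.

    Returns (difference in bp, difference in Mb rounded to one decimal).
    """
    if copies_a < 0 or copies_b < 0:
        raise ValueError("copy numbers must be nonnegative")
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    diff_bp = abs(copies_a - copies_b) * unit_length
    return diff_bp, round(diff_bp / 1e6, 1)


def fold_difference(copies_a: float, copies_b: float) -> float:
    """Fold-range between two copy numbers: max/min."""
    if copies_a <= 0 or copies_b <= 0:
        raise ValueError("copy numbers must be positive for a fold ratio")
    hi, lo = max(copies_a, copies_b), min(copies_a, copies_b)
    return hi / lo
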