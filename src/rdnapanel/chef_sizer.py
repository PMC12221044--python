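"""CHEF (pulsed-field) gel ladder calibration and rDNA array sizing.

A SwaI digest releases the intact rDNA array as a single megabase-scale
fragment, which a CHEF gel separates by size. Sizing works from measured
band migration distances: a ladder of known fragment sizes calibrates a
strictly decreasing distance -> size mapping, and a sample band's size
divided by the 7.2 kb repeat-unit length gives its copy number.

Two calibration modes are provided. The default fits log10(size) as a
linear function of migration distance; migration is close to log-linear
within one switch-time regime. Interpolation mode instead joins the ladder
points piecewise-linearly in (distance, log10 size), which is exact at the
ladder bands and preferable when a run spans regimes where global
log-linearity fails.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ChefLadder",
    "Calibration",
    "BandSizing",
    "calibrate_ladder",
    "band_to_copies",
    "size_bands",
    "YEAST_PFG_SIZES_BP",
    "HANSENULA_PFG_SIZES_BP",
    "SWAI_FLANK_BP",
]

RDNA_UNIT_BP = 7200
#: Distance from the SwaI cut site to the start of the repeat array; the
#: default sizing does not subtract it (pass flank_bp to do so).
SWAI_FLANK_BP = 3927

#: S. cerevisiae chromosome sizes (bp), the ladder used for arrays ~0.2-1.1 Mb.
YEAST_PFG_SIZES_BP = (
    225_000, 285_000, 365_000, 450_000, 565_000, 610_000, 680_000,
    745_000, 785_000, 825_000, 945_000, 1_020_000, 1_100_000, 1_125_000,
)

#: H. wingei chromosome sizes (bp), resolving up to 3.13 Mb for long arrays.
HANSENULA_PFG_SIZES_BP = (1_050_000, 1_370_000, 1_810_000, 2_350_000, 2_700_000, 3_130_000)


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ChefLadder:
    """Known ladder bands as parallel (size bp, migration distance mm) arrays."""

    sizes_bp: np.ndarray
    distances_mm: np.ndarray

    def __post_init__(self) -> None:
        sizes = np.asarray(self.sizes_bp, dtype=float)
        dists = np.asarray(self.distances_mm, dtype=float)
        object.__setattr__(self, "sizes_bp", sizes)
        object.__setattr__(self, "distances_mm", dists)
        if sizes.shape != dists.shape or sizes.ndim != 1:
            raise CalibrationError("ladder sizes and distances must be parallel 1-D arrays")
        if sizes.size < 3:
            raise CalibrationError("ladder needs at least 3 bands")
        order = np.argsort(dists)
        if np.any(np.diff(dists[order]) <= 0):
            raise CalibrationError("ladder migration distances must be distinct")
        if np.any(np.diff(sizes[order]) >= 0):
            raise CalibrationError("ladder must be strictly size-decreasing with distance")

    @classmethod
    def from_log_linear(
        cls, sizes_bp, *, slope_mm_per_log10bp: float = -55.0, intercept_mm: float = 360.0
    ) -> "ChefLadder":
        """Synthetic ladder: place known sizes on an ideal log-linear gel.

        A stand-in for a measured ladder when only band sizes are known;
        distances are generated, not observed.
        """
        sizes = np.asarray(sorted(sizes_bp, reverse=True), dtype=float)
        dists = intercept_mm + slope_mm_per_log10bp * np.log10(sizes)
        return cls(sizes_bp=sizes, distances_mm=dists)

    @classmethod
    def from_csv(cls, path) -> "ChefLadder":
        df = pd.read_csv(path)
        return cls(df["size_bp"].to_numpy(), df["distance_mm"].to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"size_bp": self.sizes_bp, "distance_mm": self.distances_mm}
        ).to_csv(path, index=False)


@dataclass
class Calibration:
    """Fitted strictly decreasing distance (mm) -> size (bp) mapping."""

    ladder: ChefLadder
    mode: str                      # "log-linear" | "interp"
    coef: tuple[float, float] | None   # (intercept, slope) of log10(size) ~ distance
    residuals_log10: np.ndarray    # log10-size residuals at the ladder points

    @property
    def distance_range(self) -> tuple[float, float]:
        d = self.ladder.distances_mm
        return float(d.min()), float(d.max())

    def _log10_size_at(self, distance_mm: np.ndarray) -> np.ndarray:
        d = np.asarray(distance_mm, dtype=float)
        if self.mode == "log-linear":
            a, b = self.coef
            return a + b * d
        order = np.argsort(self.ladder.distances_mm)
        return np.interp(
            d,
            self.ladder.distances_mm[order],
            np.log10(self.ladder.sizes_bp[order]),
        )

    def size_at(self, distance_mm) -> np.ndarray:
        """Fragment size at a migration distance; extrapolates in log-linear mode."""
        return 10.0 ** self._log10_size_at(distance_mm)

    def distance_at(self, size_bp) -> np.ndarray:
        """Inverse mapping, used when simulating gels with the same fit."""
        logs = np.log10(np.asarray(size_bp, dtype=float))
        if self.mode == "log-linear":
            a, b = self.coef
            return (logs - a) / b
        order = np.argsort(self.ladder.sizes_bp)
        return np.interp(
            logs,
            np.log10(self.ladder.sizes_bp[order]),
            self.ladder.distances_mm[order],
        )

    def in_range(self, distance_mm) -> np.ndarray:
        lo, hi = self.distance_range
        d = np.asarray(distance_mm, dtype=float)
        return (d >= lo) & (d <= hi)


def calibrate_ladder(ladder: ChefLadder, mode: str = "log-linear") -> Calibration:
    """Fit the size-vs-distance relationship of a ladder.

    Parameters
    ----------
    ladder : ChefLadder
    mode : {"log-linear", "interp"}
        Least-squares line in (distance, log10 size), or monotone
        piecewise-linear interpolation through the ladder points.
    """
    if mode not in ("log-linear", "interp"):
        raise CalibrationError(f"unknown calibration mode: {mode!r}")
    coef = None
    if mode == "log-linear":
        slope, intercept = np.polyfit(ladder.distances_mm, np.log10(ladder.sizes_bp), 1)
        if slope >= 0:
            raise CalibrationError("fitted size-distance relation is not decreasing")
        coef = (float(intercept), float(slope))
    cal = Calibration(ladder=ladder, mode=mode, coef=coef, residuals_log10=np.zeros(0))
    cal.residuals_log10 = (
        np.log10(ladder.sizes_bp) - cal._log10_size_at(ladder.distances_mm)
    )
    return cal


@dataclass(frozen=True)
class BandSizing:
    distance_mm: float
    size_bp: float
    copies: float
    copies_rounded: int
    extrapolated: bool


def band_to_copies(
    distance_mm: float,
    cal: Calibration,
    unit_length: int = RDNA_UNIT_BP,
    flank_bp: float = 0.0,
) -> BandSizing:
    """Convert one band's migration distance to array size and copy number.

    ``flank_bp`` is subtracted from the fragment size before dividing by the
    unit length (the released fragment carries a short non-repeat flank from
    the SwaI site); the default 0 matches sizing that divides the whole
    fragment by 7.2 kb.
    """
    if unit_length <= 0:
        raise ValueError("unit_length must be positive")
    size = float(cal.size_at(distance_mm))
    extrapolated = not bool(cal.in_range(distance_mm))
    if extrapolated:
        warnings.warn(
            f"distance {distance_mm} mm outside calibrated range "
            f"{cal.distance_range}; sizing is extrapolated",
            stacklevel=2,
        )
    copies = (size - flank_bp) / unit_length
    return BandSizing(
        distance_mm=float(distance_mm),
        size_bp=size,
        copies=copies,
        copies_rounded=int(round(copies)),
        extrapolated=extrapolated,
    )


def size_bands(
    bands: pd.DataFrame,
    cal: Calibration,
    unit_length: int = RDNA_UNIT_BP,
    flank_bp: float = 0.0,
) -> pd.DataFrame:
    """Size a table of measured bands (columns: lane, distance_mm)."""
    rows = []
    for _, rec in bands.iterrows():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            bs = band_to_copies(rec["distance_mm"], cal, unit_length, flank_bp)
        rows.append(
            {
                "lane": rec["lane"],
                "distance_mm": bs.distance_mm,
                "size_bp": bs.size_bp,
                "copies": bs.copies,
                "copies_rounded": bs.copies_rounded,
                "extrapolated": bs.extrapolated,
            }
        )
    return pd.DataFrame(rows)
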