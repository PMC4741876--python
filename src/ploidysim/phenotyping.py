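"""Size and ploidy phenotyping and cohort summaries.

Size classes follow the attached-cell area thresholds: small < 3,000 µm²,
medium 3,000–6,000 µm² (inclusive at both ends, matching the printed interval
notation), giant > 6,000 µm².  Ploidy classes partition C values at 4C and 8C
with the boundary belonging to the lower class (para-diploid ≤ 4C).
Nuclear-size classes reuse the same three-way split with thresholds scaled by
the nuclear/cell area ratio, since absolute nuclear thresholds are not defined.
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd

from .calibration import MARKERS, QUADRANTS, SIZE_CLASSES
from .errors import InputError

SIZE_T1 = 3000.0
SIZE_T2 = 6000.0
PLOIDY_T1 = 4.0
PLOIDY_T2 = 8.0


class SizeClass(str, Enum):
    S = "S"
    M = "M"
    G = "G"


class PloidyClass(str, Enum):
    PARA = "para"
    POLY = "poly"
    HIGHPOLY = "high"


def classify_size(area_um2: float) -> SizeClass:
    """S iff area < 3,000; M iff 3,000 ≤ area ≤ 6,000; G iff area > 6,000."""
    if not area_um2 > 0:
        raise InputError(f"area must be positive, got {area_um2}")
    if area_um2 < SIZE_T1:
        return SizeClass.S
    if area_um2 <= SIZE_T2:
        return SizeClass.M
    return SizeClass.G


def classify_ploidy(dna_content_C: float) -> PloidyClass:
    """PARA iff ≤ 4C; POLY iff 4C < c ≤ 8C; HIGHPOLY iff > 8C."""
    if not dna_content_C > 0:
        raise InputError(f"DNA content must be positive, got {dna_content_C}")
    if dna_content_C <= PLOIDY_T1:
        return PloidyClass.PARA
    if dna_content_C <= PLOIDY_T2:
        return PloidyClass.POLY
    return PloidyClass.HIGHPOLY


def classify_nuclear_size(nuclear_area_um2: float, nuclear_ratio: float = 0.25) -> SizeClass:
    """Nuclear three-way split with thresholds ``nuclear_ratio`` × the cell thresholds."""
    if not nuclear_area_um2 > 0:
        raise InputError(f"nuclear area must be positive, got {nuclear_area_um2}")
    if not nuclear_ratio > 0:
        raise InputError(f"nuclear_ratio must be positive, got {nuclear_ratio}")
    return classify_size(nuclear_area_um2 / nuclear_ratio)


def classify_sizes(areas: np.ndarray | pd.Series, t1: float = SIZE_T1, t2: float = SIZE_T2) -> np.ndarray:
    """Vectorized size classification; returns an array of 'S'/'M'/'G' labels."""
    a = np.asarray(areas, dtype=float)
    if np.any(~(a > 0)):
        raise InputError("all areas must be positive")
    out = np.where(a < t1, "S", np.where(a <= t2, "M", "G"))
    return out


def classify_ploidies(dna: np.ndarray | pd.Series) -> np.ndarray:
    c = np.asarray(dna, dtype=float)
    if np.any(~(c > 0)):
        raise InputError("all DNA contents must be positive")
    return np.where(c <= PLOIDY_T1, "para", np.where(c <= PLOIDY_T2, "poly", "high"))


def summarize(measurements: pd.DataFrame, nuclear_ratio: float = 0.25) -> pd.DataFrame:
    """Per-timepoint summary of a measurement table.

    Returns a tidy frame with columns ``timepoint, statistic, group, value``
    covering size-class fractions, median cell and nuclear area, nuclear-class
    fractions, ploidy-band fractions, marker positivity and — where both p21 and
    BrdU columns exist — per-size-class p21×BrdU quadrant fractions.  Missing
    marker columns are recorded as absent (no rows), not as zero.  The median
    uses the midpoint convention for even counts.
    """
    if measurements.empty:
        raise InputError("cannot summarize an empty measurement table")
    rows: list[tuple[float, str, str, float]] = []
    for tp, grp in measurements.groupby("timepoint", sort=True):
        n = len(grp)
        size_labels = classify_sizes(grp["area_um2"])
        for c in SIZE_CLASSES:
            rows.append((tp, "size_fraction", c, float((size_labels == c).mean())))
        rows.append((tp, "median_area_um2", "all", float(np.median(grp["area_um2"]))))
        if "nuclear_area_um2" in grp.columns and grp["nuclear_area_um2"].notna().all():
            nuc_labels = classify_sizes(grp["nuclear_area_um2"] / nuclear_ratio)
            for c in SIZE_CLASSES:
                rows.append((tp, "nuclear_fraction", c, float((nuc_labels == c).mean())))
            rows.append(
                (tp, "median_nuclear_area_um2", "all", float(np.median(grp["nuclear_area_um2"])))
            )
        if "dna_content_C" in grp.columns:
            bands = classify_ploidies(grp["dna_content_C"])
            for b in ("para", "poly", "high"):
                rows.append((tp, "ploidy_fraction", b, float((bands == b).mean())))
            rows.append((tp, "ploidy_fraction", "gt4C", float((bands != "para").mean())))
        for m in MARKERS:
            if m in grp.columns:
                rows.append((tp, "marker_positive", m, float(grp[m].mean())))
        if "p21" in grp.columns and "BrdU" in grp.columns:
            p21 = grp["p21"].astype(bool).to_numpy()
            brdu = grp["BrdU"].astype(bool).to_numpy()
            quad = {
                "pp": p21 & brdu, "pm": p21 & ~brdu, "mp": ~p21 & brdu, "mm": ~p21 & ~brdu,
            }
            for c in SIZE_CLASSES:
                in_class = size_labels == c
                n_c = int(in_class.sum())
                if n_c == 0:
                    continue
                for q in QUADRANTS:
                    rows.append(
                        (tp, "p21_brdu_quadrant", f"{c}/{q}", float(quad[q][in_class].sum() / n_c))
                    )
    return pd.DataFrame(rows, columns=["timepoint", "statistic", "group", "value"])
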