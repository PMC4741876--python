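"""Synthetic per-cell measurements and 70-hour fate-track tables.

Both generators are pure functions of ``(seed, parameters)``: identical inputs
produce bitwise-identical tables.  Measurement frames carry, besides the public
CSV schema, the latent class labels actually drawn (``size_class_true``,
``nuclear_class_true``, ``dna_band_true``); the CSV writers drop them.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import (
    MARKERS,
    PLOIDY_BANDS,
    QUADRANTS,
    SIZE_CLASSES,
    CalibrationTable,
    TimepointCalibration,
    load_default_calibration,
)
from .errors import ConfigurationError, InputError
from .rates import EPOCHS, TRACK_COLUMNS, ClassEpochRates, RateTable, load_default_rates

#: Public CSV schema of a measurement table.
MEASUREMENT_COLUMNS: tuple[str, ...] = (
    "cell_id", "timepoint", "area_um2", "nuclear_area_um2", "dna_content_C", *MARKERS,
)


def _sample_mixture(
    rng: np.random.Generator,
    n: int,
    weights: dict[str, float],
    keys: tuple[str, ...],
) -> np.ndarray:
    """Class indices (into ``keys``) drawn from ``weights``."""
    p = np.array([weights[k] for k in keys])
    return rng.choice(len(keys), size=n, p=p)


def generate_cell_measurements(
    timepoint: str,
    n: int,
    seed: int,
    calibration: CalibrationTable | None = None,
) -> pd.DataFrame:
    """Draw ``n`` synthetic cells for ``timepoint`` from the calibrated mixtures.

    Areas come from the size-class-weighted log-normal mixture, nuclear areas
    from the nuclear-class mixture scaled by the nuclear/cell ratio, DNA content
    from the three-band C-value mixture, and markers from per-timepoint Bernoulli
    probabilities — except p21/BrdU, which are drawn jointly from the quadrant
    table when one is calibrated.
    """
    if n < 0:
        raise InputError(f"n must be non-negative, got {n}")
    cal = calibration if calibration is not None else load_default_calibration()
    tp = cal.require(timepoint)
    rng = np.random.default_rng(seed)

    size_idx = _sample_mixture(rng, n, tp.size_weights, SIZE_CLASSES)
    area = np.empty(n)
    for i, c in enumerate(SIZE_CLASSES):
        mask = size_idx == i
        area[mask] = tp.area_components[c].sample(rng, int(mask.sum()))

    nuc_idx = _sample_mixture(rng, n, tp.nuclear_weights, SIZE_CLASSES)
    nuclear = np.empty(n)
    for i, c in enumerate(SIZE_CLASSES):
        mask = nuc_idx == i
        comp = tp.area_components[c]
        nuclear[mask] = tp.nuclear_ratio * comp.sample(rng, int(mask.sum()))

    dna_idx = _sample_mixture(rng, n, tp.dna_weights, PLOIDY_BANDS)
    dna = np.empty(n)
    for i, b in enumerate(PLOIDY_BANDS):
        mask = dna_idx == i
        dna[mask] = tp.dna_components[b].sample(rng, int(mask.sum()))

    data: dict[str, np.ndarray | list[str] | float] = {
        "cell_id": [f"{timepoint}_c{i:07d}" for i in range(n)],
        "timepoint": np.full(n, tp.days),
        "area_um2": area,
        "nuclear_area_um2": nuclear,
        "dna_content_C": dna,
    }

    if tp.quadrants is not None:
        q = rng.choice(4, size=n, p=[tp.quadrants[k] for k in QUADRANTS])
        data["p21"] = np.isin(q, [0, 1]).astype(np.int8)   # pp, pm
        data["BrdU"] = np.isin(q, [0, 2]).astype(np.int8)  # pp, mp
    for name in MARKERS:
        if name in data:
            continue
        if name in tp.markers:
            data[name] = (rng.random(n) < tp.markers[name]).astype(np.int8)
    # latent labels, for calibration-fidelity checks; dropped on CSV export
    data["size_class_true"] = np.array(SIZE_CLASSES)[size_idx] if n else np.array([], dtype=str)
    data["nuclear_class_true"] = np.array(SIZE_CLASSES)[nuc_idx] if n else np.array([], dtype=str)
    data["dna_band_true"] = np.array(PLOIDY_BANDS)[dna_idx] if n else np.array([], dtype=str)
    return pd.DataFrame(data)


def write_measurements_csv(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the public measurement schema (booleans as 0/1, latent labels dropped)."""
    cols = [c for c in MEASUREMENT_COLUMNS if c in frame.columns]
    frame[cols].to_csv(path, index=False)


def _draw_fused_pairs(
    rng: np.random.Generator, n_daughters: np.ndarray, p_fusion: float
) -> np.ndarray:
    """Fused sibling pairs per division.

    Daughters pair off after cytokinesis (⌊k/2⌋ pairs).  The pair-level fusion
    probability is scaled by k/(2⌊k/2⌋) so the *per-daughter* marginal equals
    ``p_fusion`` for every daughter count, which makes the downstream estimator
    2·pairs/daughters unbiased.
    """
    pairs = np.zeros(len(n_daughters), dtype=np.int64)
    for k in np.unique(n_daughters):
        mask = n_daughters == k
        n_pairs = int(k) // 2
        if n_pairs == 0:
            continue
        p_pair = min(1.0, p_fusion * int(k) / (2 * n_pairs))
        pairs[mask] = rng.binomial(n_pairs, p_pair, size=int(mask.sum()))
    return pairs


def _sample_division_block(
    rng: np.random.Generator, n_div: int, cer: ClassEpochRates
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_daughters, fused pairs, buds) for ``n_div`` division events."""
    p_multi = cer.p_multi or 0.0
    is_multi = rng.random(n_div) < p_multi
    n_daughters = np.full(n_div, 2, dtype=np.int64)
    n_multi = int(is_multi.sum())
    if n_multi:
        dist = cer.multi_daughter_dist or {3: 2 / 3, 4: 1 / 3}
        ks = np.array(sorted(dist))
        ps = np.array([dist[k] for k in ks])
        n_daughters[is_multi] = rng.choice(ks, size=n_multi, p=ps)
    fused = _draw_fused_pairs(rng, n_daughters, cer.p_fusion_per_daughter or 0.0)
    buds = np.zeros(n_div, dtype=np.int64)
    if n_multi and (cer.bud_rate or 0.0) > 0:
        buds[is_multi] = rng.poisson(cer.bud_rate, size=n_multi)
    return n_daughters, fused, buds


def generate_fate_tracks(
    epoch: str,
    n_per_class: dict[str, int],
    seed: int,
    rates: RateTable | None = None,
) -> pd.DataFrame:
    """Draw per-class 70-hour fate tracks for one epoch from a rate table.

    Outcomes are categorical draws from the epoch's fate probabilities; division
    events split into bipolar vs multi-daughter by ``p_multi``; multi-daughter
    counts follow the {3, 4} distribution; sibling fusion and budding follow the
    per-daughter fusion probability and the bud rate.
    """
    if epoch not in EPOCHS:
        raise ConfigurationError(f"unknown epoch {epoch!r}; expected one of {EPOCHS}")
    rt = rates if rates is not None else load_default_rates()
    rng = np.random.default_rng(seed)
    frames: list[pd.DataFrame] = []
    for sc in SIZE_CLASSES:
        if sc not in n_per_class:
            continue
        n = int(n_per_class[sc])
        if n < 0:
            raise InputError(f"negative track count for class {sc!r}")
        if n == 0:
            continue
        cer = rt.get(sc, epoch)  # raises ConfigurationError when missing
        outcome_idx = rng.choice(3, size=n, p=[cer.p_death, cer.p_divide, cer.p_rest])
        outcome = np.array(["death", "division", "resting"])[outcome_idx]
        n_daughters = np.zeros(n, dtype=np.int64)
        fused = np.zeros(n, dtype=np.int64)
        buds = np.zeros(n, dtype=np.int64)
        div_mask = outcome == "division"
        n_div = int(div_mask.sum())
        if n_div:
            d, f, b = _sample_division_block(rng, n_div, cer)
            n_daughters[div_mask] = d
            fused[div_mask] = f
            buds[div_mask] = b
        frames.append(
            pd.DataFrame(
                {
                    "track_id": [f"{epoch}_{sc}_t{i:06d}" for i in range(n)],
                    "epoch": epoch,
                    "size_class": sc,
                    "outcome": outcome,
                    "n_daughters": n_daughters,
                    "n_fused_daughter_pairs": fused,
                    "n_buds": buds,
                }
            )
        )
    if not frames:
        return pd.DataFrame({c: pd.Series(dtype=object) for c in TRACK_COLUMNS})
    return pd.concat(frames, ignore_index=True)


def write_tracks_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[list(TRACK_COLUMNS)].to_csv(path, index=False)
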