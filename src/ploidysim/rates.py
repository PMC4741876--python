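"""Per-class, per-epoch cell-fate event model.

The unit of observation is a 70-hour time-lapse window.  For each
(size class, epoch) cell a :class:`ClassEpochRates` holds the categorical fate
distribution (death / division / resting), and conditional on division: the
probability of a multi-daughter (depolyploidizing) division, the daughter-count
distribution over {3, 4}, the per-daughter sibling-fusion probability, and the
expected number of budded daughters per depolyploidizing cell.

:func:`estimate_rates` recovers these parameters from a fate-track table with
Clopper–Pearson exact 95% intervals (several cells have few events, so a normal
approximation would be misleading) and reports a chi-squared test of
fate-distribution homogeneity across epochs within each class.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .calibration import SIZE_CLASSES
from .errors import ConfigurationError, EstimationError

EPOCHS: tuple[str, ...] = ("day14", "day30", "day49plus")
OUTCOMES: tuple[str, ...] = ("death", "division", "resting")

#: CSV schema of a fate-track table.
TRACK_COLUMNS: tuple[str, ...] = (
    "track_id", "epoch", "size_class", "outcome",
    "n_daughters", "n_fused_daughter_pairs", "n_buds",
)

_PROB_TOL = 1e-9


def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact binomial confidence interval for k successes in n trials."""
    if n == 0:
        return (0.0, 1.0)
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return (lo, hi)


@dataclass
class ClassEpochRates:
    """Fate parameters for one (size class, epoch) cell; probabilities per 70-h window."""

    p_death: float
    p_divide: float
    p_rest: float
    p_multi: float | None = None
    multi_daughter_dist: dict[int, float] | None = None
    p_fusion_per_daughter: float | None = None
    bud_rate: float | None = None
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_tracks: int | None = None
    source: dict[str, str] = field(default_factory=dict)

    def validate(self, where: str = "") -> None:
        prefix = f"{where}/" if where else ""
        for name in ("p_death", "p_divide", "p_rest"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{prefix}{name} = {v} outside [0, 1]")
        total = self.p_death + self.p_divide + self.p_rest
        if abs(total - 1.0) > _PROB_TOL:
            raise ConfigurationError(
                f"{prefix}fate probabilities sum to {total!r}, not 1"
            )
        for name in ("p_multi", "p_fusion_per_daughter"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{prefix}{name} = {v} outside [0, 1]")
        if self.bud_rate is not None and self.bud_rate < 0:
            raise ConfigurationError(f"{prefix}bud_rate = {self.bud_rate} negative")
        if self.multi_daughter_dist is not None:
            dist = self.multi_daughter_dist
            if any(k < 3 for k in dist):
                raise ConfigurationError(f"{prefix}multi_daughter_dist has counts < 3")
            if any(not (0.0 <= p <= 1.0) for p in dist.values()):
                raise ConfigurationError(f"{prefix}multi_daughter_dist values outside [0, 1]")
            if abs(sum(dist.values()) - 1.0) > _PROB_TOL:
                raise ConfigurationError(f"{prefix}multi_daughter_dist does not sum to 1")

    @property
    def division_defined(self) -> bool:
        return self.p_multi is not None

    def mean_multi_daughters(self) -> float:
        if not self.multi_daughter_dist:
            raise EstimationError("multi-daughter count distribution undefined")
        return sum(k * p for k, p in self.multi_daughter_dist.items())


@dataclass
class RateTable:
    """Rates keyed by (size class, epoch), plus per-class epoch-homogeneity tests."""

    rates: dict[tuple[str, str], ClassEpochRates]
    chi2_homogeneity: dict[str, dict[str, float]] = field(default_factory=dict)

    def get(self, size_class: str, epoch: str) -> ClassEpochRates:
        key = (size_class, epoch)
        if key not in self.rates:
            raise ConfigurationError(
                f"rate table has no entry for class {size_class!r}, epoch {epoch!r}"
            )
        return self.rates[key]

    def validate(self) -> None:
        for (sc, ep), cer in self.rates.items():
            cer.validate(where=f"{sc}/{ep}")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        doc: dict = {"rates": {}, "chi2_homogeneity": self.chi2_homogeneity}
        for (sc, ep), cer in self.rates.items():
            entry = asdict(cer)
            if entry["multi_daughter_dist"] is not None:
                entry["multi_daughter_dist"] = {
                    str(k): v for k, v in entry["multi_daughter_dist"].items()
                }
            doc["rates"].setdefault(sc, {})[ep] = entry
        return doc

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "RateTable":
        rates: dict[tuple[str, str], ClassEpochRates] = {}
        raw = doc["rates"] if "rates" in doc else doc
        for sc, per_epoch in raw.items():
            if sc not in SIZE_CLASSES:
                raise ConfigurationError(f"unknown size class {sc!r} in rate table")
            for ep, entry in per_epoch.items():
                if ep not in EPOCHS:
                    raise ConfigurationError(f"unknown epoch {ep!r} in rate table")
                dist = entry.get("multi_daughter_dist")
                cer = ClassEpochRates(
                    p_death=float(entry["p_death"]),
                    p_divide=float(entry["p_divide"]),
                    p_rest=float(entry["p_rest"]),
                    p_multi=(None if entry.get("p_multi") is None else float(entry["p_multi"])),
                    multi_daughter_dist=(
                        None if dist is None else {int(k): float(v) for k, v in dist.items()}
                    ),
                    p_fusion_per_daughter=(
                        None
                        if entry.get("p_fusion_per_daughter") is None
                        else float(entry["p_fusion_per_daughter"])
                    ),
                    bud_rate=(None if entry.get("bud_rate") is None else float(entry["bud_rate"])),
                    ci={k: tuple(v) for k, v in entry.get("ci", {}).items()},
                    n_tracks=entry.get("n_tracks"),
                    source=dict(entry.get("source", {})),
                )
                cer.validate(where=f"{sc}/{ep}")
                rates[(sc, ep)] = cer
        return cls(rates=rates, chi2_homogeneity=dict(doc.get("chi2_homogeneity", {})))

    @classmethod
    def from_json(cls, path: str | Path) -> "RateTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RateTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_default_rates() -> RateTable:
    """The packaged default rate table (giant-cell anchors plus flagged placeholders)."""
    ref = resources.files("ploidysim.data").joinpath("default_rates.yaml")
    with ref.open() as fh:
        return RateTable.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# estimation


def estimate_rates(
    tracks: pd.DataFrame,
    require: list[tuple[str, str]] | None = None,
) -> RateTable:
    """Estimate a :class:`RateTable` from a fate-track table.

    Probabilities are empirical fractions with Clopper–Pearson exact 95%
    intervals.  The per-daughter fusion probability is estimated as
    ``2 * fused pairs / total daughters`` and the bud rate as
    ``buds / multi-daughter divisions``.  ``require`` lists (class, epoch)
    cells that must be present; an empty required cell raises
    :class:`EstimationError` naming it.
    """
    if tracks.empty:
        raise EstimationError("no fate tracks supplied")
    missing = [c for c in TRACK_COLUMNS if c not in tracks.columns]
    if missing:
        raise EstimationError(f"fate-track table missing columns {missing}")

    present = {
        (sc, ep) for (sc, ep), _ in tracks.groupby(["size_class", "epoch"], sort=False)
    }
    for cell in require or []:
        if cell not in present:
            raise EstimationError(f"no tracks for class {cell[0]!r}, epoch {cell[1]!r}")

    rates: dict[tuple[str, str], ClassEpochRates] = {}
    outcome_counts: dict[str, dict[str, np.ndarray]] = {}
    for (sc, ep), grp in tracks.groupby(["size_class", "epoch"], sort=False):
        n = len(grp)
        n_death = int((grp["outcome"] == "death").sum())
        n_div = int((grp["outcome"] == "division").sum())
        n_rest = int((grp["outcome"] == "resting").sum())
        ci = {
            "p_death": clopper_pearson(n_death, n),
            "p_divide": clopper_pearson(n_div, n),
            "p_rest": clopper_pearson(n_rest, n),
        }
        p_multi = None
        dist = None
        p_fus = None
        bud = None
        if n_div > 0:
            div = grp[grp["outcome"] == "division"]
            is_multi = div["n_daughters"] >= 3
            n_multi = int(is_multi.sum())
            p_multi = n_multi / n_div
            ci["p_multi"] = clopper_pearson(n_multi, n_div)
            if n_multi > 0:
                counts = div.loc[is_multi, "n_daughters"].value_counts()
                dist = {int(k): float(v) / n_multi for k, v in counts.items()}
                bud = float(div.loc[is_multi, "n_buds"].sum()) / n_multi
            total_daughters = int(div["n_daughters"].sum())
            fused = int(div["n_fused_daughter_pairs"].sum())
            if total_daughters > 0:
                p_fus = 2.0 * fused / total_daughters
                ci["p_fusion_per_daughter"] = clopper_pearson(2 * fused, total_daughters)
        rates[(sc, ep)] = ClassEpochRates(
            p_death=n_death / n,
            p_divide=n_div / n,
            p_rest=n_rest / n,
            p_multi=p_multi,
            multi_daughter_dist=dist,
            p_fusion_per_daughter=p_fus,
            bud_rate=bud,
            ci=ci,
            n_tracks=n,
            source={"all": "estimated"},
        )
        outcome_counts.setdefault(sc, {})[ep] = np.array([n_death, n_div, n_rest])

    chi2: dict[str, dict[str, float]] = {}
    for sc, per_epoch in outcome_counts.items():
        if len(per_epoch) < 2:
            continue
        table = np.column_stack([per_epoch[ep] for ep in sorted(per_epoch)])
        table = table[table.sum(axis=1) > 0]  # drop outcomes never observed
        if table.shape[0] < 2:
            continue
        res = stats.chi2_contingency(table)
        chi2[sc] = {"statistic": float(res.statistic), "pvalue": float(res.pvalue), "dof": int(res.dof)}

    return RateTable(rates=rates, chi2_homogeneity=chi2)


def expected_progeny(
    rates: RateTable,
    size_class: str,
    epoch: str,
    mode: str = "depolyploidizing",
) -> float:
    """Expected daughters per cell per 70-h window.

    ``mode="depolyploidizing"`` returns E[daughters | multi-daughter division]
    plus the bud rate — the average total progeny of a depolyploidizing cell.
    ``mode="per_division"`` mixes bipolar (2 daughters) and multi-daughter
    outcomes by ``p_multi``.
    """
    cer = rates.get(size_class, epoch)
    if not cer.division_defined or cer.multi_daughter_dist is None:
        raise EstimationError(
            f"division-conditional fields undefined for class {size_class!r}, epoch {epoch!r}"
        )
    bud = cer.bud_rate or 0.0
    conditional = cer.mean_multi_daughters() + bud
    if mode == "depolyploidizing":
        return conditional
    if mode == "per_division":
        return (1.0 - cer.p_multi) * 2.0 + cer.p_multi * conditional
    raise ValueError(f"unknown mode {mode!r}")


def division_ratio(rates: RateTable, size_class: str, epoch: str) -> float:
    """Bipolar : multi-daughter division ratio, ``(1 - p_multi) / p_multi``.

    Returns ``math.inf`` when no multi-daughter divisions occur.
    """
    cer = rates.get(size_class, epoch)
    if not cer.division_defined:
        raise EstimationError(
            f"p_multi undefined for class {size_class!r}, epoch {epoch!r}"
        )
    if cer.p_multi == 0.0:
        return math.inf
    return (1.0 - cer.p_multi) / cer.p_multi
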