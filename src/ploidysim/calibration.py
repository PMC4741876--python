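"""Calibration tables for the synthetic carboplatin time course.

A :class:`CalibrationTable` holds, per timepoint label (``d0`` … ``21w``), the
parameters from which synthetic per-cell measurements are drawn: size-class
weights and log-normal area components, nuclear-class weights (areas scaled by a
nuclear/cell ratio), a three-band DNA-content mixture (para-diploid ≤4C,
polyploid 4–8C, high-polyploid >8C), per-marker positivity probabilities, and —
where the joint structure matters — p21×BrdU quadrant probabilities.

Where a timepoint carries a ``target_median_um2`` with an ``anchor_class``, the
anchor component's log-normal median is solved in closed form at load time so the
mixture median equals the target exactly: with non-anchor class CDFs
:math:`F_c` fixed, the anchor component must satisfy
:math:`F_a(T) = (1/2 - \\sum_{c \\ne a} w_c F_c(T)) / w_a`, hence
:math:`m_a = T \\exp(-\\Phi^{-1}(q)\\,\\sigma_a)`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .errors import ConfigurationError

SIZE_CLASSES: tuple[str, ...] = ("S", "M", "G")
PLOIDY_BANDS: tuple[str, ...] = ("para", "poly", "high")
MARKERS: tuple[str, ...] = ("p21", "BrdU", "beta_gal", "OCT4", "IL1B", "SMA")
QUADRANTS: tuple[str, ...] = ("pp", "pm", "mp", "mm")  # (p21, BrdU) = (+,+),(+,-),(-,+),(-,-)

#: Closed registry of timepoint labels → days since treatment start.
TIMEPOINT_DAYS: dict[str, float] = {
    "d0": 0.0, "d8": 8.0, "d10": 10.0, "d14": 14.0,
    "d28": 28.0, "d30": 30.0, "w7": 49.0, "21w": 147.0,
}

_WEIGHT_TOL = 1e-9


def _check_weights(name: str, weights: dict[str, float], keys: tuple[str, ...]) -> None:
    if set(weights) != set(keys):
        raise ConfigurationError(f"{name}: expected keys {keys}, got {sorted(weights)}")
    for k, v in weights.items():
        if not (0.0 <= v <= 1.0):
            raise ConfigurationError(f"{name}[{k}] = {v} outside [0, 1]")
    total = sum(weights.values())
    if abs(total - 1.0) > _WEIGHT_TOL:
        raise ConfigurationError(f"{name}: weights sum to {total!r}, not 1")


@dataclass(frozen=True)
class LognormComponent:
    """A log-normal component parameterized by its median and log-scale sigma."""

    median: float
    sigma: float

    def __post_init__(self) -> None:
        if self.median <= 0 or self.sigma <= 0:
            raise ConfigurationError(
                f"log-normal component requires median > 0 and sigma > 0, "
                f"got median={self.median}, sigma={self.sigma}"
            )

    def cdf(self, x: float) -> float:
        return float(norm.cdf((math.log(x) - math.log(self.median)) / self.sigma))

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.median * np.exp(self.sigma * rng.standard_normal(n))


@dataclass
class TimepointCalibration:
    """All generator parameters for one timepoint of the treatment time course."""

    label: str
    days: float
    size_weights: dict[str, float]
    area_components: dict[str, LognormComponent]
    nuclear_weights: dict[str, float]
    nuclear_ratio: float
    dna_weights: dict[str, float]
    dna_components: dict[str, LognormComponent]
    markers: dict[str, float]
    quadrants: dict[str, float] | None = None
    source: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        _check_weights(f"{self.label}.size_weights", self.size_weights, SIZE_CLASSES)
        _check_weights(f"{self.label}.nuclear_weights", self.nuclear_weights, SIZE_CLASSES)
        _check_weights(f"{self.label}.dna_weights", self.dna_weights, PLOIDY_BANDS)
        if self.quadrants is not None:
            _check_weights(f"{self.label}.p21_brdu_quadrants", self.quadrants, QUADRANTS)
        if self.days < 0:
            raise ConfigurationError(f"{self.label}: days must be non-negative")
        if self.nuclear_ratio <= 0:
            raise ConfigurationError(f"{self.label}: nuclear_ratio must be positive")
        for name, p in self.markers.items():
            if name not in MARKERS:
                raise ConfigurationError(f"{self.label}: unknown marker {name!r}")
            if not (0.0 <= p <= 1.0):
                raise ConfigurationError(f"{self.label}.markers[{name}] = {p} outside [0, 1]")

    def marker_probability(self, name: str) -> float:
        """Marginal positivity for ``name``; p21/BrdU marginals come from the quadrants
        when a joint table is present."""
        if self.quadrants is not None:
            if name == "p21":
                return self.quadrants["pp"] + self.quadrants["pm"]
            if name == "BrdU":
                return self.quadrants["pp"] + self.quadrants["mp"]
        if name not in self.markers:
            raise ConfigurationError(f"{self.label}: marker {name!r} not calibrated")
        return self.markers[name]

    def mixture_area_median(self) -> float:
        """Median of the size mixture, solved numerically (used by tests)."""
        from scipy.optimize import brentq

        def f(x: float) -> float:
            return sum(
                self.size_weights[c] * self.area_components[c].cdf(x) for c in SIZE_CLASSES
            ) - 0.5

        return float(brentq(f, 10.0, 1e6))


def solve_anchor_median(
    target: float,
    anchor: str,
    weights: dict[str, float],
    components: dict[str, LognormComponent],
    sigma_anchor: float,
) -> float:
    """Median of the anchor log-normal component such that the class-weighted
    mixture median equals ``target`` with the remaining components held fixed."""
    other = sum(
        weights[c] * components[c].cdf(target) for c in weights if c != anchor
    )
    q = (0.5 - other) / weights[anchor]
    if not (0.0 < q < 1.0):
        raise ConfigurationError(
            f"cannot anchor class {anchor!r} at median {target}: "
            f"required component CDF value {q!r} outside (0, 1)"
        )
    return float(target * math.exp(-norm.ppf(q) * sigma_anchor))


@dataclass
class CalibrationTable:
    """Per-timepoint generator calibrations keyed by the closed label registry."""

    timepoints: dict[str, TimepointCalibration]

    def require(self, label: str) -> TimepointCalibration:
        if label not in self.timepoints:
            raise ConfigurationError(
                f"unknown timepoint label {label!r}; calibrated labels: "
                f"{sorted(self.timepoints)}"
            )
        return self.timepoints[label]

    def __getitem__(self, label: str) -> TimepointCalibration:
        return self.require(label)

    def labels(self) -> list[str]:
        return sorted(self.timepoints, key=lambda k: self.timepoints[k].days)

    @classmethod
    def from_dict(cls, doc: dict) -> "CalibrationTable":
        try:
            defaults = doc.get("defaults", {})
            base_sigmas = dict(defaults.get("class_sigmas", {}))
            base_medians = dict(defaults.get("class_medians_um2", {}))
            nuclear_ratio = float(defaults.get("nuclear_ratio", 0.25))
            dna_defaults = defaults.get("dna_components", {})
            tps: dict[str, TimepointCalibration] = {}
            for label, entry in doc["timepoints"].items():
                if label not in TIMEPOINT_DAYS:
                    raise ConfigurationError(f"unknown timepoint label {label!r}")
                sigmas = {**base_sigmas, **entry.get("class_sigmas", {})}
                medians = {**base_medians, **entry.get("class_medians_um2", {})}
                comps = {
                    c: LognormComponent(medians[c], sigmas[c]) for c in SIZE_CLASSES
                }
                if "target_median_um2" in entry:
                    anchor = entry.get("anchor_class")
                    if anchor not in SIZE_CLASSES:
                        raise ConfigurationError(
                            f"{label}: target_median_um2 requires anchor_class in {SIZE_CLASSES}"
                        )
                    comps[anchor] = LognormComponent(
                        solve_anchor_median(
                            float(entry["target_median_um2"]),
                            anchor,
                            entry["size_weights"],
                            comps,
                            sigmas[anchor],
                        ),
                        sigmas[anchor],
                    )
                dna_entry = {**dna_defaults, **entry.get("dna_components", {})}
                dna_comps = {
                    b: LognormComponent(float(dna_entry[b]["center_C"]), float(dna_entry[b]["sigma"]))
                    for b in PLOIDY_BANDS
                }
                tp = TimepointCalibration(
                    label=label,
                    days=float(entry.get("days", TIMEPOINT_DAYS[label])),
                    size_weights={k: float(v) for k, v in entry["size_weights"].items()},
                    area_components=comps,
                    nuclear_weights={k: float(v) for k, v in entry["nuclear_weights"].items()},
                    nuclear_ratio=float(entry.get("nuclear_ratio", nuclear_ratio)),
                    dna_weights={k: float(v) for k, v in entry["dna_weights"].items()},
                    dna_components=dna_comps,
                    markers={k: float(v) for k, v in entry.get("markers", {}).items()},
                    quadrants=(
                        {k: float(v) for k, v in entry["p21_brdu_quadrants"].items()}
                        if "p21_brdu_quadrants" in entry
                        else None
                    ),
                    source=dict(entry.get("source", {})),
                )
                tp.validate()
                tps[label] = tp
            return cls(timepoints=tps)
        except KeyError as exc:
            raise ConfigurationError(f"calibration document missing field {exc}") from exc

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationTable":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise ConfigurationError(f"{path}: not a mapping document")
        return cls.from_dict(doc)


def load_default_calibration() -> CalibrationTable:
    """The packaged default calibration (every printed measurement plus flagged
    placeholders for the unprinted timepoints)."""
    ref = resources.files("ploidysim.data").joinpath("default_calibration.yaml")
    with ref.open() as fh:
        return CalibrationTable.from_dict(yaml.safe_load(fh))
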