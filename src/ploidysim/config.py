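"""Run configuration: a validated YAML document driving the full pipeline.

Every probability in the referenced calibration and rate documents carries a
``source`` flag (measured / derived / placeholder) so unanchored defaults stay
visible in run manifests.  Inline ``rate_overrides`` are merged onto the rate
table after loading and re-validated, so a bad value fails with the offending
field path (e.g. ``G/day14/p_death``).
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, PrivateAttr, ValidationError

from .calibration import CalibrationTable, load_default_calibration
from .errors import ConfigurationError
from .popsim import WINDOW_DAYS
from .rates import RateTable, load_default_rates

logger = logging.getLogger("ploidysim")

DEFAULT_SEED = 0


class RunConfig(BaseModel):
    """Validated configuration for simulation and contribution runs."""

    calibration: str | None = None   #: path to a calibration YAML; packaged default if None
    rates: str | None = None         #: path to a rate-table YAML/JSON; packaged default if None
    rate_overrides: dict[str, dict[str, dict]] | None = None
    seed: int = DEFAULT_SEED
    replicates: int = Field(default=100, ge=1)
    start_days: float = Field(default=14.0, ge=0.0)
    horizon_days: float = 60.0
    step_days: float = Field(default=WINDOW_DAYS, gt=0.0)
    initial_counts: dict[str, int] = Field(
        default_factory=lambda: {"S": 80, "M": 160, "G": 760}
    )
    outdir: str | None = None
    interpolate: bool = False
    medium_depolyploidization: bool = False
    fusion_enabled: bool = True
    multi_daughter_class: str = "S"

    _base_dir: Path | None = PrivateAttr(default=None)

    model_config = {"extra": "forbid"}

    def _resolve(self, p: str) -> Path:
        path = Path(p)
        if not path.is_absolute() and self._base_dir is not None:
            path = self._base_dir / path
        return path

    def load_calibration(self) -> CalibrationTable:
        if self.calibration is None:
            return load_default_calibration()
        return CalibrationTable.from_yaml(self._resolve(self.calibration))

    def load_rates(self) -> RateTable:
        if self.rates is None:
            table = load_default_rates()
        else:
            path = self._resolve(self.rates)
            if path.suffix == ".json":
                table = RateTable.from_json(path)
            else:
                table = RateTable.from_yaml(path)
        if self.rate_overrides:
            doc = table.to_dict()
            for sc, per_epoch in self.rate_overrides.items():
                for ep, fields in per_epoch.items():
                    doc["rates"].setdefault(sc, {}).setdefault(ep, {}).update(fields)
            table = RateTable.from_dict(doc)  # re-validated; names bad fields
        return table

    def canonical_dict(self) -> dict:
        return self.model_dump(mode="json")


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    A missing ``seed`` is filled with the documented default (0) and logged as a
    warning.  Schema violations raise :class:`ConfigurationError` listing the
    offending field paths.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ConfigurationError(f"{path}: configuration must be a mapping")
    if "seed" not in doc:
        logger.warning("config %s has no seed; using default %d", path, DEFAULT_SEED)
    try:
        cfg = RunConfig(**doc)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigurationError(f"{path}: invalid configuration ({details})") from exc
    cfg._base_dir = path.parent
    # touching the rate table here surfaces bad overrides at load time with field paths
    cfg.load_rates()
    return cfg


def default_config_path() -> Path:
    """Path of the packaged default run configuration."""
    from importlib import resources

    return Path(str(resources.files("ploidysim.data").joinpath("default_config.yaml")))


def default_config() -> RunConfig:
    return RunConfig()
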