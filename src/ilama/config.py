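"""Schema-validated run configuration.

All study constants live in the shipped ``data/paper_defaults.yaml`` fixture,
never hard-coded in command logic.  Unknown keys are rejected and validation
messages name the offending field.
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .mass_action import CellInput, ReceptorProfile, RecoveryFactors
from .simulate import (
    WITH_COMPETITION,
    WITHOUT_COMPETITION,
    SelectionProtocol,
    SelectionRoundParams,
    build_panel,
)
from .classify import ClassifierThresholds, derive_thresholds
from .optimize import OptimizationCriteria, default_criteria
from .synthetic import SyntheticCohortSpec
from . import defaults

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "default_config_path",
    "build_protocol",
    "build_panel_from_config",
    "build_thresholds",
    "build_criteria",
    "build_cohort_spec",
]

log = logging.getLogger("ilama")


class ConfigError(ValueError):
    """Invalid or unreadable configuration."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class RoundConfig(_Model):
    target_cells: float = Field(gt=0)
    nontarget_cells: float = Field(ge=0)
    volume: float = Field(default=defaults.DEFAULT_VOLUME, gt=0)
    elution: float = Field(default=defaults.ELUTION, ge=0, le=1)
    cell_recovery: float = Field(default=defaults.CELL_RECOVERY, ge=0, le=1)
    amplification_into_next: float = Field(default=0.0, ge=0)
    hit_rate: float = Field(ge=0, le=1)  # required: never silently invented
    hit_rate_is_estimate: bool = False


class ProtocolConfig(_Model):
    initial_copies: float = Field(default=defaults.INITIAL_COPIES, gt=0)
    rounds: list[RoundConfig] = Field(min_length=1)


class PanelConfig(_Model):
    min_copies: float = Field(default=defaults.PANEL_MIN_COPIES, gt=0)
    max_copies: float = Field(default=defaults.PANEL_MAX_COPIES, gt=0)
    fold_step: float = Field(default=defaults.PANEL_FOLD_STEP, gt=1)
    include_restricted: bool = True
    upregulation_ratios: list[float] = Field(default=[2.0, 4.0, 10.0])

    @model_validator(mode="after")
    def _check(self) -> "PanelConfig":
        if self.min_copies > self.max_copies:
            raise ValueError("panel min_copies must be <= max_copies")
        if not self.include_restricted and not self.upregulation_ratios:
            raise ValueError("panel category spec is empty")
        return self


class ThresholdsConfig(_Model):
    mode: Literal["constants", "recompute"] = "constants"
    low_threshold_ppm: float = 1.32
    high_threshold_ppm: float = 750.0
    ratio_threshold: float = 100.0
    fallback_round3_ratio: float = 10.0


class CategoryConfig(_Model):
    name: str
    copies_target: float = Field(ge=0)
    copies_nontarget: float = Field(default=0.0, ge=0)


class OptimizerConfig(_Model):
    ct_grid: list[float] = Field(default=[1e5, 1e6, 1e7, 1e8], min_length=1)
    excess_grid: list[float] = Field(default=[0.0, 1.0, 10.0, 100.0, 1000.0, 1e4],
                                     min_length=1)
    capture_floor: float = Field(default=1.0, gt=0)
    kd: float = Field(default=defaults.MEDIAN_KD, gt=0)
    wanted: Optional[list[CategoryConfig]] = None
    unwanted: Optional[list[CategoryConfig]] = None


class SyntheticConfig(_Model):
    clones_per_category: dict[str, int]
    kd_median: float = Field(default=defaults.MEDIAN_KD, gt=0)
    kd_sigma_ln: float = Field(default=0.4, ge=0)
    read_depth: int = Field(default=25_000_000, gt=0)
    nonspecific_jitter_sigma: float = Field(default=0.0, ge=0)


class RunConfig(_Model):
    seed: int = 0
    log_level: str = "INFO"
    model_kd: float = Field(default=defaults.MEDIAN_KD, gt=0)
    min_reads: int = Field(default=2, ge=0)
    protocols: dict[str, ProtocolConfig]
    panel: PanelConfig = PanelConfig()
    thresholds: ThresholdsConfig = ThresholdsConfig()
    optimizer: OptimizerConfig = OptimizerConfig()
    synthetic: SyntheticConfig

    @model_validator(mode="after")
    def _check_arms(self) -> "RunConfig":
        known = {WITH_COMPETITION, WITHOUT_COMPETITION}
        unknown = set(self.protocols) - known
        if unknown:
            raise ValueError(f"unknown protocol arm(s) {sorted(unknown)}; "
                             f"expected a subset of {sorted(known)}")
        if not self.protocols:
            raise ValueError("at least one protocol arm is required")
        return self


def default_config_path() -> Path:
    """Path of the shipped study-defaults config."""
    return Path(str(resources.files("ilama").joinpath("data/paper_defaults.yaml")))


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config (shipped defaults when *path* is None)."""
    cfg_path = Path(path) if path is not None else default_config_path()
    try:
        raw = yaml.safe_load(cfg_path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {cfg_path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{cfg_path}: config must be a mapping")
    try:
        cfg = RunConfig.model_validate(raw)
    except ValidationError as exc:
        raise ConfigError(f"{cfg_path}: {exc}") from exc
    _log_resolved(cfg)
    return cfg


def _log_resolved(cfg: RunConfig) -> None:
    for arm, proto in cfg.protocols.items():
        for i, rnd in enumerate(proto.rounds, start=1):
            defaults.warn_unreported_volume(rnd.volume)
            if rnd.hit_rate_is_estimate:
                log.info("%s round %d: hit_rate=%g is an estimate, not a measurement",
                         arm, i, rnd.hit_rate)
    log.debug("resolved config: %s", cfg.model_dump())


def build_protocol(cfg: RunConfig, arm: str) -> SelectionProtocol:
    if arm not in cfg.protocols:
        raise ConfigError(f"config defines no protocol for arm {arm!r}")
    proto = cfg.protocols[arm]
    rounds = tuple(
        SelectionRoundParams(
            cells=CellInput(r.target_cells, r.nontarget_cells),
            recovery=RecoveryFactors(r.elution, r.cell_recovery),
            volume=r.volume,
            amplification_into_next=r.amplification_into_next,
            hit_rate=r.hit_rate,
        )
        for r in proto.rounds
    )
    return SelectionProtocol(rounds=rounds, arm=arm, initial_copies=proto.initial_copies)


def build_panel_from_config(cfg: RunConfig) -> list[ReceptorProfile]:
    categories: list[float | None] = []
    if cfg.panel.include_restricted:
        categories.append(None)
    categories.extend(cfg.panel.upregulation_ratios)
    return build_panel(cfg.panel.min_copies, cfg.panel.max_copies,
                       cfg.panel.fold_step, categories)


def build_thresholds(cfg: RunConfig) -> ClassifierThresholds:
    t = cfg.thresholds
    if t.mode == "constants":
        return ClassifierThresholds(t.low_threshold_ppm, t.high_threshold_ppm,
                                    t.ratio_threshold, t.fallback_round3_ratio)
    protocol = build_protocol(cfg, WITH_COMPETITION)
    from .simulate import CloneModel, simulate_protocol  # local to avoid cycle noise
    pool = [
        simulate_protocol(CloneModel(rp.name, cfg.model_kd, rp), protocol)
        for rp in build_panel_from_config(cfg)
    ]
    return derive_thresholds(protocol, pool, kd=cfg.model_kd,
                             ratio_threshold=t.ratio_threshold,
                             fallback_round3_ratio=t.fallback_round3_ratio)


def build_criteria(cfg: RunConfig) -> OptimizationCriteria:
    o = cfg.optimizer
    if o.wanted is None and o.unwanted is None:
        base = default_criteria()
        return OptimizationCriteria(base.wanted, base.unwanted, o.kd, o.capture_floor)
    if o.wanted is None or o.unwanted is None:
        raise ConfigError("optimizer wanted/unwanted must be given together")
    wanted = tuple(ReceptorProfile(c.name, c.copies_target, c.copies_nontarget)
                   for c in o.wanted)
    unwanted = tuple(ReceptorProfile(c.name, c.copies_target, c.copies_nontarget)
                     for c in o.unwanted)
    return OptimizationCriteria(wanted, unwanted, o.kd, o.capture_floor)


def build_cohort_spec(cfg: RunConfig, seed: int | None = None) -> SyntheticCohortSpec:
    s = cfg.synthetic
    return SyntheticCohortSpec(
        clones_per_category=dict(s.clones_per_category),
        kd_median=s.kd_median,
        kd_sigma_ln=s.kd_sigma_ln,
        read_depth=s.read_depth,
        nonspecific_jitter_sigma=s.nonspecific_jitter_sigma,
        seed=cfg.seed if seed is None else seed,
    )
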