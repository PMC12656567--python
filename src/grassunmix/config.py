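"""Declarative run configuration (TOML) with strict validation.

Every pipeline stage reads its parameters from one [stage] block; unknown
keys are rejected (strict by default) and every violation is reported with
its full key path. Band ranges and thresholds are validated here so stage
code can assume well-formed inputs.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields as dc_fields

from .errors import ConfigError

__all__ = ["RunConfig", "validate_config"]


@dataclass
class SceneConfig:
    rows: int = 100
    cols: int = 100
    n_bands: int = 426
    noise_sd: float = 0.01
    smoothness_px: float = 0.3
    concentration_2018: list = field(default_factory=lambda: [0.15, 0.12, 0.10])
    concentration_2022: list = field(default_factory=lambda: [0.10, 0.13, 0.13])
    n_nodata: int = 5
    n_negative: int = 5


@dataclass
class PreprocessConfig:
    sentinel: float = -9999.0
    min_valid: float = 0.0
    band_exclusions: list = field(
        default_factory=lambda: [[192, 212], [282, 314]]
    )
    aoi: str = ""  # optional GeoJSON path; empty = no clip


@dataclass
class EndmemberConfig:
    n_regions_per_class: int = 20
    purity: float = 0.95


@dataclass
class UnmixConfig:
    mode: str = "fcls"


@dataclass
class TrendConfig:
    years: list = field(default_factory=lambda: [2018, 2022])
    breaks: list = field(default_factory=lambda: [-0.085, -0.036, 0.037])


@dataclass
class SummaryConfig:
    n_bins: int = 10
    category_breaks: list = field(default_factory=lambda: [0.3, 0.6])


@dataclass
class ValidateConfig:
    tau: list = field(default_factory=lambda: [0.5, 0.75])
    n_per_class: int = 50
    purity: float = 0.75


@dataclass
class RunConfig:
    seed: int = 0
    scene: SceneConfig = field(default_factory=SceneConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    endmembers: EndmemberConfig = field(default_factory=EndmemberConfig)
    unmix: UnmixConfig = field(default_factory=UnmixConfig)
    trend: TrendConfig = field(default_factory=TrendConfig)
    summary: SummaryConfig = field(default_factory=SummaryConfig)
    validate: ValidateConfig = field(default_factory=ValidateConfig)


_SECTIONS = {
    "scene": SceneConfig,
    "preprocess": PreprocessConfig,
    "endmembers": EndmemberConfig,
    "unmix": UnmixConfig,
    "trend": TrendConfig,
    "summary": SummaryConfig,
    "validate": ValidateConfig,
}


def _fill_section(cls, block: dict, path: str, strict: bool):
    known = {f.name for f in dc_fields(cls)}
    unknown = set(block) - known
    if unknown and strict:
        key = sorted(unknown)[0]
        raise ConfigError(f"unknown key {path}.{key}")
    return cls(**{k: v for k, v in block.items() if k in known})


def _check(cfg: RunConfig):
    """Cross-field constraint checks, each reported with its key path."""
    sc = cfg.scene
    if sc.rows < 1 or sc.cols < 1:
        raise ConfigError("scene.rows and scene.cols must be at least 1")
    if sc.n_bands < 2:
        raise ConfigError("scene.n_bands must be at least 2")
    if sc.noise_sd < 0:
        raise ConfigError("scene.noise_sd must be non-negative")
    if len(sc.concentration_2018) != len(sc.concentration_2022):
        raise ConfigError(
            "scene.concentration_2018 and scene.concentration_2022 must have "
            "equal length"
        )
    if any(c <= 0 for c in sc.concentration_2018 + sc.concentration_2022):
        raise ConfigError("scene concentrations must be positive")
    for pair in cfg.preprocess.band_exclusions:
        if len(pair) != 2 or pair[0] > pair[1] or pair[0] < 1:
            raise ConfigError(
                f"preprocess.band_exclusions entry {pair} is not a 1-based "
                "inclusive [low, high] pair"
            )
        if pair[1] > sc.n_bands:
            raise ConfigError(
                f"preprocess.band_exclusions entry {pair} exceeds scene.n_bands"
            )
    if cfg.unmix.mode not in ("ols", "sto", "nnls", "fcls"):
        raise ConfigError(f"unmix.mode {cfg.unmix.mode!r} is not a known mode")
    if len(cfg.trend.years) != 2 or cfg.trend.years[1] <= cfg.trend.years[0]:
        raise ConfigError("trend.years must be two increasing calendar years")
    breaks = cfg.trend.breaks
    if any(b2 <= b1 for b1, b2 in zip(breaks, breaks[1:])):
        raise ConfigError("trend.breaks must be strictly increasing")
    if cfg.summary.n_bins < 1:
        raise ConfigError("summary.n_bins must be at least 1")
    cb = cfg.summary.category_breaks
    if any(not 0 < b < 1 for b in cb) or any(b2 <= b1 for b1, b2 in zip(cb, cb[1:])):
        raise ConfigError(
            "summary.category_breaks must be strictly increasing inside (0, 1)"
        )
    for t in cfg.validate.tau:
        if not 0 < t < 1:
            raise ConfigError(f"validate.tau value {t} outside (0, 1)")
    if not 0 < cfg.validate.purity <= 1:
        raise ConfigError("validate.purity must lie in (0, 1]")
    if not 0 < cfg.endmembers.purity <= 1:
        raise ConfigError("endmembers.purity must lie in (0, 1]")


def validate_config(source, strict: bool = True) -> RunConfig:
    """Load and validate a configuration from a TOML path or a dict.

    Returns a fully resolved RunConfig with defaults filled in; raises
    ConfigError naming the offending key path on any violation.
    """
    if isinstance(source, RunConfig):
        _check(source)
        return source
    if isinstance(source, dict):
        doc = source
    else:
        try:
            with open(source, "rb") as fh:
                doc = tomllib.load(fh)
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {source}") from exc
        except tomllib.TOMLDecodeError as exc:
            raise ConfigError(f"config is not valid TOML: {exc}") from exc

    top_known = set(_SECTIONS) | {"seed"}
    unknown = set(doc) - top_known
    if unknown and strict:
        raise ConfigError(f"unknown key {sorted(unknown)[0]}")
    kwargs = {"seed": int(doc.get("seed", 0))}
    for name, cls in _SECTIONS.items():
        block = doc.get(name, {})
        if not isinstance(block, dict):
            raise ConfigError(f"section [{name}] must be a table")
        kwargs[name] = _fill_section(cls, block, name, strict)
    cfg = RunConfig(**kwargs)
    _check(cfg)
    return cfg
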