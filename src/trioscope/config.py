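"""Tunable configuration: adjudication thresholds, caller parameters and
annotation-join field maps, loadable from a TOML file.

Every threshold is pure configuration — changing it changes verdicts and
filters, never the underlying counts.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Union

__all__ = [
    "AdjudicationConfig",
    "CallerConfig",
    "JoinConfig",
    "RankConfig",
    "Config",
    "load_config",
]


@dataclass(frozen=True)
class AdjudicationConfig:
    """Allele-balance cutoffs for de novo adjudication and
    genotype/evidence consistency checks."""

    het_low: float = 0.20          # het AB below this: poor support
    het_high: float = 0.80
    hom_alt_min: float = 0.90      # hom-alt calls want AB >= this
    hom_ref_max: float = 0.05      # hom-ref calls tolerate alt fraction <= this
    parent_min_alt: int = 2        # parental alt reads needed to suspect inheritance
    parent_min_frac: float = 0.02  # ... together with this alt fraction
    min_depth_hard: int = 5        # below this the site is uninformative
    low_cov_warn: int = 20         # below this a supported verdict is flagged


@dataclass(frozen=True)
class CallerConfig:
    """Stand-in genotyper parameters: per-read error rate, genotype priors
    and discovery-mode emission thresholds. The permissive mapping-quality /
    coverage defaults mirror the upstream caller invocation this replaces."""

    error_rate: float = 0.01
    priors: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    min_alt_obs: int = 3
    min_ab: float = 0.10
    min_mapq: int = 0
    min_baseq: int = 13
    min_coverage: int = 0
    count_duplicates: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error_rate must lie in (0, 0.5)")
        if abs(sum(self.priors) - 1.0) > 1e-9:
            raise ValueError("genotype priors must sum to 1")


@dataclass(frozen=True)
class JoinConfig:
    """INFO field names in the population / clinical snapshot VCFs."""

    af_field: str = "AF"
    het_field: str = "nhet"
    hom_field: str = "nhomalt"
    clnsig_field: str = "CLNSIG"
    review_status_field: str = "CLNREVSTAT"


@dataclass(frozen=True)
class RankConfig:
    max_af: float | None = None
    min_impact: str | None = None
    low_coverage_threshold: int = 10


@dataclass(frozen=True)
class Config:
    adjudication: AdjudicationConfig = field(default_factory=AdjudicationConfig)
    caller: CallerConfig = field(default_factory=CallerConfig)
    join: JoinConfig = field(default_factory=JoinConfig)
    rank: RankConfig = field(default_factory=RankConfig)


_SECTIONS = {
    "adjudication": AdjudicationConfig,
    "caller": CallerConfig,
    "join": JoinConfig,
    "rank": RankConfig,
}


def load_config(path: Union[str, Path, None] = None) -> Config:
    """Read a TOML config with sections [adjudication], [caller], [join],
    [rank]; absent sections and keys keep their defaults."""
    cfg = Config()
    if path is None:
        return cfg
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    updates = {}
    for section, cls in _SECTIONS.items():
        if section not in raw:
            continue
        known = {f.name for f in fields(cls)}
        unknown = set(raw[section]) - known
        if unknown:
            raise ValueError(f"[{section}] has unknown keys: {sorted(unknown)}")
        values = dict(raw[section])
        if "priors" in values:
            values["priors"] = tuple(values["priors"])
        updates[section] = cls(**values)
    return replace(cfg, **updates)
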