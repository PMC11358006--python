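"""Run configuration: every tunable threshold of the pipeline in one place.

Defaults follow the source study where it states a value (gating log2 ratio
1, DE fold 1.5 / p 0.05 / expression 0.1, localization probability 0.75,
imputation width 0.3 / downshift 1.8, kinase FDR 0.02, target t-test p
0.05); the remainder are explicit package decisions documented in
docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger("ersecretome")


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass
class GatingConfig:
    log2_ratio_threshold: float = 1.0
    pseudocount: float = 0.01

    def validate(self) -> None:
        _check(self.pseudocount > 0, "gating.pseudocount must be > 0")


@dataclass
class DEConfig:
    fold_threshold: float = 1.5
    p_threshold: float = 0.05
    min_expression: float = 0.1

    def validate(self) -> None:
        _check(self.fold_threshold > 0, "de.fold_threshold must be > 0")
        _check(0 < self.p_threshold < 1, "de.p_threshold must be in (0,1)")


@dataclass
class PhosphoConfig:
    loc_prob_threshold: float = 0.75
    impute_width: float = 0.3
    impute_downshift: float = 1.8
    fdr_threshold: float = 0.02
    target_p_threshold: float = 0.05
    anova_alpha: float = 0.05
    min_substrates: int = 5
    fisher_alternative: str = "two-sided"

    def validate(self) -> None:
        _check(0 < self.loc_prob_threshold < 1, "phospho.loc_prob_threshold must be in (0,1)")
        _check(self.impute_width >= 0, "phospho.impute_width must be >= 0")
        _check(self.impute_downshift >= 0, "phospho.impute_downshift must be >= 0")
        _check(0 < self.fdr_threshold < 1, "phospho.fdr_threshold must be in (0,1)")
        _check(0 < self.target_p_threshold < 1, "phospho.target_p_threshold must be in (0,1)")
        _check(0 < self.anova_alpha < 1, "phospho.anova_alpha must be in (0,1)")
        _check(self.min_substrates >= 1, "phospho.min_substrates must be >= 1")
        _check(
            self.fisher_alternative in {"two-sided", "greater", "less"},
            "phospho.fisher_alternative must be two-sided/greater/less",
        )


@dataclass
class TriageConfig:
    tm_window: int = 19
    tm_threshold: float = 1.6
    tm_min_length: int = 15
    signal_anchor_region: int = 30
    motif_set: tuple[str, ...] = ("KDEL", "HDEL", "RDEL", "REDL", "ADEL", "DDEL")

    def validate(self) -> None:
        _check(self.tm_window >= 7 and self.tm_window % 2 == 1, "triage.tm_window must be odd and >= 7")
        _check(all(len(m) == 4 for m in self.motif_set), "triage.motif_set entries must be tetrapeptides")


@dataclass
class InducibilityConfig:
    fold_threshold: float = 2.0

    def validate(self) -> None:
        _check(self.fold_threshold > 0, "inducibility.fold_threshold must be > 0")


@dataclass
class RunConfig:
    gating: GatingConfig = field(default_factory=GatingConfig)
    de: DEConfig = field(default_factory=DEConfig)
    phospho: PhosphoConfig = field(default_factory=PhosphoConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    inducibility: InducibilityConfig = field(default_factory=InducibilityConfig)
    rng_seed: int = 0

    def validate(self) -> "RunConfig":
        for section in (self.gating, self.de, self.phospho, self.triage, self.inducibility):
            section.validate()
        return self

    # -- (de)serialisation -------------------------------------------------
    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ConfigError(f"unknown config section {key!r}")
            attr = getattr(cfg, key)
            if dataclasses.is_dataclass(attr):
                for sub, subval in value.items():
                    if not hasattr(attr, sub):
                        raise ConfigError(f"unknown config key {key}.{sub}")
                    if sub == "motif_set":
                        subval = tuple(subval)
                    setattr(attr, sub, subval)
            else:
                setattr(cfg, key, value)
        return cfg.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def log_effective(self) -> None:
        """Echo the effective configuration, one line per leaf key."""
        for section_name, section in self.to_dict().items():
            if isinstance(section, dict):
                for key, value in section.items():
                    logger.info("config %s.%s = %r", section_name, key, value)
            else:
                logger.info("config %s = %r", section_name, section)
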