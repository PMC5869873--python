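"""Structured pipeline configuration with YAML loading and validation.

Every randomized stage (bootstrap, effect simulation) must carry an explicit
seed; a configuration without one is rejected at load time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .categorical import CategoricalThresholds
from .errors import ConfigError


@dataclass
class PipelineConfig:
    ecg_csv: str = "ecg.csv"
    pk_csv: str = "pk.csv"
    truth_csv: str | None = None
    output_dir: str = "out"
    correction_methods: tuple = ("QTcI", "QTcF")
    include_bazett: bool = False
    min_dosing_days: int = 4          # evaluability rule before the steady-state day
    drop_predose_delta_day1: bool = True
    selection_alpha: float = 0.05
    covariate_alpha: float = 0.01
    bootstrap_b: int = 1000
    bootstrap_seed: int | None = None
    sim_n: int = 1000
    sim_seed: int | None = None
    reference_conc_nM: float = 2760.0
    thresholds: CategoricalThresholds = field(default_factory=CategoricalThresholds)
    run_bootstrap: bool = True

    def __post_init__(self):
        if self.bootstrap_seed is None or self.sim_seed is None:
            raise ConfigError(
                "bootstrap_seed and sim_seed are required: every randomized "
                "stage must carry an explicit seed"
            )
        for name in ("selection_alpha", "covariate_alpha"):
            a = getattr(self, name)
            if not (0.0 < a < 1.0):
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.reference_conc_nM <= 0:
            raise ConfigError("reference_conc_nM must be positive")
        if self.bootstrap_b < 1 or self.sim_n < 1:
            raise ConfigError("bootstrap_b and sim_n must be >= 1")
        thr = self.thresholds
        if any(t <= 0 for t in (*thr.qtc_abs_ms, *thr.dqtc_ms, thr.pr_abs_ms,
                                thr.qrs_abs_ms, thr.rel_increase_pct)):
            raise ConfigError("categorical thresholds must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "thresholds" in d and isinstance(d["thresholds"], dict):
            t = dict(d["thresholds"])
            for tup in ("qtc_abs_ms", "dqtc_ms"):
                if tup in t:
                    t[tup] = tuple(t[tup])
            d["thresholds"] = CategoricalThresholds(**t)
        if "correction_methods" in d:
            d["correction_methods"] = tuple(d["correction_methods"])
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        return cls.from_dict(d)

    def to_yaml(self, path) -> None:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["thresholds"] = {
            "qtc_abs_ms": list(self.thresholds.qtc_abs_ms),
            "dqtc_ms": list(self.thresholds.dqtc_ms),
            "pr_abs_ms": self.thresholds.pr_abs_ms,
            "qrs_abs_ms": self.thresholds.qrs_abs_ms,
            "rel_increase_pct": self.thresholds.rel_increase_pct,
        }
        d["correction_methods"] = list(self.correction_methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
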