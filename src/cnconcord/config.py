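"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

#: GISTIC-scale discrete copy-number levels.
CALL_LEVELS = (-2, -1, 0, 1, 2)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic paired CNV/expression/clinical cohort.

    The generator emulates the statistical structure the concordance
    analysis assumes: a linear copy-number dosage effect on expression for
    most genes, a dosage-insensitive minority, amplification events more
    frequent than deletion events, rare sign-flipped (discordant) events,
    and survival times whose hazard depends on carrying a planted gene's
    concordant amplification.

    Genes fall into five tiers: background (event rates ``amp_rate`` /
    ``del_rate``), planted AUGs (``aug_amp_rate``), planted DDGs
    (``ddg_del_rate``), and calibration-reference oncogenes / tumor
    suppressors with intermediate event rates and slopes attenuated by
    ``ref_slope_factor`` so that reference-median thresholds sit between
    the background and the planted tiers.
    """

    n_genes: int = 2000
    n_samples: int = 500
    #: fraction of genes with a linear CN->expression dosage effect
    dosage_fraction: float = 0.85
    slope_mean: float = 1.0
    slope_sd: float = 0.2
    noise_sd: float = 0.5
    #: per-(gene,sample) probabilities of calls +2 / -2 / +1 / -1
    amp_rate: float = 0.02
    del_rate: float = 0.005
    gain_rate: float = 0.05
    hemiloss_rate: float = 0.03
    #: probability a +-2 event's expression effect is sign-flipped
    discord_rate: float = 0.01
    # planted concordant genes with known truth
    n_planted_aug: int = 50
    n_planted_ddg: int = 30
    aug_amp_rate: float = 0.15
    ddg_del_rate: float = 0.08
    # calibration-reference tiers (oncogene / tumor-suppressor stand-ins)
    n_ref_oncogenes: int = 30
    n_ref_tsgs: int = 10
    ref_amp_rate: float = 0.08
    ref_del_rate: float = 0.03
    ref_slope_factor: float = 0.75
    # baseline expression (RSEM-like arbitrary units)
    baseline_low: float = 5.0
    baseline_high: float = 15.0
    # survival model: exponential event and censoring hazards (per month)
    survival_hazard_ratio: float = 3.0
    baseline_hazard: float = 1.0 / 24.0
    censoring_hazard: float = 1.0 / 36.0
    seed: int = 0

    def validate(self) -> None:
        """Raise :class:`ValueError` naming the first offending parameter."""
        if self.n_genes < 1:
            raise ValueError(f"n_genes must be >= 1, got {self.n_genes}")
        if self.n_samples < 4:
            raise ValueError(
                f"n_samples must be >= 4 (downstream needs >=3 diploid "
                f"reference samples), got {self.n_samples}"
            )
        for name in (
            "dosage_fraction", "amp_rate", "del_rate", "gain_rate",
            "hemiloss_rate", "discord_rate", "aug_amp_rate", "ddg_del_rate",
            "ref_amp_rate", "ref_del_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.amp_rate + self.del_rate + self.gain_rate + self.hemiloss_rate
        if total > 1.0:
            raise ValueError(
                f"amp_rate + del_rate + gain_rate + hemiloss_rate must be "
                f"<= 1, got {total}"
            )
        for name in ("slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("n_planted_aug", "n_planted_ddg", "n_ref_oncogenes",
                     "n_ref_tsgs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        n_special = (self.n_planted_aug + self.n_planted_ddg
                     + self.n_ref_oncogenes + self.n_ref_tsgs)
        n_sensitive = round(self.dosage_fraction * self.n_genes)
        if n_special > n_sensitive:
            raise ValueError(
                f"planted + reference genes ({n_special}) exceed the "
                f"dosage-sensitive gene count ({n_sensitive}); raise "
                f"dosage_fraction or n_genes"
            )
        if self.baseline_high < self.baseline_low:
            raise ValueError("baseline_high must be >= baseline_low")
        for name in ("survival_hazard_ratio", "baseline_hazard",
                     "censoring_hazard"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= int(self.seed) < 2**31:
            raise ValueError(f"seed must be in [0, 2^31), got {self.seed}")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass(frozen=True)
class PipelineConfig:
    """End-to-end run configuration loaded from a YAML file.

    ``cn_mode`` selects the copy-number dialect: ``gistic`` reads a
    discrete five-level call matrix from ``calls``; ``picnic`` derives
    calls from ``absolute_cn`` + ``ploidy`` via the ploidy-conditional
    criteria.
    """

    expression: Path
    output_dir: Path
    cn_mode: str = "gistic"
    calls: Optional[Path] = None
    absolute_cn: Optional[Path] = None
    ploidy: Optional[Path] = None
    clinical: Optional[Path] = None
    annotation: Optional[Path] = None
    grouping: Optional[Path] = None
    oncogene_list: Optional[Path] = None
    tsg_list: Optional[Path] = None
    min_diploid: int = 3
    deg_threshold: float = 2.0
    log2_offset: Optional[float] = None
    threshold_mode: str = "calibrated"
    fixed_rho_min_aug: float = 0.4
    fixed_count_min_aug: float = 146.5
    fixed_rho_min_ddg: float = 0.41
    fixed_count_min_ddg: float = 18.5
    ratio_min: float = 0.5
    max_survival_genes: int = 50
    seed: int = 0

    def validate(self) -> None:
        if self.cn_mode not in ("gistic", "picnic"):
            raise ValueError(f"cn_mode must be 'gistic' or 'picnic', got "
                             f"{self.cn_mode!r}")
        if self.threshold_mode not in ("calibrated", "fixed"):
            raise ValueError(
                f"threshold_mode must be 'calibrated' or 'fixed', got "
                f"{self.threshold_mode!r}")
        if self.cn_mode == "gistic" and self.calls is None:
            raise ValueError("cn_mode 'gistic' requires a 'calls' path")
        if self.cn_mode == "picnic" and (self.absolute_cn is None
                                         or self.ploidy is None):
            raise ValueError(
                "cn_mode 'picnic' requires 'absolute_cn' and 'ploidy' paths")
        if self.min_diploid < 2:
            raise ValueError(f"min_diploid must be >= 2, got {self.min_diploid}")
        if self.deg_threshold <= 0:
            raise ValueError("deg_threshold must be > 0")
        if not 0 < self.ratio_min < 1:
            raise ValueError("ratio_min must be in (0, 1)")
        required = {"expression": self.expression}
        if self.cn_mode == "gistic":
            required["calls"] = self.calls
        else:
            required["absolute_cn"] = self.absolute_cn
            required["ploidy"] = self.ploidy
        for key in ("clinical", "annotation", "grouping", "oncogene_list",
                    "tsg_list"):
            if getattr(self, key) is not None:
                required[key] = getattr(self, key)
        for key, path in required.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"{key} file not found: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
        path_keys = {"expression", "output_dir", "calls", "absolute_cn",
                     "ploidy", "clinical", "annotation", "grouping",
                     "oncogene_list", "tsg_list"}
        for key in path_keys & set(raw):
            if raw[key] is not None:
                p = Path(raw[key])
                raw[key] = p if p.is_absolute() else base / p
        cfg = cls(**raw)
        cfg.validate()
        return cfg
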