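"""Run configuration for the whole toolkit.

All tunable thresholds live here so that every pipeline stage reads its
parameters from one validated object.  Defaults mirror the contracts of the
external tools whose behaviour the toolkit re-implements: the annotation
realignment uses intron-free ungapped placement with >=16 matched bases, 0
mismatches and at most 100 loci; read alignment uses >=14 matched bases and
<=1 mismatch; the transcript quantifier runs 100 bootstrap rounds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import yaml


@dataclass
class ForgeParams:
    """Annotation-forging thresholds.

    max_seq_len is exclusive (sequences must be <100 nt); pirnabank_max_len
    is exclusive too (<69 nt piRNA-database sequences are integrated with the
    completing database, longer ones are dropped).
    """

    max_seq_len: int = 100
    pirnabank_max_len: int = 69
    min_match: int = 16
    max_mismatch: int = 0
    max_loci: int = 100
    stringent_coding_filter: bool = True
    region_max_gap: int = 1000
    embedded_same_strand: bool = True

    def validate(self) -> None:
        for name in ("max_seq_len", "pirnabank_max_len", "min_match", "max_loci", "region_max_gap"):
            if getattr(self, name) <= 0:
                raise ValueError(f"forge.{name} must be positive")
        if self.max_mismatch < 0:
            raise ValueError("forge.max_mismatch must be >= 0")


@dataclass
class QuantParams:
    """Read-alignment and transcript-EM thresholds."""

    min_match: int = 14
    max_mismatch: int = 1
    max_loci: int = 100
    no_splice: bool = True
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    max_error_rate: float = 0.1
    min_read_len: int = 15
    count_mode: str = "fractional"  # unique | all | fractional
    n_bootstraps: int = 100
    em_tol: float = 1e-8
    em_max_iter: int = 1000

    def validate(self) -> None:
        for name in ("min_match", "max_loci", "min_read_len", "n_bootstraps", "em_max_iter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"quant.{name} must be positive")
        if self.em_tol <= 0:
            raise ValueError("quant.em_tol must be > 0")
        if self.count_mode not in ("unique", "all", "fractional"):
            raise ValueError(f"unknown count_mode {self.count_mode!r}")


@dataclass
class StatsParams:
    cpm_threshold: float = 1.0
    min_samples: int | None = None  # None -> size of the smallest group
    tmm_logratio_trim: float = 0.30
    tmm_sum_trim: float = 0.05
    mds_top_features: int = 500

    def validate(self) -> None:
        if self.cpm_threshold <= 0:
            raise ValueError("stats.cpm_threshold must be positive")


@dataclass
class DEParams:
    alpha: float = 0.05
    merge_mode: str = "union"  # union | intersection
    prior_df_mode: str = "moment-matched"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("de.alpha must be in (0, 1)")
        if self.merge_mode not in ("union", "intersection"):
            raise ValueError(f"unknown merge_mode {self.merge_mode!r}")


STANDARD_CHROM_PATTERN = (
    [str(i) for i in range(1, 23)] + ["X", "Y", "MT", "M"]
)


@dataclass
class RunConfig:
    """Top-level configuration: forge, quantification, statistics, DE, seed."""

    forge: ForgeParams = field(default_factory=ForgeParams)
    quant: QuantParams = field(default_factory=QuantParams)
    stats: StatsParams = field(default_factory=StatsParams)
    de: DEParams = field(default_factory=DEParams)
    seed: int = 0
    standard_chromosomes: Sequence[str] | None = None  # None -> name-pattern rule

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        self.forge.validate()
        self.quant.validate()
        self.stats.validate()
        self.de.validate()

    def is_standard_chromosome(self, name: str) -> bool:
        if self.standard_chromosomes is not None:
            return name in set(self.standard_chromosomes)
        stripped = name[3:] if name.lower().startswith("chr") else name
        return stripped.upper() in STANDARD_CHROM_PATTERN

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            forge=ForgeParams(**raw.get("forge", {})),
            quant=QuantParams(**raw.get("quant", {})),
            stats=StatsParams(**raw.get("stats", {})),
            de=DEParams(**raw.get("de", {})),
            seed=raw.get("seed", 0),
            standard_chromosomes=raw.get("standard_chromosomes"),
        )
        return cfg

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
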