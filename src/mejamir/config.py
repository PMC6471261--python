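"""Run configuration: sample sheet, decision thresholds, random seed.

The experimental design is fixed by the study layout: four timepoints of a
methyl-jasmonate (MeJA) elicitation time course — CK (0 h, control), T1
(24 h), T2 (36 h), T3 (48 h) — with two biological replicates each, i.e.
eight small-RNA libraries.  All stage thresholds live here so a run is
fully described by one YAML file plus its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

TIMEPOINTS = ("CK", "T1", "T2", "T3")

#: the six pairwise comparisons reported for a four-timepoint design
COMPARISONS = (
    ("CK", "T1"), ("CK", "T2"), ("CK", "T3"),
    ("T1", "T2"), ("T1", "T3"), ("T2", "T3"),
)


@dataclass
class Thresholds:
    """Decision thresholds used across the pipeline stages.

    fold_change : minimum fold change (on TPM) for a DE call, default 2.
    de_p        : p-value cutoff of the exact two-library count test.
    cor_threshold : Pearson r cutoff for miRNA–mRNA anti-correlation
                    (a pair qualifies when r < cor_threshold).
    cor_p       : p-value cutoff of the correlation t-test.
    stem_p      : profile over-occupancy cutoff (permutation, corrected).
    mfe_ratio   : minimum |E_duplex| / |E_perfect| for a target site.
    max_mismatch : maximum duplex mismatch score (G:U counts 0.5).
    """

    fold_change: float = 2.0
    de_p: float = 0.05
    cor_threshold: float = -0.50
    cor_p: float = 0.05
    stem_p: float = 0.02
    mfe_ratio: float = 0.74
    max_mismatch: float = 4.0

    def __post_init__(self) -> None:
        for name in ("fold_change", "de_p", "cor_p", "stem_p",
                     "mfe_ratio", "max_mismatch"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")
        if self.cor_threshold >= 0:
            raise ValueError("cor_threshold must be negative")


@dataclass
class SampleSheet:
    """Library id → (timepoint, replicate index).  Order is authoritative:
    every matrix in the pipeline uses this column order."""

    libraries: list[str]
    timepoint: dict[str, str]
    replicate: dict[str, int]

    @classmethod
    def default(cls) -> "SampleSheet":
        libs, tp, rep = [], {}, {}
        for t in TIMEPOINTS:
            for r in (1, 2):
                lib = f"{t}-{r}"
                libs.append(lib)
                tp[lib] = t
                rep[lib] = r
        return cls(libs, tp, rep)

    def __post_init__(self) -> None:
        seen = set(self.timepoint.values())
        if seen != set(TIMEPOINTS):
            raise ValueError(
                f"sample sheet must cover exactly the timepoints {TIMEPOINTS}, got {sorted(seen)}"
            )
        for lib in self.libraries:
            if lib not in self.timepoint:
                raise ValueError(f"library {lib!r} missing a timepoint label")

    def group(self, timepoint: str) -> list[str]:
        if timepoint not in TIMEPOINTS:
            raise ValueError(f"unknown timepoint label {timepoint!r}")
        return [l for l in self.libraries if self.timepoint[l] == timepoint]


@dataclass
class RunConfig:
    """Everything a pipeline run needs besides the input files."""

    samples: SampleSheet = field(default_factory=SampleSheet.default)
    thresholds: Thresholds = field(default_factory=Thresholds)
    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter
    adapter5: str = "GTTCAGAGTTCTACAGTCCGACGATC"
    seed: int = 1
    stem_permutations: int = 10_000

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        samples = raw.get("samples")
        sheet = (SampleSheet(**samples) if samples else SampleSheet.default())
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            samples=sheet,
            thresholds=thr,
            adapter3=raw.get("adapter3", cls.adapter3),
            adapter5=raw.get("adapter5", cls.adapter5),
            seed=int(raw.get("seed", 1)),
            stem_permutations=int(raw.get("stem_permutations", 10_000)),
        )
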