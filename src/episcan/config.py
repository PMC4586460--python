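"""Configuration for the synthetic 450K cohort generator.

The defaults emulate the study design the pipeline was built for: a
33-placenta cohort split into six phenotype × gestational-weight-gain
categories (FGR/normal × insufficient/adequate/excessive, sizes
5/5/4/9/5/5), with individual-specific epimutation burdens of 46-74
outlier probes per subject in the reference (normal_adequate) category
and 44-421 in the five adverse categories, hypermethylation effect
sizes Δβ ~ N(0.18, 0.11) injected as runs of ≥2 adjacent CpG-island
promoter probes, and hypomethylation Δβ ~ N(-0.27, 0.12) injected at
isolated open-sea probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence, Tuple

import yaml

CATEGORIES = (
    "FGR_adequate",
    "FGR_insufficient",
    "FGR_excessive",
    "normal_adequate",
    "normal_insufficient",
    "normal_excessive",
)

DEFAULT_CATEGORY_SIZES: Mapping[str, int] = {
    "FGR_adequate": 5,
    "FGR_insufficient": 5,
    "FGR_excessive": 4,
    "normal_adequate": 9,
    "normal_insufficient": 5,
    "normal_excessive": 5,
}

DEFAULT_BURDEN: Mapping[str, Tuple[int, int]] = {
    "FGR_adequate": (44, 421),
    "FGR_insufficient": (44, 421),
    "FGR_excessive": (44, 421),
    "normal_adequate": (46, 74),
    "normal_insufficient": (44, 421),
    "normal_excessive": (44, 421),
}

# gestational weight gain (kg): mean, sd, (low, high) clip per category,
# matching the cohort's clinical summary; used only for burden-profile
# ordering, never by the statistics.
DEFAULT_GWG_KG: Mapping[str, Tuple[float, float, float, float]] = {
    "FGR_adequate": (8.2, 1.2, 7.0, 12.0),
    "FGR_insufficient": (4.5, 1.8, 0.5, 6.9),
    "FGR_excessive": (13.5, 0.9, 12.1, 20.0),
    "normal_adequate": (8.7, 1.1, 7.0, 12.0),
    "normal_insufficient": (6.3, 0.7, 0.5, 6.9),
    "normal_excessive": (14.7, 1.0, 12.1, 20.0),
}

# hg19 autosome lengths (Mb), used to apportion probes across chromosomes
_CHROM_MB = {
    "1": 249, "2": 243, "3": 198, "4": 191, "5": 181, "6": 171,
    "7": 159, "8": 146, "9": 141, "10": 136, "11": 135, "12": 134,
    "13": 115, "14": 107, "15": 103, "16": 90, "17": 81, "18": 78,
    "19": 59, "20": 63, "21": 48, "22": 51,
}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort; see module docstring for defaults."""

    n_probes: int = 60_000
    chromosome_layout: Sequence[Tuple[str, int]] | None = None
    fraction_cgi_promoter: float = 0.30
    fraction_snp_flagged: float = 0.185  # 89,678 / 485,577 flagged on the real array
    n_sex_chrom_probes: int = 1_000
    n_rs_control_probes: int = 65
    n_detection_fail_probes: int = 50

    category_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_SIZES))
    burden_per_category: Mapping[str, Tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BURDEN))
    fraction_hyper: float = 0.68  # 2,983 of 4,399 detected outliers were hyper

    hyper_delta: Tuple[float, float] = (0.18, 0.11)   # mean, sd of injected +Δβ
    hypo_delta: Tuple[float, float] = (-0.27, 0.12)   # mean, sd of injected -Δβ
    min_abs_delta: float = 0.01
    cluster_length_geom_p: float = 0.45  # run length ~ 2 + Geom(p), capped
    max_cluster_length: int = 8

    promoter_beta_low: Tuple[float, float] = (0.02, 0.07)
    opensea_beta_high: Tuple[float, float] = (0.87, 0.97)
    fraction_intermediate: float = 0.05  # probes drawn from a mid-β component
    promoter_logit_sd: Tuple[float, float] = (0.05, 0.15)
    opensea_logit_sd: Tuple[float, float] = (0.10, 0.30)

    batch_labels: Tuple[str, ...] = ("batch1", "batch2")
    batch_logit_shift: Tuple[float, ...] = (0.0, 0.25)
    batch_logit_scale: Tuple[float, ...] = (1.0, 1.10)

    asm_fraction: float = 0.05  # of SNP-flagged probes showing trimodal ASM
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived -------------------------------------------------------
    @property
    def cohort_size(self) -> int:
        return sum(self.category_sizes.values())

    def layout(self) -> list[Tuple[str, int]]:
        """Autosomal probe counts per chromosome (explicit or size-proportional)."""
        if self.chromosome_layout is not None:
            return [(str(c), int(n)) for c, n in self.chromosome_layout]
        total_mb = sum(_CHROM_MB.values())
        counts = {c: int(round(self.n_probes * mb / total_mb))
                  for c, mb in _CHROM_MB.items()}
        # pin the total exactly to n_probes
        drift = self.n_probes - sum(counts.values())
        counts["1"] += drift
        return [(c, counts[c]) for c in _CHROM_MB]

    # -- validation ----------------------------------------------------
    def validate(self) -> None:
        for name in ("fraction_cgi_promoter", "fraction_snp_flagged",
                     "fraction_hyper", "fraction_intermediate", "asm_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_probes", "n_sex_chrom_probes", "n_rs_control_probes",
                     "n_detection_fail_probes"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_probes == 0:
            raise ValueError("n_probes must be positive")
        if set(self.category_sizes) != set(CATEGORIES):
            raise ValueError("category_sizes must cover exactly the six "
                             f"categories {CATEGORIES}")
        if any(n < 0 for n in self.category_sizes.values()):
            raise ValueError("category sizes must be >= 0")
        for cat, (lo, hi) in self.burden_per_category.items():
            if lo < 0 or hi < lo:
                raise ValueError(f"burden range for {cat} must satisfy 0 <= min <= max")
        if not (len(self.batch_labels) == len(self.batch_logit_shift)
                == len(self.batch_logit_scale)):
            raise ValueError("batch_labels, batch_logit_shift and batch_logit_scale "
                             "must have equal length")
        if self.hyper_delta[0] <= 0:
            raise ValueError("hyper_delta mean must be positive")
        if self.hypo_delta[0] >= 0:
            raise ValueError("hypo_delta mean must be negative")
        if not 0 < self.cluster_length_geom_p < 1:
            raise ValueError("cluster_length_geom_p must be in (0, 1)")
        if self.max_cluster_length < 2:
            raise ValueError("max_cluster_length must be >= 2 (clusters are runs of >= 2)")

    # -- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["category_sizes"] = dict(self.category_sizes)
        d["burden_per_category"] = {k: list(v) for k, v in self.burden_per_category.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "burden_per_category" in d:
            d["burden_per_category"] = {k: tuple(v) for k, v in d["burden_per_category"].items()}
        for key in ("hyper_delta", "hypo_delta", "promoter_beta_low", "opensea_beta_high",
                    "promoter_logit_sd", "opensea_logit_sd", "batch_labels",
                    "batch_logit_shift", "batch_logit_scale"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
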