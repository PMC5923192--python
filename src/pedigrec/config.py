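"""Configuration objects for simulation, QC and the pipeline."""
from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import yaml


@dataclass(frozen=True)
class SimConfig:
    """Conditions for the synthetic three-generation cohort generator.

    The defaults emulate a dairy-cattle pedigree study at desk scale:
    sex-specific genome lengths of 24.8 (male) and 22.5 (female)
    expected crossovers per meiosis, a small fraction of hotspot
    intervals with strongly elevated intensity, a mixture of a
    full-density and a reduced-density SNP panel (75.7% / 24.3% of
    animals), 0.2% genotyping error and 1% missing calls.

    ``seed`` fully determines the output.
    """

    seed: int
    n_chromosomes: int = 10
    snps_per_chromosome: int = 400
    chromosome_length_bp: int = 100_000_000
    n_families: int = 250                       # per breed
    breeds: tuple = ("jersey", "brown_swiss", "ayrshire")
    male_map_length: float = 24.8               # expected crossovers / meiosis
    female_map_length: float = 22.5
    hotspot_fraction: float = 0.02              # share of intervals designated hot
    hotspot_multiplier: float = 20.0            # hot intensity = multiplier x baseline
    panels: tuple = ((1.0, 0.757), (0.5, 0.243))  # (fraction of SNPs, share of animals)
    genotyping_error_rate: float = 0.002
    missing_rate: float = 0.01
    male_donor_fraction: float = 0.5

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.male_map_length <= 0 or self.female_map_length <= 0:
            raise ValueError("genome map lengths must be positive")
        if self.n_families < 1:
            raise ValueError("at least one family per breed is required")
        if not self.breeds:
            raise ValueError("at least one breed is required")
        for p in (
            self.hotspot_fraction,
            self.genotyping_error_rate,
            self.missing_rate,
            self.male_donor_fraction,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.hotspot_multiplier <= 0:
            raise ValueError("hotspot multiplier must be positive")
        n_int = self.snps_per_chromosome - 1
        if self.hotspot_fraction > 0 and self.hotspot_fraction * n_int < 1:
            raise ValueError(
                "hotspot_fraction designates no interval per chromosome; "
                "use 0 or a larger fraction"
            )
        total = sum(w for _, w in self.panels)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("panel proportions must sum to 1")
        for frac, _ in self.panels:
            if not 0.0 < frac <= 1.0:
                raise ValueError("panel SNP fractions must be in (0, 1]")

    def replace(self, **kw) -> "SimConfig":
        return replace(self, **kw)

    def map_length(self, sex: str) -> float:
        return self.male_map_length if sex == "M" else self.female_map_length


@dataclass(frozen=True)
class QcConfig:
    """Meiosis-level quality control.

    ``max_crossovers``: meioses with strictly more genome-wide
    crossovers are removed (boundary retained).  ``min_support``:
    minimum number of consecutive informative sites required to accept
    a haplotype-template switch; shorter runs are treated as genotyping
    error and masked.  ``max_mendel_rate``: families whose donor shows
    a higher fraction of Mendelian-error sites are dropped.
    """

    max_crossovers: int = 45
    min_support: int = 2
    max_mendel_rate: float = 0.02

    def __post_init__(self):
        if self.max_crossovers < 1 or self.min_support < 1:
            raise ValueError("QC thresholds must be positive integers")


@dataclass(frozen=True)
class HotspotCriteria:
    """Hotspot rule: rate > mean + multiplier x SD of interval rates."""

    multiplier: float = 2.5

    def __post_init__(self):
        if self.multiplier <= 0:
            raise ValueError("hotspot multiplier must be > 0")


def _to_plain(obj):
    d = asdict(obj)
    for k, v in d.items():
        if isinstance(v, tuple):
            d[k] = [list(x) if isinstance(x, tuple) else x for x in v]
    return d


def sim_config_to_yaml(cfg: SimConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=True)


def sim_config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "seed" not in raw:
        raise ValueError("config file must set a seed")
    if "breeds" in raw:
        raw["breeds"] = tuple(raw["breeds"])
    if "panels" in raw:
        raw["panels"] = tuple(tuple(p) for p in raw["panels"])
    return SimConfig(**raw)
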