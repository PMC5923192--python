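"""Synthetic genotyped three-generation cohorts with known crossover truth.

The generator draws unlinked founder genotypes, transmits gametes down
a three-generation pedigree with a Poisson crossover process whose
per-interval intensity comes from a sex-specific "true" map (optionally
with hotspot enrichment), and degrades the resulting genotypes with
panel-density reduction, symmetric genotyping error and missingness.
Every analyzed meiosis (donor parent -> offspring) is recorded in a
truth table so downstream detection can be scored exactly.

Each family contains five genotyped animals: grandsire and granddam
(founders), the donor parent (their child), the donor's mate (an
unrelated founder) and one offspring.  Crossovers are recorded only for
the donor -> offspring meiosis, the one the pedigree analysis can see.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .config import SimConfig
from .io import Cohort, MarkerMap, GENO_MISSING

SEXES = ("M", "F")


@dataclass
class TrueMap:
    """Sex-specific expected crossovers per SNP interval.

    ``intensity[sex]`` is a per-SNP-row vector (0 on the first SNP of
    each chromosome, matching the map-file convention); its genome-wide
    sum is the expected crossover count per meiosis for that sex.
    ``hot_rows`` flags the rows whose interval was designated a hotspot.
    """

    markers: MarkerMap
    intensity: dict
    hot_rows: np.ndarray

    def genome_length(self, sex: str) -> float:
        return float(self.intensity[sex].sum())

    def chrom_totals(self, sex: str) -> np.ndarray:
        lam = self.intensity[sex]
        return np.array([lam[sl].sum() for _, sl in self.markers.chrom_slices()])


class SimResult(NamedTuple):
    cohort: Cohort
    truth: pd.DataFrame      # meiosis, donor, offspring, sex, chrom, bp
    true_map: TrueMap


def _substreams(seed: int):
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(3)
    return (np.random.default_rng(k) for k in kids)


def _make_markers(config: SimConfig, rng: np.random.Generator) -> MarkerMap:
    """Irregularly spaced, strictly increasing positions per chromosome."""
    rows = []
    m = config.snps_per_chromosome
    L = config.chromosome_length_bp
    for c in range(1, config.n_chromosomes + 1):
        base = np.linspace(L / m, L, m)
        gap = L / m
        jitter = rng.uniform(-0.45 * gap, 0.45 * gap, size=m)
        bp = np.round(base + jitter).astype(np.int64)
        bp = np.maximum.accumulate(bp)
        bp += np.arange(m)  # enforce strict increase after rounding
        rows.append(pd.DataFrame({
            "name": [f"snp{c}_{i + 1}" for i in range(m)],
            "chrom": c,
            "bp": bp,
        }))
    return MarkerMap(pd.concat(rows, ignore_index=True))


def make_true_map(config: SimConfig, markers: MarkerMap | None = None) -> TrueMap:
    """Build the sex-specific true map for ``config``.

    Every SNP interval carries the same baseline intensity; a
    per-chromosome random subset of intervals (``hotspot_fraction``)
    is multiplied by ``hotspot_multiplier`` before per-sex
    renormalization to the configured genome lengths.
    """
    rng_mark, rng_map, _ = _substreams(config.seed)
    if markers is None:
        markers = _make_markers(config, rng_mark)

    base = markers.has_interval.astype(float)
    hot = np.zeros(markers.n_snps, dtype=bool)
    if config.hotspot_fraction > 0:
        for _, sl in markers.chrom_slices():
            rows = np.flatnonzero(markers.has_interval[sl]) + sl.start
            n_hot = max(1, int(round(config.hotspot_fraction * rows.size)))
            hot[rng_map.choice(rows, size=n_hot, replace=False)] = True
    shaped = base.copy()
    shaped[hot] *= config.hotspot_multiplier

    intensity = {}
    total = shaped.sum()
    for sex in SEXES:
        length = config.map_length(sex)
        if length <= 0:
            raise ValueError(f"non-positive map length for sex {sex}")
        intensity[sex] = shaped * (length / total)
    return TrueMap(markers=markers, intensity=intensity, hot_rows=hot)


def simulate_meiosis(haplotypes: np.ndarray, true_map: TrueMap, sex: str,
                     rng: np.random.Generator):
    """Transmit one gamete from a pair of parental haplotypes.

    Per chromosome the crossover count is Poisson with mean equal to the
    chromosome's intensity sum; crossover intervals are drawn with
    probability proportional to intensity and positions uniformly in bp
    within the interval.  The starting haplotype is chosen with
    probability 1/2 independently per chromosome.

    Returns ``(gamete, (chrom, bp))`` where the second element holds the
    realized crossover positions (bp strictly between two adjacent SNPs).
    """
    if sex not in true_map.intensity:
        raise ValueError(f"sex {sex!r} absent from true map")
    mk = true_map.markers
    if haplotypes.shape != (2, mk.n_snps):
        raise ValueError("haplotypes do not match the marker set")
    lam = true_map.intensity[sex]
    chrom_tot = true_map.chrom_totals(sex)
    counts = rng.poisson(chrom_tot)
    total = int(counts.sum())

    starts = rng.integers(0, 2, size=mk.n_chromosomes)
    row_chrom_idx = np.cumsum(mk.first_of_chrom) - 1
    if total == 0:
        gam_idx = starts[row_chrom_idx]
        gamete = np.take_along_axis(
            haplotypes, gam_idx[None, :], axis=0)[0]
        return gamete, (np.empty(0, np.int64), np.empty(0, np.int64))

    # inverse-CDF placement on the concatenated intensity vector
    cum = np.cumsum(lam)
    chrom_base = np.r_[0.0, cum[mk.chrom_end_row[:-1] - 1]]
    chrom_of_x = np.repeat(np.arange(mk.n_chromosomes), counts)
    u = rng.random(total)
    targets = chrom_base[chrom_of_x] + u * chrom_tot[chrom_of_x]
    rows = np.searchsorted(cum, targets, side="right")
    rows = np.minimum(rows, mk.n_snps - 1)
    # row has an interval by construction (first-of-chrom intensity is 0)
    left = mk.bp[rows - 1]
    width = mk.bp[rows] - left
    frac = rng.random(total)
    bp = left + 1 + np.floor(frac * (width - 1)).astype(np.int64)
    bp = np.minimum(bp, mk.bp[rows] - 1)  # strictly between the two SNPs

    gx = mk.genome_coord(mk.chrom[rows], bp)
    order = np.argsort(gx, kind="stable")
    gx = gx[order]
    n_before = np.searchsorted(gx, mk.genome_bp, side="left")
    gam_idx = (starts[row_chrom_idx] + n_before) % 2
    gamete = np.take_along_axis(haplotypes, gam_idx[None, :], axis=0)[0]
    return gamete, (mk.chrom[rows][order], bp[order])


def _founder_haplotypes(freq: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    return (rng.random((2, freq.size)) < freq).astype(np.int8)


def simulate_cohort(config: SimConfig) -> SimResult:
    """Generate the full cohort plus the crossover truth table."""
    rng_mark, rng_map, rng_cohort = _substreams(config.seed)
    markers = _make_markers(config, rng_mark)
    true_map = make_true_map(config, markers=markers)
    rng = rng_cohort

    n = markers.n_snps
    freq = rng.uniform(0.05, 0.95, size=n)

    n_animals_total = 5 * config.n_families * len(config.breeds)
    G = np.empty((n_animals_total, n), dtype=np.int8)
    ped_rows = []
    ids = []
    truth_rows = {"meiosis": [], "donor": [], "offspring": [],
                  "sex": [], "chrom": [], "bp": []}

    def add_animal(aid, sire, dam, sex, breed, haps):
        ped_rows.append((aid, sire, dam, sex, breed))
        np.add(haps[0], haps[1], out=G[len(ids)])
        ids.append(aid)

    for breed in config.breeds:
        n_male = int(round(config.male_donor_fraction * config.n_families))
        for i in range(config.n_families):
            donor_sex = "M" if i < n_male else "F"
            tag = f"{breed}_f{i:05d}"
            gs_id, gd_id = f"{tag}_gs", f"{tag}_gd"
            dn_id, mt_id, of_id = f"{tag}_dn", f"{tag}_mt", f"{tag}_of"

            gs = _founder_haplotypes(freq, rng)
            gd = _founder_haplotypes(freq, rng)
            mt = _founder_haplotypes(freq, rng)
            dn = np.empty((2, n), np.int8)
            dn[0], _ = simulate_meiosis(gs, true_map, "M", rng)
            dn[1], _ = simulate_meiosis(gd, true_map, "F", rng)

            gam_dn, (x_chrom, x_bp) = simulate_meiosis(dn, true_map, donor_sex, rng)
            mate_sex = "F" if donor_sex == "M" else "M"
            gam_mt, _ = simulate_meiosis(mt, true_map, mate_sex, rng)

            off = np.empty((2, n), np.int8)
            if donor_sex == "M":
                off[0], off[1] = gam_dn, gam_mt   # paternal, maternal
            else:
                off[0], off[1] = gam_mt, gam_dn

            add_animal(gs_id, "0", "0", "M", breed, gs)
            add_animal(gd_id, "0", "0", "F", breed, gd)
            add_animal(mt_id, "0", "0", mate_sex, breed, mt)
            add_animal(dn_id, gs_id, gd_id, donor_sex, breed, dn)
            sire, dam = (dn_id, mt_id) if donor_sex == "M" else (mt_id, dn_id)
            add_animal(of_id, sire, dam, "M" if rng.random() < 0.5 else "F",
                       breed, off)

            mid = f"{dn_id}>{of_id}"
            k = len(x_bp)
            truth_rows["meiosis"].extend([mid] * k)
            truth_rows["donor"].extend([dn_id] * k)
            truth_rows["offspring"].extend([of_id] * k)
            truth_rows["sex"].extend([donor_sex] * k)
            truth_rows["chrom"].extend(x_chrom.tolist())
            truth_rows["bp"].extend(x_bp.tolist())

    n_animals = len(ids)

    # panel-density reduction: each panel is a fixed evenly spaced SNP subset
    panel_masks = []
    for frac, _ in config.panels:
        k = max(2, int(round(frac * n)))
        idx = np.unique(np.round(np.linspace(0, n - 1, k)).astype(int))
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        panel_masks.append(mask)
    props = np.array([w for _, w in config.panels])
    assign = rng.choice(len(panel_masks), size=n_animals, p=props / props.sum())

    # degrade in row chunks to bound temporary-array memory
    chunk = max(1, 2_000_000 // max(n, 1))
    for a in range(0, n_animals, chunk):
        b = min(a + chunk, n_animals)
        block = G[a:b]
        typed = np.stack([panel_masks[j] for j in assign[a:b]])
        # symmetric genotyping error: replace by a uniform draw from the other two
        if config.genotyping_error_rate > 0:
            err = (rng.random(block.shape) < config.genotyping_error_rate) & typed
            shift = rng.integers(1, 3, size=int(err.sum()), dtype=np.int8)
            block[err] = (block[err] + shift) % 3
        if config.missing_rate > 0:
            miss = (rng.random(block.shape) < config.missing_rate) & typed
            block[miss] = GENO_MISSING
        block[~typed] = GENO_MISSING

    ped = pd.DataFrame(
        ped_rows, columns=["id", "sire", "dam", "sex", "breed"]
    ).set_index("id")
    cohort = Cohort(ped=ped, markers=markers, genotypes=G, ids=np.array(ids, dtype=object))
    truth = pd.DataFrame(truth_rows)
    return SimResult(cohort=cohort, truth=truth, true_map=true_map)


def truth_counts(truth: pd.DataFrame) -> pd.Series:
    """Realized crossover count per analyzed meiosis."""
    return truth.groupby("meiosis").size()
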