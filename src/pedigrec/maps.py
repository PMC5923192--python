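"""Breed- and sex-specific recombination maps and their comparison.

A map's per-interval rate is the average crossover mass per meiosis in
that adjacent-SNP interval; the genome-wide sum of rates equals the
mean crossover count of the contributing meioses.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from .io import MarkerMap


@dataclass
class RecombinationMap:
    breed: str
    sex: str
    rates: np.ndarray        # per SNP row; 0 on first-of-chromosome rows
    n_meioses: int
    markers: MarkerMap

    @property
    def map_length(self) -> float:
        """Genome length in expected crossovers per meiosis."""
        return float(self.rates.sum())

    def interval_rates(self) -> np.ndarray:
        return self.rates[self.markers.has_interval]


def crossover_rate(total_crossovers: float, n_meioses: int) -> float:
    """Genome-wide recombination rate: total crossovers / meioses."""
    if n_meioses < 1:
        raise ValueError("at least one meiosis is required")
    return total_crossovers / n_meioses


def genome_wide_rate(meioses) -> float:
    """Mean detected crossover mass per meiosis over ``meioses``."""
    meioses = list(meioses)
    return crossover_rate(sum(r.total_mass for r in meioses), len(meioses))


def build_recmap(meioses, markers: MarkerMap, breed: str = "all",
                 sex: str = "all") -> RecombinationMap:
    """Aggregate meioses into a map: rate_i = sum(mass_i) / n_meioses.

    ``meioses`` may be pre-filtered by the caller (breed, sex, density);
    when ``breed``/``sex`` are given they only label the result.
    """
    meioses = list(meioses)
    if not meioses:
        raise ValueError("cannot build a map from zero meioses")
    rates = np.zeros(markers.n_snps, dtype=float)
    for r in meioses:
        np.add.at(rates, r.interval_rows, r.masses)
    rates /= len(meioses)
    return RecombinationMap(breed=breed, sex=sex, rates=rates,
                            n_meioses=len(meioses), markers=markers)


def map_correlation(a: RecombinationMap, b: RecombinationMap) -> float:
    """Pearson correlation of per-interval rates; NaN if degenerate."""
    if a.markers != b.markers:
        raise ValueError("maps are defined on different SNP sets")
    x, y = a.interval_rates(), b.interval_rates()
    if np.ptp(x) == 0 or np.ptp(y) == 0:   # constant map: r undefined
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def equal_sample_correlation(meioses_by_breed: dict, markers: MarkerMap,
                             k: int, n_resample: int,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Mean pairwise map correlation at equalized sample size.

    For each repetition, ``k`` meioses are drawn without replacement
    from every breed, maps rebuilt and correlated; the element-wise
    mean over repetitions is returned.  Removes the sample-size
    imbalance that otherwise drives between-breed correlation
    differences.
    """
    breeds = list(meioses_by_breed)
    for b, recs in meioses_by_breed.items():
        if len(recs) < k:
            raise ValueError(f"breed {b} has {len(recs)} meioses < k={k}")
    acc = np.zeros((len(breeds), len(breeds)))
    for _ in range(n_resample):
        sampled_maps = []
        for b in breeds:
            recs = meioses_by_breed[b]
            idx = rng.choice(len(recs), size=k, replace=False)
            sampled_maps.append(build_recmap([recs[i] for i in idx], markers,
                                             breed=b))
        for i in range(len(breeds)):
            acc[i, i] += 1.0
            for j in range(i + 1, len(breeds)):
                r = map_correlation(sampled_maps[i], sampled_maps[j])
                acc[i, j] += r
                acc[j, i] += r
    return pd.DataFrame(acc / n_resample, index=breeds, columns=breeds)


def position_profile(rmap: RecombinationMap, smoothing: float | None = None,
                     n_points: int = 101, n_bins: int = 100) -> pd.DataFrame:
    """Smoothed recombination rate against relative chromosomal position.

    Each interval contributes (midpoint bp / chromosome length,
    rate per Mb); intervals of all chromosomes are pooled, averaged in
    ``n_bins`` equal relative-position bins, and a cubic smoothing
    spline fitted to the bin means (``smoothing`` is the roughness
    penalty lambda; ``None`` selects it by generalized
    cross-validation, falling back to a mild fixed penalty when the
    GCV criterion has no interior optimum).  Returns the fitted curve
    on a grid of relative positions in [0, 1].
    """
    mk = rmap.markers
    xs, ys = [], []
    for ci, (_, sl) in enumerate(mk.chrom_slices()):
        length = float(mk.chrom_length_bp[ci])
        rows = np.flatnonzero(mk.has_interval[sl]) + sl.start
        mid = (mk.bp[rows] + mk.bp[rows - 1]) / 2.0
        width_mb = mk.interval_bp[rows] / 1e6
        xs.append(mid / length)
        ys.append(rmap.rates[rows] / width_mb)
    x = np.concatenate(xs)
    y = np.concatenate(ys)

    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    filled = counts > 0
    bx = ((edges[:-1] + edges[1:]) / 2.0)[filled]
    by = (np.bincount(which, weights=y, minlength=n_bins)[filled]
          / counts[filled])
    if filled.sum() < 4:
        raise ValueError("too few populated position bins for a spline")
    try:
        spl = make_smoothing_spline(bx, by, lam=smoothing)
    except ValueError:
        if smoothing is not None:
            raise
        # GCV found no interior optimum: mild fixed roughness penalty
        spl = make_smoothing_spline(bx, by, lam=1e-4)
    grid = np.linspace(bx.min(), bx.max(), n_points)
    fitted = spl(grid)
    return pd.DataFrame({"rel_pos": grid, "rate_per_mb": fitted})
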