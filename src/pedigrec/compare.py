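"""Per-interval chi-square scan for breed differences in recombination.

For each SNP interval a 2x2 table [crossover mass, meioses - mass] x
breed is tested with the 1-df Pearson chi-square, Bonferroni-corrected
over the intervals actually tested.  Fractional masses from the even
crossover assignment enter the table directly; because each crossover's
mass is split over the SNP intervals between its flanking informative
sites, per-interval masses vary less than binomial counts and the test
is conservative at SNP-interval resolution (it never overstates
significance).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import MarkerMap
from .maps import build_recmap


def chisq_2x2(xa, na, xb, nb):
    """Vectorized 1-df Pearson chi-square for [x, n - x] x group tables."""
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    a, b = xa, na - xa
    c, d = xb, nb - xb
    n = float(na + nb)
    num = n * (a * d - b * c) ** 2
    den = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(den > 0, num / den, 0.0)
    p = chi2.sf(stat, df=1)
    return stat, p


def interval_chisq_scan(meioses_a, meioses_b, markers: MarkerMap,
                        alpha: float = 0.05,
                        mass_a: np.ndarray | None = None, n_a: int | None = None,
                        mass_b: np.ndarray | None = None, n_b: int | None = None
                        ) -> pd.DataFrame:
    """Scan all intervals for a rate difference between two breeds.

    Sources may be meiosis-record lists or precomputed per-row mass
    vectors with meiosis counts.  Intervals with zero total mass in
    both breeds are recorded as untestable (NaN p) and excluded from
    the Bonferroni denominator.
    """
    if mass_a is None:
        ma = build_recmap(meioses_a, markers)
        mass_a, n_a = ma.rates * ma.n_meioses, ma.n_meioses
    if mass_b is None:
        mb = build_recmap(meioses_b, markers)
        mass_b, n_b = mb.rates * mb.n_meioses, mb.n_meioses

    rows = np.flatnonzero(markers.has_interval)
    xa, xb = mass_a[rows], mass_b[rows]
    testable = (xa + xb) > 0
    stat = np.full(rows.size, np.nan)
    p = np.full(rows.size, np.nan)
    stat[testable], p[testable] = chisq_2x2(xa[testable], n_a,
                                            xb[testable], n_b)
    n_tests = int(testable.sum())
    threshold = alpha / n_tests if n_tests else np.nan
    out = pd.DataFrame({
        "snp": markers.name[rows],
        "chrom": markers.chrom[rows],
        "bp": markers.bp[rows],
        "mass_a": xa, "n_a": n_a, "mass_b": xb, "n_b": n_b,
        "chisq": stat, "p": p,
        "testable": testable,
        "significant": testable & (p < threshold),
    })
    out.attrs["bonferroni_threshold"] = threshold
    out.attrs["n_tests"] = n_tests
    return out


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    if n_tests < 1:
        raise ValueError("need at least one test")
    return alpha / n_tests
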