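"""Scoring detected crossovers against simulation truth.

Detection resolution is the informative interval: between two
consecutive surviving informative sites only the parity of the true
crossover count is observable, and events outside the span of
informative sites are invisible.  The scores here are therefore
defined at that resolution:

* an *expected switch* is an informative interval containing an odd
  number of true crossovers (within the informative span);
* recall   = detected switches that are expected / expected switches;
* precision = detected switches whose informative interval contains at
  least one true crossover / detected switches.

On error-free data with ``min_support=1`` detection must reproduce the
expected switches exactly.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .io import MarkerMap


def score_detection(records, truth: pd.DataFrame, markers: MarkerMap) -> dict:
    """Score records (built with ``keep_sites=True``) against truth."""
    truth_by_meiosis = dict(tuple(truth.groupby("meiosis")))
    n_expected = n_detected = n_hit = n_detected_with_truth = 0
    n_truth = 0
    exact = True

    for rec in records:
        if rec.used_rows is None:
            raise ValueError("records must be built with keep_sites=True")
        used = np.sort(rec.used_rows)
        t = truth_by_meiosis.get(rec.meiosis_id)
        if t is None or len(t) == 0:
            tx = np.empty(0, dtype=np.int64)
        else:
            tx = np.sort(markers.genome_coord(
                t["chrom"].to_numpy(), t["bp"].to_numpy()))
        n_truth += tx.size
        ug = markers.genome_bp[used]
        # truth event at x lies in informative interval j-1..j where j is
        # the first used site with position > x (crossover bp sits strictly
        # between two SNPs); the flanking sites must share a chromosome,
        # otherwise the event is outside the informative span
        j = np.searchsorted(ug, tx, side="left")
        inside = (j > 0) & (j < ug.size)
        same_chrom = np.zeros_like(inside)
        ji = j[inside]
        same_chrom[inside] = markers.chrom[used[ji - 1]] == markers.chrom[used[ji]]
        inside &= same_chrom
        counts = np.bincount(j[inside], minlength=ug.size)
        expected = {(int(used[i - 1]), int(used[i]))
                    for i in np.flatnonzero(counts % 2 == 1)}
        with_truth = {(int(used[i - 1]), int(used[i]))
                      for i in np.flatnonzero(counts > 0)}
        det = {(a, b) for a, b in rec.switch_sites}

        n_expected += len(expected)
        n_detected += len(det)
        n_hit += len(det & expected)
        n_detected_with_truth += len(det & with_truth)
        if det != expected:
            exact = False

    return {
        "n_truth": n_truth,
        "n_expected_switches": n_expected,
        "n_detected": n_detected,
        "recall": n_hit / n_expected if n_expected else float("nan"),
        "precision": (n_detected_with_truth / n_detected
                      if n_detected else float("nan")),
        "exact": exact,
        "spurious_per_meiosis": ((n_detected - n_detected_with_truth)
                                 / max(len(records), 1)),
    }


def truth_interval_counts(truth: pd.DataFrame, markers: MarkerMap) -> np.ndarray:
    """Integer crossover counts per SNP interval row, summed over meioses."""
    counts = np.zeros(markers.n_snps, dtype=np.int64)
    if len(truth) == 0:
        return counts
    gx = markers.genome_coord(truth["chrom"].to_numpy(), truth["bp"].to_numpy())
    rows = np.searchsorted(markers.genome_bp, gx, side="left")
    np.add.at(counts, rows, 1)
    return counts


def truth_rates(truth: pd.DataFrame, markers: MarkerMap, n_meioses: int) -> np.ndarray:
    return truth_interval_counts(truth, markers) / float(n_meioses)
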