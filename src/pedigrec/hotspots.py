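"""Hotspot-region calling and cross-map sharing.

A hotspot region is a SNP interval whose rate exceeds the map mean by
more than ``multiplier`` (default 2.5) population standard deviations.
At typical SNP-panel spacing these regions are tens of kb wide —
coarser than the kb-scale hotspots of human or mouse fine maps, hence
"region".
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .config import HotspotCriteria
from .maps import RecombinationMap


@dataclass
class HotspotSet:
    breed: str
    sex: str
    rows: frozenset            # marker-table row indices of hot intervals
    threshold: float

    @property
    def label(self) -> str:
        return f"{self.breed}_{self.sex}"

    def __len__(self) -> int:
        return len(self.rows)


def call_hotspots(rmap: RecombinationMap,
                  criteria: HotspotCriteria | None = None) -> HotspotSet:
    """Flag intervals with rate > mean + multiplier * SD (strict).

    Mean and SD (population form, n denominator) are taken over all
    intervals, zeros included.
    """
    criteria = criteria or HotspotCriteria()
    rates = rmap.interval_rates()
    if rates.size < 2:
        raise ValueError("hotspot calling needs at least two intervals")
    threshold = float(rates.mean() + criteria.multiplier * rates.std(ddof=0))
    rows = np.flatnonzero(rmap.markers.has_interval)
    hot = rows[rmap.rates[rows] > threshold]
    return HotspotSet(breed=rmap.breed, sex=rmap.sex,
                      rows=frozenset(int(r) for r in hot), threshold=threshold)


def hotspot_sharing(sets) -> dict:
    """Venn-style sharing summary across hotspot sets.

    Returns a dict with the full exclusive ``partition`` (membership
    signature -> count; counts sum to the union size), the all-shared
    core, per-set unique counts, and pairwise intersections excluding
    the core (the "in addition to the common hotspots" convention).
    """
    sets = list(sets)
    if len(sets) < 2:
        raise ValueError("sharing needs at least two hotspot sets")
    labels = [s.label for s in sets]
    if len(set(labels)) != len(labels):
        raise ValueError("hotspot sets must carry distinct breed/sex labels")

    universe = set().union(*(s.rows for s in sets))
    partition: dict = {}
    for item in universe:
        sig = tuple(lab for lab, s in zip(labels, sets) if item in s.rows)
        partition[sig] = partition.get(sig, 0) + 1

    core = set.intersection(*(set(s.rows) for s in sets))
    unique = {lab: partition.get((lab,), 0) for lab in labels}
    pairwise_excl_core = {}
    for (la, sa), (lb, sb) in combinations(zip(labels, sets), 2):
        pairwise_excl_core[(la, lb)] = len((sa.rows & sb.rows) - core)

    return {
        "partition": partition,
        "all_shared": len(core),
        "unique": unique,
        "pairwise_excl_core": pairwise_excl_core,
        "union": len(universe),
    }


def hotspots_to_frame(hs: HotspotSet, rmap: RecombinationMap) -> pd.DataFrame:
    rows = sorted(hs.rows)
    mk = rmap.markers
    return pd.DataFrame({
        "breed": hs.breed, "sex": hs.sex,
        "snp": mk.name[rows], "chrom": mk.chrom[rows], "bp": mk.bp[rows],
        "rate": rmap.rates[rows], "threshold": hs.threshold,
    })
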