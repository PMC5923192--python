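"""Shared fixtures: tiny hand-built objects and mid-size simulated cohorts."""
import numpy as np
import pandas as pd
import pytest

from pedigrec.config import QcConfig, SimConfig
from pedigrec.io import Cohort, MarkerMap
from pedigrec.crossover import detect_meioses, qc_filter_meioses
from pedigrec.families import extract_families
from pedigrec.sim import simulate_cohort


def make_markers(chrom_positions):
    """Build a MarkerMap from {chrom_id: [bp, ...]}."""
    rows = []
    for c, positions in chrom_positions.items():
        for i, bp in enumerate(positions):
            rows.append((f"snp{c}_{i + 1}", c, bp))
    return MarkerMap(pd.DataFrame(rows, columns=["name", "chrom", "bp"]))


def make_cohort(markers, animals):
    """Build a Cohort from [(id, sire, dam, sex, breed, genotypes), ...].

    ``genotypes=None`` leaves the animal in the pedigree but ungenotyped.
    """
    ped = pd.DataFrame(
        [(a[0], a[1], a[2], a[3], a[4]) for a in animals],
        columns=["id", "sire", "dam", "sex", "breed"],
    ).set_index("id")
    genotyped = [(a[0], a[5]) for a in animals if a[5] is not None]
    ids = np.array([g[0] for g in genotyped], dtype=object)
    G = np.array([g[1] for g in genotyped], dtype=np.int8)
    return Cohort(ped=ped, markers=markers, genotypes=G, ids=ids)


@pytest.fixture(scope="session")
def clean_sim():
    """Error-free full-density two-breed cohort at moderate scale."""
    cfg = SimConfig(seed=11, n_chromosomes=6, snps_per_chromosome=250,
                    n_families=150, breeds=("holstein", "jersey"),
                    genotyping_error_rate=0.0, missing_rate=0.0,
                    panels=((1.0, 1.0),))
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_records(clean_sim):
    """Traced meioses of the clean cohort (support filter off, sites kept)."""
    cohort = clean_sim.cohort
    fams, _ = extract_families(cohort, int(0.75 * cohort.markers.n_snps))
    records, dropped = detect_meioses(cohort, fams, QcConfig(min_support=1),
                                      keep_sites=True)
    assert not dropped
    kept, _ = qc_filter_meioses(records)
    return kept
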