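"""Map construction, correlations, equal-sample resampling, profiles."""
import numpy as np
import pandas as pd
import pytest

from pedigrec.config import QcConfig, SimConfig
from pedigrec.crossover import MeiosisRecord, detect_meioses
from pedigrec.families import extract_families
from pedigrec.maps import (RecombinationMap, build_recmap, crossover_rate,
                           equal_sample_correlation, genome_wide_rate,
                           map_correlation, position_profile)
from pedigrec.sim import simulate_cohort
from tests.conftest import make_markers


def rec(rows, masses, donor="d", sex="M", breed="b"):
    rows = np.asarray(rows, np.int32)
    masses = np.asarray(masses, float)
    return MeiosisRecord(donor=donor, offspring="o", sex=sex, breed=breed,
                         interval_rows=rows, masses=masses,
                         n_crossovers=int(round(masses.sum())),
                         donor_informative=0, offspring_informative=0,
                         density=0)


MK10 = make_markers({1: list(range(100, 1200, 100))})  # 11 SNPs, 10 intervals


class TestBuild:
    def test_rate_definition_two_meioses(self):
        m = build_recmap([rec([7], [1.0]), rec([], [])], MK10)
        assert m.rates[7] == pytest.approx(0.5)
        assert m.map_length == pytest.approx(0.5)
        assert (np.delete(m.rates, 7) == 0).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_recmap([], MK10)

    def test_printed_ayrshire_totals_reproduced(self):
        """Total crossovers / meioses with the published Ayrshire male and
        female counts gives 24.8 and 22.5 at one decimal."""
        assert round(crossover_rate(40161, 1620), 1) == 24.8
        assert round(crossover_rate(11821, 526), 1) == 22.5

    def test_genome_wide_rate_equals_mean_mass(self):
        rng = np.random.default_rng(0)
        recs = [rec(rng.integers(1, 11, 3), rng.random(3)) for _ in range(20)]
        expect = np.mean([r.total_mass for r in recs])
        assert genome_wide_rate(recs) == pytest.approx(expect, rel=1e-12)

    def test_merge_property_weighted_average(self):
        rng = np.random.default_rng(1)
        a = [rec(rng.integers(1, 11, 2), rng.random(2)) for _ in range(7)]
        b = [rec(rng.integers(1, 11, 2), rng.random(2)) for _ in range(13)]
        ma, mb = build_recmap(a, MK10), build_recmap(b, MK10)
        mu = build_recmap(a + b, MK10)
        weighted = (7 * ma.rates + 13 * mb.rates) / 20
        np.testing.assert_allclose(mu.rates, weighted, atol=1e-15)

    def test_map_sum_times_n_equals_total_mass(self, clean_records, clean_sim):
        m = build_recmap(clean_records, clean_sim.cohort.markers)
        total = sum(r.total_mass for r in clean_records)
        assert m.map_length * m.n_meioses == pytest.approx(total, rel=1e-9)


class TestCorrelation:
    def make_map(self, rates):
        r = np.r_[0.0, np.asarray(rates, float)]
        return RecombinationMap(breed="b", sex="M", rates=r, n_meioses=1,
                                markers=MK10)

    def test_self_correlation_is_one(self):
        m = self.make_map(np.random.default_rng(2).random(10))
        assert map_correlation(m, m) == pytest.approx(1.0)

    def test_constant_map_undefined(self):
        m = self.make_map(np.random.default_rng(3).random(10))
        c = self.make_map(np.full(10, 0.3))
        assert np.isnan(map_correlation(m, c))

    def test_matches_covariance_formula(self):
        mk = make_markers({1: list(range(1, 1002))})
        rng = np.random.default_rng(4)
        x, y = rng.random(1000), rng.random(1000)
        a = RecombinationMap("a", "M", np.r_[0.0, x], 1, mk)
        b = RecombinationMap("b", "M", np.r_[0.0, y], 1, mk)
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        assert map_correlation(a, b) == pytest.approx(expected, abs=1e-12)

    def test_different_marker_sets_rejected(self):
        m = self.make_map(np.ones(10))
        other = RecombinationMap("b", "M", np.zeros(3), 1,
                                 make_markers({1: [1, 2, 3]}))
        with pytest.raises(ValueError):
            map_correlation(m, other)


@pytest.fixture(scope="module")
def breed_records():
    cfg = SimConfig(seed=31, n_chromosomes=2, snps_per_chromosome=300,
                    n_families=800, breeds=("b1", "b2", "b3"),
                    genotyping_error_rate=0.0, missing_rate=0.0,
                    panels=((1.0, 1.0),), male_donor_fraction=1.0)
    res = simulate_cohort(cfg)
    fams, _ = extract_families(res.cohort, 400)
    records, _ = detect_meioses(res.cohort, fams, QcConfig())
    by_breed = {}
    for r in records:
        by_breed.setdefault(r.breed, []).append(r)
    return res.cohort.markers, by_breed


class TestEqualSample:
    def test_determinism(self, breed_records):
        mk, by_breed = breed_records
        a = equal_sample_correlation(by_breed, mk, k=50, n_resample=1,
                                     rng=np.random.default_rng(5))
        b = equal_sample_correlation(by_breed, mk, k=50, n_resample=1,
                                     rng=np.random.default_rng(5))
        pd.testing.assert_frame_equal(a, b)

    def test_exchangeable_breeds_have_similar_correlations(self, breed_records):
        """All breeds share one true map, so mean off-diagonal
        correlations at equal sample size must agree closely."""
        mk, by_breed = breed_records
        corr = equal_sample_correlation(by_breed, mk, k=500, n_resample=200,
                                        rng=np.random.default_rng(6))
        off = [corr.iloc[i, j] for i in range(3) for j in range(i + 1, 3)]
        assert max(off) - min(off) < 0.02

    def test_k_larger_than_smallest_breed_rejected(self, breed_records):
        mk, by_breed = breed_records
        with pytest.raises(ValueError):
            equal_sample_correlation(by_breed, mk, k=10_000, n_resample=1,
                                     rng=np.random.default_rng(7))

    def test_disjoint_hotspots_lower_correlation(self):
        """Two breeds with disjoint hotspot placements correlate less
        than two sharing the same true map, at the same sample size."""
        def records_for(seed):
            cfg = SimConfig(seed=seed, n_chromosomes=2, snps_per_chromosome=300,
                            n_families=200, breeds=("z",),
                            hotspot_fraction=0.1, hotspot_multiplier=40.0,
                            genotyping_error_rate=0.0, missing_rate=0.0,
                            panels=((1.0, 1.0),), male_donor_fraction=1.0)
            res = simulate_cohort(cfg)
            fams, _ = extract_families(res.cohort, 400)
            recs, _ = detect_meioses(res.cohort, fams, QcConfig())
            return res.cohort.markers, recs

        mk, shared_a = records_for(41)     # same seed -> same hotspots
        _, shared_b = records_for(41)
        _, disjoint = records_for(42)      # different hotspot placement
        rng = np.random.default_rng(8)
        same = equal_sample_correlation({"a": shared_a, "b": shared_b}, mk,
                                        k=150, n_resample=30, rng=rng)
        diff = equal_sample_correlation({"a": shared_a, "c": disjoint}, mk,
                                        k=150, n_resample=30, rng=rng)
        assert diff.loc["a", "c"] < same.loc["a", "b"]


class TestProfile:
    def flat_map(self):
        mk = make_markers({c: list(range(10_000, 1_010_000, 10_000))
                           for c in (1, 2)})
        rates = np.full(mk.n_snps, 0.01)
        rates[mk.first_of_chrom] = 0.0
        return RecombinationMap("b", "M", rates, 1, mk)

    def test_flat_map_gives_constant_curve(self):
        prof = position_profile(self.flat_map())
        assert prof["rate_per_mb"].std() < 0.01 * prof["rate_per_mb"].mean()

    def test_positions_in_unit_interval(self):
        prof = position_profile(self.flat_map())
        assert prof["rel_pos"].between(0, 1).all()

    def test_telomeric_enrichment_detected(self):
        mk = make_markers({c: list(range(10_000, 1_010_000, 10_000))
                           for c in (1, 2)})
        rates = np.full(mk.n_snps, 0.005)
        rates[mk.first_of_chrom] = 0.0
        # enrich the distal 10% of each chromosome
        for _, sl in mk.chrom_slices():
            rows = np.arange(sl.start, sl.stop)
            distal = rows[mk.bp[rows] > 0.9 * mk.bp[rows[-1]]]
            rates[distal] *= 5
        m = RecombinationMap("b", "M", rates, 1, mk)
        prof = position_profile(m)
        at = lambda x: prof.iloc[(prof["rel_pos"] - x).abs().argmin()]["rate_per_mb"]
        assert at(0.95) > at(0.5)
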