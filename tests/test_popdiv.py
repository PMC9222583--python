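"""Coverage standardization, SNP calling, F_st estimator, af-SNP detector."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecomorphdiv import popdiv
from ecomorphdiv.popdiv import SnpRecord
from ecomorphdiv.synthdata import SimConfig, simulate_pool_alleles, simulate_transcripts

from conftest import make_site


def fst_oracle(p1: float, p2: float) -> float:
    """Independent evaluation of (H_T - H_S) / H_T via expected
    heterozygosities written out as 2pq."""
    h1 = 2 * p1 * (1 - p1)
    h2 = 2 * p2 * (1 - p2)
    hs = (h1 + h2) / 2
    pm = (p1 + p2) / 2
    ht = 2 * pm * (1 - pm)
    return 0.0 if ht == 0 else (ht - hs) / ht


class TestStandardizeCoverage:
    def test_subsample_to_target(self):
        site = make_site("t1", 1, [{"A": 20, "C": 5}, {"A": 25}])
        out = popdiv.standardize_coverage([site], target=20, seed=0)
        assert len(out) == 1
        arr = np.asarray(out[0].counts)[:, :4]
        assert (arr.sum(axis=1) == 20).all()
        # without replacement: A count of pool 0 between 15 and 20
        assert 15 <= arr[0, 0] <= 20
        assert arr[0, 2] == 20 - arr[0, 0]

    def test_low_coverage_site_removed(self):
        site = make_site("t1", 2, [{"A": 19}, {"A": 30}])
        assert popdiv.standardize_coverage([site], target=20, seed=0) == []

    def test_exact_coverage_unchanged(self):
        site = make_site("t1", 3, [{"A": 12, "G": 8}, {"C": 20}])
        out = popdiv.standardize_coverage([site], target=20, seed=0)
        assert np.asarray(out[0].counts)[:, :4].sum(axis=1).tolist() == [20, 20]
        assert out[0].counts[0][0] == 12 and out[0].counts[0][3] == 8

    def test_subsample_never_exceeds_original(self, rng):
        sites = []
        for i in range(50):
            counts = rng.integers(0, 30, size=(3, 4))
            sites.append(
                popdiv.SyncRecord(
                    "t", i + 1, "A",
                    tuple(tuple(int(x) for x in row) + (0, 0) for row in counts),
                )
            )
        out = popdiv.standardize_coverage(sites, target=20, seed=3)
        originals = {(r.contig, r.position): np.asarray(r.counts) for r in sites}
        for rec in out:
            sub = np.asarray(rec.counts)[:, :4]
            orig = originals[(rec.contig, rec.position)][:, :4]
            assert (sub <= orig).all()
            assert (sub.sum(axis=1) == 20).all()

    def test_site_order_independent_streams(self):
        sites = [
            make_site("t1", 1, [{"A": 20, "C": 10}]),
            make_site("t1", 2, [{"A": 25, "G": 10}]),
        ]
        fwd = popdiv.standardize_coverage(sites, target=20, seed=7)
        rev = popdiv.standardize_coverage(sites[::-1], target=20, seed=7)
        assert sorted(fwd, key=lambda r: r.position) == sorted(
            rev, key=lambda r: r.position
        )


class TestCallSnps:
    def test_maf_boundary_kept(self):
        # combined 108 A / 12 C over 120 -> MAF exactly 10%, retained
        site = make_site("t1", 1, [{"A": 54, "C": 6}, {"A": 54, "C": 6}])
        snps = popdiv.call_snps([site], maf_threshold=0.10)
        assert len(snps) == 1
        assert snps[0].maf == pytest.approx(0.10)

    def test_below_threshold_discarded(self):
        site = make_site("t1", 1, [{"A": 58, "C": 2}, {"A": 57, "C": 3}])
        assert popdiv.call_snps([site], maf_threshold=0.10) == []

    def test_third_allele_demoted(self):
        site = make_site("t1", 1, [{"A": 50, "C": 8, "G": 5}, {"A": 50, "C": 7}])
        snps = popdiv.call_snps([site], maf_threshold=0.10)
        assert len(snps) == 1
        snp = snps[0]
        assert (snp.major, snp.minor) == ("A", "C")
        assert snp.maf == pytest.approx(15 / 115)

    def test_monomorphic_dropped(self):
        site = make_site("t1", 1, [{"A": 20}, {"A": 20}])
        assert popdiv.call_snps([site]) == []

    def test_tie_broken_by_base_order(self):
        # C and G tie for second; C wins (A < C < G < T)
        site = make_site("t1", 1, [{"A": 40, "C": 10, "G": 10}])
        (snp,) = popdiv.call_snps([site], maf_threshold=0.05)
        assert snp.minor == "C"


class TestPairwiseFst:
    def _snp(self, counts1, counts2):
        return SnpRecord("t", 1, "A", "C", (counts1[0], counts2[0]),
                         (counts1[1], counts2[1]), 0.5)

    def test_alternative_fixation_is_one(self):
        rec = popdiv.pairwise_fst(self._snp((20, 0), (0, 20)), 0, 1)
        assert rec.fst == pytest.approx(1.0, abs=1e-12)

    def test_identical_frequencies_zero(self):
        rec = popdiv.pairwise_fst(self._snp((10, 10), (10, 10)), 0, 1)
        assert rec.fst == pytest.approx(0.0, abs=1e-12)

    def test_hand_evaluated_example(self):
        # p1 = 0.75, p2 = 0.25: pi_within = 0.375, pi_total = 0.5, fst = 0.25
        rec = popdiv.pairwise_fst(self._snp((15, 5), (5, 15)), 0, 1)
        assert rec.pi_within == pytest.approx(0.375)
        assert rec.pi_total == pytest.approx(0.5)
        assert rec.fst == pytest.approx(0.25)

    def test_monomorphic_both_units_zero(self):
        rec = popdiv.pairwise_fst(self._snp((20, 0), (20, 0)), 0, 1)
        assert rec.pi_total == 0.0
        assert rec.fst == 0.0

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        p1=st.floats(0, 1, allow_nan=False),
        p2=st.floats(0, 1, allow_nan=False),
    )
    def test_estimator_matches_oracle(self, p1, p2):
        _, _, fst = popdiv.fst_from_freqs(p1, p2)
        assert fst == pytest.approx(fst_oracle(p1, p2), abs=1e-12)
        if abs(p1 - p2) < 1 and (0 < p1 < 1 or 0 < p2 < 1):
            assert -1e-12 <= fst <= 1 + 1e-12

    def test_oracle_agreement_on_many_random_sites(self, rng):
        freqs = rng.random((1000, 2))
        for p1, p2 in freqs:
            assert popdiv.fst_from_freqs(p1, p2)[2] == pytest.approx(
                fst_oracle(p1, p2), abs=1e-12
            )


class TestMedianMatrix:
    def _snps(self, freq_rows):
        """freq_rows: list of per-pool (major, minor) count tuples."""
        out = []
        for i, pools in enumerate(freq_rows):
            out.append(
                SnpRecord("t", i + 1, "A", "C",
                          tuple(p[0] for p in pools),
                          tuple(p[1] for p in pools), 0.5)
            )
        return out

    def test_median_of_three(self):
        # pool pair with fst {0.1..}: use frequencies giving known fsts
        # p pairs: (1,0) -> 1; (.5,.5) -> 0; (.75,.25) -> .25; median .25
        snps = self._snps(
            [
                [(20, 0), (0, 20)],
                [(10, 10), (10, 10)],
                [(15, 5), (5, 15)],
            ]
        )
        mat = popdiv.median_fst_matrix(snps, 2)
        assert mat.iloc[0, 1] == pytest.approx(0.25)
        assert mat.iloc[0, 0] == 0.0
        assert mat.iloc[0, 1] == mat.iloc[1, 0]

    def test_identical_pools_zero(self):
        snps = self._snps([[(12, 8), (12, 8)], [(5, 15), (5, 15)]])
        assert popdiv.median_fst_matrix(snps, 2).iloc[0, 1] == 0.0


@pytest.fixture(scope="module")
def planted_sim():
    cfg = SimConfig(n_genes=150, af_snp_fraction=0.01, mean_coverage=40,
                    seed=31)
    seqs, _ = simulate_transcripts(cfg)
    sync, truth = simulate_pool_alleles(cfg, seqs)
    std = popdiv.standardize_coverage(sync, 20, seed=31)
    snps = popdiv.call_snps(std, 0.10)
    wood, rock = popdiv.morph_pool_indices(cfg.n_pools_per_morph)
    return cfg, snps, truth, wood, rock


class TestPlantedSimulation:
    def test_within_medians_below_across_medians(self, planted_sim):
        cfg, snps, _, wood, rock = planted_sim
        mat = popdiv.median_fst_matrix(snps, 6)
        within = [mat.iloc[i, j] for grp in (wood, rock)
                  for i in grp for j in grp if i < j]
        across = [mat.iloc[i, j] for i in wood for j in rock]
        assert max(within) < min(across)

    def test_combined_unit_is_sum_of_pools(self, planted_sim):
        cfg, snps, truth, wood, rock = planted_sim
        tab, summary = popdiv.combined_fst_distribution(snps, wood, rock)
        af_called = {(s.contig, s.position) for s in snps} & truth.true_af_snps
        sub = tab.set_index(["contig", "position"]).loc[sorted(af_called)]
        assert np.allclose(sub["fst"], 1.0, atol=1e-12)

    def test_af_detector_recovers_planted_set(self, planted_sim):
        cfg, snps, truth, wood, rock = planted_sim
        flagged = popdiv.detect_af_snps(snps, wood, rock)
        detected = {(s.contig, s.position) for s in flagged if s.af_snp}
        called = {(s.contig, s.position) for s in snps}
        assert detected == truth.true_af_snps & called

    def test_detector_equivalent_to_fst_criterion(self, planted_sim):
        cfg, snps, _, wood, rock = planted_sim
        flagged = popdiv.detect_af_snps(snps, wood, rock)
        for snp in flagged[:400]:
            assert snp.af_snp == popdiv.af_snp_fst_criterion(snp, wood, rock)


class TestCombinedDistribution:
    def test_identical_pools_median_zero(self):
        snps = [
            SnpRecord("t", i, "A", "C", (12,) * 6, (8,) * 6, 0.4)
            for i in range(1, 4)
        ]
        _, summary = popdiv.combined_fst_distribution(snps, [0, 1, 2], [3, 4, 5])
        assert summary["median_fst"] == 0.0

    def test_shared_variation_only_median_near_zero(self):
        # pure shared variation (no morph divergence, no af-SNPs):
        # combined-unit fst reflects binomial sampling only
        cfg = SimConfig(n_genes=100, af_snp_fraction=0.0, morph_fst=0.0,
                        mean_coverage=40, seed=13)
        seqs, _ = simulate_transcripts(cfg)
        sync, _ = simulate_pool_alleles(cfg, seqs)
        std = popdiv.standardize_coverage(sync, 20, seed=13)
        snps = popdiv.call_snps(std, 0.10)
        _, summary = popdiv.combined_fst_distribution(snps, [0, 1, 2], [3, 4, 5])
        assert summary["median_fst"] < 0.02

    def test_af_snp_has_60x_units_and_fst_one(self):
        snp = SnpRecord("t", 1, "A", "C", (20, 20, 20, 0, 0, 0),
                        (0, 0, 0, 20, 20, 20), 0.5)
        tab, _ = popdiv.combined_fst_distribution([snp], [0, 1, 2], [3, 4, 5])
        assert tab["fst"].iloc[0] == pytest.approx(1.0, abs=1e-12)


class TestAfDetector:
    def test_clean_fixation_detected(self):
        snp = SnpRecord("t", 1, "A", "C", (20, 20, 20, 0, 0, 0),
                        (0, 0, 0, 20, 20, 20), 0.5)
        (out,) = popdiv.detect_af_snps([snp], [0, 1, 2], [3, 4, 5])
        assert out.af_snp

    def test_one_polymorphic_pool_rejected(self):
        snp = SnpRecord("t", 1, "A", "C", (19, 20, 20, 0, 0, 0),
                        (1, 0, 0, 20, 20, 20), 0.5)
        (out,) = popdiv.detect_af_snps([snp], [0, 1, 2], [3, 4, 5])
        assert not out.af_snp

    def test_same_allele_both_morphs_rejected(self):
        snp = SnpRecord("t", 1, "A", "C", (20,) * 6, (0,) * 6, 0.0)
        (out,) = popdiv.detect_af_snps([snp], [0, 1, 2], [3, 4, 5])
        assert not out.af_snp

    def test_adding_af_snp_cannot_decrease_across_median(self, planted_sim):
        cfg, snps, _, wood, rock = planted_sim
        _, before = popdiv.combined_fst_distribution(snps, wood, rock)
        extra = SnpRecord("extra", 1, "A", "C", (20, 20, 20, 0, 0, 0),
                          (0, 0, 0, 20, 20, 20), 0.5)
        _, after = popdiv.combined_fst_distribution(snps + [extra], wood, rock)
        assert after["median_fst"] >= before["median_fst"]
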