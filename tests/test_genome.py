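"""Genome-scale divergence: filtering, lifting, windowed theta, admixture
EM and genotype PCA."""

import itertools

import numpy as np
import pytest

from invdiverge import genome, simulate
from invdiverge.genome import (
    ChromosomeMap,
    ContigPlacement,
    VariantFilterSpec,
    VariantRecord,
)
from oracles import wc_components_biallelic


def variant(contig, pos, gts, gqs=None, qual=500.0, ref="A", alts=("C",)):
    gts = np.asarray(gts, dtype=np.int8)
    gqs = np.full(gts.shape, 99.0) if gqs is None else np.asarray(gqs, float)
    return VariantRecord(contig, pos, ref, tuple(alts), qual, gts, gqs)


class TestFilterVariants:
    def test_toy_cascade(self):
        # six hand-written sites; manual application of each rule keeps
        # positions 1 and 12000 only
        g_clean = [0, 1, 2, 0]
        records = [
            variant("s1", 1, g_clean),
            variant("s1", 3000, g_clean, alts=("C", "G")),  # triallelic
            variant("s1", 5000, g_clean),  # clean but within 10 kb of pos 1
            variant("s1", 7000, g_clean, qual=399.0),
            variant("s1", 9000, g_clean, gqs=[5, 5, 99, 99]),  # 2 missing
            variant("s1", 12000, g_clean),
        ]
        kept = genome.filter_variants(records)
        assert [r.position for r in kept] == [1, 12000]

    def test_empty_input(self):
        assert genome.filter_variants([]) == []

    def test_clean_spread_sites_pass_unchanged(self):
        records = [variant("s1", 1 + 10_000 * i, [0, 1, 2, 0]) for i in range(5)]
        assert genome.filter_variants(records) == records

    def test_gq_masking_precedes_missingness(self):
        # one genotype masked -> exactly 1 missing -> survives
        r = variant("s1", 1, [0, 1, 2, 0], gqs=[5, 99, 99, 99])
        (kept,) = genome.filter_variants([r])
        assert kept.genotypes[0] == -1 and (kept.genotypes[1:] >= 0).all()

    def test_thinning_is_per_contig(self):
        records = [
            variant("s1", 1, [0, 1]),
            variant("s1", 5000, [0, 1]),
            variant("s2", 5000, [0, 1]),
        ]
        kept = genome.filter_variants(records)
        assert [(r.contig, r.position) for r in kept] == [("s1", 1), ("s2", 5000)]

    def test_unsorted_input_rejected(self):
        records = [variant("s1", 100, [0, 1]), variant("s1", 50, [0, 1])]
        with pytest.raises(ValueError, match="sorted"):
            genome.filter_variants(records)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        records = [
            variant(
                "s1",
                int(p),
                rng.integers(0, 3, 6),
                gqs=rng.integers(0, 99, 6).astype(float),
                qual=float(rng.uniform(300, 900)),
            )
            for p in np.sort(rng.choice(200_000, 80, replace=False) + 1)
        ]
        once = genome.filter_variants(records)
        assert genome.filter_variants(once) == once


class TestLifting:
    CMAP = ChromosomeMap(
        {
            "s1": ContigPlacement("2", 0, "+", 1000),
            "s2": ContigPlacement("2", 1000, "-", 500),
        }
    )

    def test_forward_offset_zero_is_identity(self):
        out = genome.lift_coordinates(variant("s1", 7, [0]), self.CMAP)
        assert (out.contig, out.position) == ("2", 7)

    def test_reverse_orientation_arithmetic(self):
        out = genome.lift_coordinates(variant("s2", 1, [0]), self.CMAP)
        assert (out.contig, out.position) == ("2", 1500)
        out = genome.lift_coordinates(variant("s2", 500, [0]), self.CMAP)
        assert out.position == 1001

    def test_unmapped_contig_goes_to_unplaced_bin(self):
        out = genome.lift_coordinates(variant("s9", 5, [0]), self.CMAP)
        assert out.contig == genome.UNPLACED

    def test_overlapping_placements_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            ChromosomeMap(
                {
                    "a": ContigPlacement("2", 0, "+", 1000),
                    "b": ContigPlacement("2", 500, "+", 1000),
                }
            )

    def test_lift_records_sorts_and_partitions(self):
        records = [variant("s2", 10, [0]), variant("s1", 5, [0]), variant("s9", 1, [0])]
        placed, unplaced = genome.lift_records(records, self.CMAP)
        assert [r.position for r in placed] == sorted(r.position for r in placed)
        assert len(unplaced) == 1


class TestThetaSite:
    def test_fixed_difference(self):
        *_, theta = genome.wc_theta_site([0] * 5, [2] * 5)
        assert theta == pytest.approx(1.0)

    def test_identical_groups_nonpositive(self):
        g = [0, 1, 2, 1, 0]
        *_, theta = genome.wc_theta_site(g, g)
        assert theta <= 0

    def test_shared_monomorphic_undefined(self):
        a, b, c, theta = genome.wc_theta_site([0, 0, 0], [0, 0])
        assert (a, b, c) == (0, 0, 0) and np.isnan(theta)

    def test_hand_configuration_matches_oracle(self):
        # nA=nB=5, pA=0.1 (one het), pB=0.9 (one het)
        gA = [1, 0, 0, 0, 0]
        gB = [1, 2, 2, 2, 2]
        a, b, c, theta = genome.wc_theta_site(gA, gB)
        ea, eb, ec = wc_components_biallelic((4, 1, 0), (0, 1, 4))
        assert (a, b, c) == pytest.approx((ea, eb, ec), abs=1e-12)
        assert theta == pytest.approx(ea / (ea + eb + ec), abs=1e-12)

    def test_exhaustive_small_counts_match_oracle(self):
        # every genotype-count configuration with n <= 3 per group
        def configs(nmax):
            for n in range(1, nmax + 1):
                for n00 in range(n + 1):
                    for n01 in range(n - n00 + 1):
                        yield n00, n01, n - n00 - n01

        for ca, cb in itertools.product(list(configs(3)), repeat=2):
            gA = [0] * ca[0] + [1] * ca[1] + [2] * ca[2]
            gB = [0] * cb[0] + [1] * cb[1] + [2] * cb[2]
            if len(gA) + len(gB) <= 2:
                continue
            a, b, c, _ = genome.wc_theta_site(gA, gB)
            ea, eb, ec = wc_components_biallelic(ca, cb)
            assert a == pytest.approx(ea, abs=1e-12)
            assert b == pytest.approx(eb, abs=1e-12)
            assert c == pytest.approx(ec, abs=1e-12)

    def test_missing_genotypes_reduce_sample_size(self):
        a1 = genome.wc_theta_site([0, 0, 1, -1], [2, 2, 2])
        a2 = genome.wc_theta_site([0, 0, 1], [2, 2, 2])
        assert a1 == pytest.approx(a2, nan_ok=True)


class TestWindowedFst:
    SAMPLES = ["a1", "a2", "b1", "b2"]

    def window(self, records, **kw):
        return genome.windowed_fst(records, self.SAMPLES, ["a1", "a2"], ["b1", "b2"], **kw)

    def test_fixed_differences_give_unit_windows(self):
        records = [variant("2", p, [0, 0, 2, 2]) for p in (100, 6000, 20_001)]
        wins = self.window(records)
        assert [w.fst for w in wins] == pytest.approx([1.0, 1.0, 1.0])
        assert [(w.start, w.end) for w in wins] == [(0, 5000), (5000, 10000), (20000, 25000)]

    def test_single_snv_window_equals_site_theta(self):
        gts = [0, 1, 2, 1]
        (win,) = self.window([variant("2", 777, gts)])
        *_, theta = genome.wc_theta_site(gts[:2], gts[2:])
        assert win.fst == pytest.approx(theta)

    def test_every_snv_in_exactly_one_window(self):
        rng = np.random.default_rng(1)
        records = [
            variant("2", int(p), rng.integers(0, 3, 4))
            for p in np.sort(rng.choice(100_000, 200, replace=False) + 1)
        ]
        wins = self.window(records)
        assert sum(w.n_snvs for w in wins) == len(records)
        for w in wins:
            inside = [r for r in records if w.start < r.position <= w.end]
            assert len(inside) == w.n_snvs

    def test_unknown_sample_errors(self):
        with pytest.raises(ValueError, match="unknown sample"):
            genome.windowed_fst([variant("2", 1, [0] * 4)], self.SAMPLES, ["zz"], ["b1"])

    def test_boundary_positions(self):
        # position 5000 belongs to window [0, 5000); 5001 to [5000, 10000)
        wins = self.window([variant("2", 5000, [0, 0, 2, 2]), variant("2", 5001, [0, 0, 2, 2])])
        assert [(w.start, w.end) for w in wins] == [(0, 5000), (5000, 10000)]


class TestMeanFst:
    def mk(self, chrom, start, num, den, n=1):
        return genome.WindowFst(chrom, start, start + 5000, n, num, den)

    def test_unit_windows_mean_one_under_both_weightings(self):
        wins = [self.mk("2", 0, 2.0, 2.0), self.mk("2", 5000, 1.0, 1.0)]
        for w in ("mean_of_windows", "ratio_of_sums"):
            assert genome.mean_fst(wins, weighting=w) == pytest.approx(1.0)

    def test_hand_set_components(self):
        wins = [self.mk("2", 0, 1.0, 4.0), self.mk("2", 5000, 3.0, 4.0)]
        assert genome.mean_fst(wins, weighting="mean_of_windows") == pytest.approx(0.5)
        assert genome.mean_fst(wins, weighting="ratio_of_sums") == pytest.approx(0.5)
        wins[1] = self.mk("2", 5000, 3.0, 12.0)
        assert genome.mean_fst(wins, weighting="mean_of_windows") == pytest.approx(0.25)
        assert genome.mean_fst(wins, weighting="ratio_of_sums") == pytest.approx(0.25)

    def test_scope_filters(self):
        wins = [self.mk("2", 0, 1.0, 1.0), self.mk("X", 0, 0.0, 1.0)]
        assert genome.mean_fst(wins, {"X"}) == 0.0
        with pytest.raises(ValueError, match="empty scope"):
            genome.mean_fst(wins, {"3"})


class TestAdmixtureEM:
    def test_forced_assignment(self):
        # two source clusters fixed for opposite alleles
        G = np.array([[2] * 50, [2] * 50, [0] * 50, [0] * 50])
        est = genome.admixture_em(G, K=2, seed=0, n_restarts=2)
        assert est.q[0] == pytest.approx([1, 0], abs=0.01)
        assert est.q[2] == pytest.approx([0, 1], abs=0.01)

    def test_q_rows_sum_to_one(self):
        rng = np.random.default_rng(2)
        G = rng.integers(0, 3, (6, 120))
        est = genome.admixture_em(G, K=2, seed=1, n_restarts=2, max_iter=300)
        assert est.q.sum(axis=1) == pytest.approx(np.ones(6), abs=1e-9)

    def test_loglik_monotone(self):
        rng = np.random.default_rng(3)
        G = rng.integers(0, 3, (8, 200))
        est = genome.admixture_em(G, K=2, seed=4, n_restarts=1, max_iter=500)
        diffs = np.diff(est.log_likelihood_trace)
        assert (diffs >= -1e-8 * abs(est.log_likelihood)).all()

    def test_individual_permutation_symmetry(self):
        rng = np.random.default_rng(5)
        G = np.vstack([rng.integers(0, 3, (3, 80)), 2 - rng.integers(0, 3, (3, 80))])
        perm = [3, 4, 5, 0, 1, 2]
        e1 = genome.admixture_em(G, K=2, seed=6, n_restarts=2, max_iter=400)
        e2 = genome.admixture_em(G[perm], K=2, seed=6, n_restarts=2, max_iter=400)
        # after aligning cluster labels, permuting individuals permutes q rows
        q1, q2 = e1.q, e2.q[np.argsort(perm)]
        if not np.allclose(q1, q2, atol=1e-4):
            q2 = q2[:, ::-1]  # label anchoring may flip cluster order
        assert np.allclose(q1, q2, atol=1e-4)

    def test_missing_genotypes_tolerated(self):
        G = np.array([[2, 2, -1, 2], [2, -1, 2, 2], [0, 0, 0, -1], [0, 0, -1, 0]])
        est = genome.admixture_em(G, K=2, seed=0, n_restarts=2)
        assert est.q.sum(axis=1) == pytest.approx(np.ones(4), abs=1e-9)

    def test_too_few_individuals(self):
        with pytest.raises(ValueError, match="at least"):
            genome.admixture_em(np.array([[0, 1, 2]]), K=2)


class TestGenotypePCA:
    def test_two_groups_separate_with_opposite_signs_on_pc1(self):
        rng = np.random.default_rng(7)
        A = rng.binomial(2, 0.1, (5, 300))
        B = rng.binomial(2, 0.9, (5, 300))
        res = genome.genotype_pca(np.vstack([A, B]))
        pc1 = res.scores[:, 0]
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()

    def test_duplicated_sample_gets_identical_scores(self):
        rng = np.random.default_rng(8)
        G = rng.integers(0, 3, (5, 100))
        G = np.vstack([G, G[0]])
        res = genome.genotype_pca(G)
        assert res.scores[0] == pytest.approx(res.scores[-1], abs=1e-8)

    def test_percent_variance_sums_to_100(self):
        rng = np.random.default_rng(9)
        res = genome.genotype_pca(rng.integers(0, 3, (6, 50)))
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-9)

    def test_monomorphic_input_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            genome.genotype_pca(np.ones((4, 10)))

    def test_admixed_individual_intermediate_on_pc1(self):
        spec = simulate.GenomeSimSpec(
            chromosomes={"2": 5_000_000, "3": 5_000_000},
            snv_spacing_bp=2_000,
            admixed_q=(0.5, 0.5),
            seed=13,
        )
        samples, recs, cmap, truth = simulate.simulate_genotypes(spec)
        G = genome.genotype_matrix(recs)
        res = genome.genotype_pca(G)
        pc1 = res.scores[:, 0]
        lo, hi = sorted([pc1[:5].mean(), pc1[5:10].mean()])
        assert lo < pc1[10] < hi and lo < pc1[11] < hi


class TestVcfIO:
    def test_vcf_round_trip(self, tmp_path):
        spec = simulate.GenomeSimSpec(
            chromosomes={"2": 2_000_000}, snv_spacing_bp=5_000, seed=21
        )
        samples, recs, cmap, _ = simulate.simulate_genotypes(spec)
        path = tmp_path / "x.vcf"
        simulate.write_vcf(samples, recs, path)
        samples2, recs2 = genome.read_vcf(path)
        assert samples2 == samples
        assert len(recs2) == len(recs)
        for r1, r2 in zip(recs, recs2):
            assert (r1.contig, r1.position, r1.ref, r1.alts) == (
                r2.contig,
                r2.position,
                r2.ref,
                r2.alts,
            )
            assert np.array_equal(r1.genotypes, r2.genotypes)
            assert r1.quality == pytest.approx(r2.quality, abs=0.05)
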