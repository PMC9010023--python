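"""Window arithmetic, variant filtering, harmonization, LD, and clumping."""

import numpy as np
import pandas as pd
import pytest

from cismr.instruments import (
    HarmonizedCandidates,
    LDMatrix,
    MonomorphicVariantError,
    clump,
    define_cis_window,
    estimate_ld,
    filter_variants,
    harmonize,
)
from cismr.simulate import GenotypePanel, simulate_genotypes
from cismr.sumstats import GeneAnnotation, SummaryStatsTable, VariantAssoc


class TestCisWindow:
    def test_flank_extends_gene_body(self):
        g = GeneAnnotation("G", "P", "1", 1_000_000, 1_050_000)
        w = define_cis_window(g, 200_000)
        assert (w.start, w.end) == (800_000, 1_250_000)
        assert w.span == 450_001  # gene length + 2*200 kbp + 1

    def test_start_clamped_at_one(self):
        g = GeneAnnotation("G", "P", "1", 100_000, 120_000)
        w = define_cis_window(g, 200_000)
        assert w.start == 1

    def test_zero_flank_is_gene_body(self):
        g = GeneAnnotation("G", "P", "1", 500, 900)
        w = define_cis_window(g, 0)
        assert (w.start, w.end) == (500, 900)

    def test_strand_canonicalization_feeds_window(self):
        g = GeneAnnotation("G", "P", "1", 900, 500, strand="-")
        w = define_cis_window(g, 100)
        assert (w.start, w.end) == (400, 1000)


def stats_table(rows, trait_type="continuous", trait_id="t"):
    df = pd.DataFrame(
        rows,
        columns=[
            "variant_id", "chrom", "pos", "effect_allele", "other_allele",
            "eaf", "beta", "se", "pval",
        ],
    )
    return SummaryStatsTable(trait_id, trait_type, df)


class TestFilterVariants:
    def setup_method(self):
        self.window = define_cis_window(
            GeneAnnotation("G", "P", "1", 1000, 2000), 500
        )

    def test_low_maf_high_eaf_and_indel_excluded(self):
        exposure = stats_table([
            ["v1", "1", 1100, "A", "G", 0.995, 0.1, 0.05, 1e-5],  # MAF 0.005
            ["v2", "1", 1200, "AT", "G", 0.30, 0.1, 0.05, 1e-5],  # indel
            ["v3", "1", 1300, "A", "G", 0.30, 0.1, 0.05, 1e-5],   # kept
            ["v4", "1", 9999, "A", "G", 0.30, 0.1, 0.05, 1e-5],   # outside
            ["v5", "1", 1400, "A", "G", np.nan, 0.1, 0.05, 1e-5], # no EAF
        ])
        outcome = stats_table([
            ["v1", "1", 1100, "A", "G", 0.99, 0.0, 0.05, 0.9],
            ["v2", "1", 1200, "AT", "G", 0.30, 0.0, 0.05, 0.9],
            ["v3", "1", 1300, "A", "G", 0.31, 0.0, 0.05, 0.9],
            ["v5", "1", 1400, "A", "G", 0.30, 0.0, 0.05, 0.9],
        ], trait_type="binary")
        got = filter_variants(exposure, outcome, self.window, maf_min=0.01)
        assert list(got["variant_id_x"]) == ["v3"]

    def test_variant_absent_from_outcome_excluded(self):
        exposure = stats_table([
            ["v1", "1", 1100, "A", "G", 0.3, 0.1, 0.05, 1e-5],
            ["v2", "1", 1200, "C", "T", 0.3, 0.1, 0.05, 1e-5],
        ])
        outcome = stats_table(
            [["v1", "1", 1100, "A", "G", 0.3, 0.0, 0.05, 0.9]],
            trait_type="binary",
        )
        got = filter_variants(exposure, outcome, self.window, 0.01)
        assert list(got["variant_id_x"]) == ["v1"]

    def test_maf_exactly_at_floor_excluded(self):
        exposure = stats_table(
            [["v1", "1", 1100, "A", "G", 0.01, 0.1, 0.05, 1e-5]]
        )
        outcome = stats_table(
            [["v1", "1", 1100, "A", "G", 0.01, 0.0, 0.05, 0.9]],
            trait_type="binary",
        )
        assert filter_variants(exposure, outcome, self.window, 0.01).empty


def assoc(ea, oa, beta=0.2, eaf=0.3, pos=100):
    return VariantAssoc("v", "1", pos, ea, oa, eaf, beta, 0.05, 0.01)


class TestHarmonize:
    def test_identical_allele_pair_unchanged(self):
        ex, out = harmonize(assoc("A", "G"), assoc("A", "G", beta=0.5))
        assert out.beta == 0.5

    def test_swapped_alleles_flip_beta_and_complement_eaf(self):
        ex, out = harmonize(assoc("A", "G"), assoc("G", "A", beta=0.2, eaf=0.3))
        assert out.beta == pytest.approx(-0.2)
        assert out.eaf == pytest.approx(0.7)
        assert (out.effect_allele, out.other_allele) == ("A", "G")

    def test_incompatible_alleles_dropped_with_reason(self):
        assert harmonize(assoc("A", "G"), assoc("A", "C")) == "allele_mismatch"

    def test_position_mismatch_dropped(self):
        assert (
            harmonize(assoc("A", "G", pos=100), assoc("A", "G", pos=101))
            == "position_mismatch"
        )


class TestEstimateLD:
    def test_unit_diagonal(self):
        panel = simulate_genotypes(500, 3, 0.5, (0.2, 0.4), seed=1)
        ld = estimate_ld(panel, panel.variant_ids())
        assert np.allclose(np.diag(ld.r), 1.0)

    def test_independent_variants_near_zero(self):
        panel = simulate_genotypes(5000, 2, 0.0, (0.2, 0.4), seed=2)
        ld = estimate_ld(panel, panel.variant_ids())
        assert abs(ld.r[0, 1]) < 0.1

    def test_matches_direct_covariance_formula(self):
        # brute-force oracle: covariance / product of SDs, python loops
        panel = simulate_genotypes(200, 5, 0.7, (0.2, 0.4), seed=3)
        ld = estimate_ld(panel, panel.variant_ids())
        g = panel.dosages.astype(float)
        n = g.shape[0]
        for i in range(5):
            for j in range(5):
                xi, xj = g[:, i], g[:, j]
                cov = sum((xi - xi.mean()) * (xj - xj.mean())) / n
                sd_i = (sum((xi - xi.mean()) ** 2) / n) ** 0.5
                sd_j = (sum((xj - xj.mean()) ** 2) / n) ** 0.5
                assert ld.r[i, j] == pytest.approx(cov / (sd_i * sd_j),
                                                   rel=1e-9)

    def test_monomorphic_variant_error_names_it(self):
        dosages = np.ones((50, 2), dtype=np.int8)
        dosages[:, 0] = np.tile([0, 2], 25)
        panel = GenotypePanel(dosages, np.array([0.5, 0.5]), np.eye(2))
        with pytest.raises(MonomorphicVariantError, match="v1"):
            estimate_ld(panel, ["v0", "v1"])


def toy_candidates(pvals, r, positions=None):
    m = len(pvals)
    positions = positions or list(range(100, 100 + m))
    ids = [f"v{i}" for i in range(m)]
    table = pd.DataFrame(
        {
            "variant_id": ids,
            "chrom": "1",
            "pos": positions,
            "effect_allele": "A",
            "other_allele": "G",
            "eaf": 0.3,
            "beta_x": 0.2,
            "se_x": 0.05,
            "pval_x": pvals,
            "beta_y": 0.1,
            "se_y": 0.05,
            "pval_y": 0.5,
        }
    )
    return HarmonizedCandidates("P", table, LDMatrix(ids, np.asarray(r, float)))


def reference_clump(pvals, positions, r2, r2_thr, p_thr):
    """Step-by-step reference of the greedy definition (independent path)."""
    alive = [i for i, p in enumerate(pvals) if p <= p_thr]
    alive.sort(key=lambda i: (pvals[i], positions[i]))
    kept = []
    while alive:
        idx = alive[0]
        kept.append(idx)
        alive = [j for j in alive[1:] if not (r2[idx][j] > r2_thr)]
    return kept


class TestClump:
    def test_perfect_ld_pair_keeps_smaller_p(self):
        r = [[1.0, 1.0], [1.0, 1.0]]
        inst = clump(toy_candidates([1e-6, 1e-5], r), 0.4, 1e-4)
        assert inst.variants == ["v0"]

    def test_independent_variants_all_retained(self):
        inst = clump(toy_candidates([1e-6, 1e-5, 1e-7], np.eye(3)), 0.05, 1e-4)
        assert sorted(inst.variants) == ["v0", "v1", "v2"]
        # output sorted by p ascending
        assert inst.variants == ["v2", "v0", "v1"]

    def test_p_filter_is_strict_greater_than(self):
        inst = clump(toy_candidates([1e-4, 1e-3], np.eye(2)), 0.4, 1e-4)
        assert inst.variants == ["v0"]  # p == threshold is kept, p > dropped

    def test_no_threshold_keeps_pval_one(self):
        inst = clump(toy_candidates([1.0, 0.5], np.eye(2)), 0.4, 1.0)
        assert len(inst.variants) == 2

    def test_r2_exactly_at_threshold_kept(self):
        r_val = np.sqrt(0.4)
        r = [[1.0, r_val], [r_val, 1.0]]
        inst = clump(toy_candidates([1e-6, 1e-5], r), 0.4, 1e-4)
        assert len(inst.variants) == 2

    def test_six_variant_toy_matches_reference(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(-1, 1, size=(6, 6))
        r = np.corrcoef(a)
        pvals = [1e-6, 1e-3, 1e-5, 1e-2, 1e-7, 1e-4]
        cand = toy_candidates(pvals, r)
        inst = clump(cand, 0.3, 1e-2)
        expected = reference_clump(
            pvals, list(range(100, 106)), (r * r).tolist(), 0.3, 1e-2
        )
        assert sorted(inst.variants) == sorted(f"v{i}" for i in expected)

    def test_random_instances_match_reference(self):
        # 200 random 10-variant instances against the independent greedy
        rng = np.random.default_rng(6)
        for rep in range(200):
            a = rng.normal(size=(10, 12))
            r = np.corrcoef(a)
            pvals = rng.uniform(1e-8, 1.0, size=10).tolist()
            r2_thr = rng.choice([0.05, 0.1, 0.2, 0.4, 0.6])
            p_thr = rng.choice([5e-8, 1e-4, 1e-2, 1.0])
            cand = toy_candidates(pvals, r)
            import warnings
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                inst = clump(cand, r2_thr, p_thr)
            expected = reference_clump(
                pvals, list(range(100, 110)), (r * r).tolist(), r2_thr, p_thr
            )
            assert sorted(inst.variants) == sorted(f"v{i}" for i in expected)

    def test_threshold_monotonicity(self):
        # lowering either threshold never increases the retained count
        rng = np.random.default_rng(7)
        a = rng.normal(size=(8, 10))
        r = np.corrcoef(a)
        pvals = rng.uniform(1e-8, 1.0, size=8).tolist()
        cand = toy_candidates(pvals, r)
        import warnings
        counts = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for r2_thr in (0.05, 0.2, 0.6):
                for p_thr in (1e-4, 1e-2, 1.0):
                    counts[(r2_thr, p_thr)] = clump(cand, r2_thr, p_thr).J
        for (r2a, pa), ca in counts.items():
            for (r2b, pb), cb in counts.items():
                if r2a <= r2b and pa <= pb:
                    assert ca <= cb

    def test_tie_break_by_position_is_deterministic(self):
        r = [[1.0, 0.9], [0.9, 1.0]]
        inst = clump(toy_candidates([1e-5, 1e-5], r), 0.4, 1e-4)
        assert inst.variants == ["v0"]  # same p: earlier position wins

    def test_empty_after_filter_warns(self):
        with pytest.warns(UserWarning, match="no instruments"):
            inst = clump(toy_candidates([0.5, 0.9], np.eye(2)), 0.4, 1e-4)
        assert inst.J == 0


class TestLDMatrix:
    def test_symmetry_and_diagonal_enforced(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))

    def test_tsv_round_trip(self, tmp_path):
        ld = LDMatrix(["a", "b"], np.array([[1.0, -0.25], [-0.25, 1.0]]))
        path = tmp_path / "ld.tsv"
        ld.write_tsv(path)
        back = LDMatrix.read_tsv(path)
        assert back.variant_ids == ["a", "b"]
        assert np.allclose(back.r, ld.r)

    def test_subset_preserves_order(self):
        r = np.array([[1, 0.1, 0.2], [0.1, 1, 0.3], [0.2, 0.3, 1.0]])
        ld = LDMatrix(["a", "b", "c"], r)
        sub = ld.subset(["c", "a"])
        assert sub.variant_ids == ["c", "a"]
        assert sub.r[0, 1] == pytest.approx(0.2)
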