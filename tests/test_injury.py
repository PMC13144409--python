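"""Injury-response statistic: invariances, background model, significance."""

import numpy as np
import pandas as pd
import pytest

from slamkit.conversions import AlignedReadRecord, substitution_spectrum
from slamkit.injury import (
    BackgroundModel,
    ConditionPair,
    GeneSetLayer,
    ZERO_BACKGROUND,
    estimate_background,
    injury_response,
    pathway_layer_score,
    permutation_test,
)
from slamkit.quantify import LabeledMatrices


def mk_pair(lab_s, unl_s, lab_i, unl_i, genes=None, cell_type="mac"):
    genes = genes or [f"g{i}" for i in range(lab_s.shape[0])]
    gi = pd.Index(genes, name="gene")
    cs = pd.Index([f"s{i}" for i in range(lab_s.shape[1])], name="unit")
    ci = pd.Index([f"i{i}" for i in range(lab_i.shape[1])], name="unit")
    sham = LabeledMatrices(pd.DataFrame(lab_s, gi, cs), pd.DataFrame(unl_s, gi, cs))
    injured = LabeledMatrices(pd.DataFrame(lab_i, gi, ci), pd.DataFrame(unl_i, gi, ci))
    return ConditionPair(
        sham, injured,
        pd.Series(cell_type, index=cs), pd.Series(cell_type, index=ci),
    )


def rand_counts(rng, shape, lam=5):
    return rng.poisson(lam, size=shape)


class TestBackgroundModel:
    def test_error_free_reads_give_zero_epsilon(self):
        reads = [
            AlignedReadRecord(f"r{i}", list(range(10)), "ACGTACGTAC", "ACGTACGTAC",
                              [30] * 10, genome_strand_of_gene="+")
            for i in range(5)
        ]
        bg = estimate_background(substitution_spectrum(reads))
        assert bg.epsilon_hat == 0.0 and bg.p_false == 0.0

    def test_uniform_error_recovered_within_3se(self):
        """Injecting each substitution type at rate 1e-3 yields epsilon ~ 1e-3."""
        rng = np.random.default_rng(2)
        eps, n, L = 1e-3, 2000, 100
        reads = []
        bases = "ACGT"
        for i in range(n):
            ref = "".join(bases[j] for j in rng.integers(0, 4, L))
            read = list(ref)
            for k in range(L):
                if rng.random() < 3 * eps:
                    read[k] = [b for b in bases if b != ref[k]][rng.integers(0, 3)]
            reads.append(
                AlignedReadRecord(f"r{i}", list(range(L)), ref, "".join(read), [30] * L,
                                  genome_strand_of_gene="+")
            )
        bg = estimate_background(substitution_spectrum(reads))
        se = np.sqrt(eps / (n * L / 4))  # per-type binomial SE on ~nL/4 sites
        assert abs(bg.epsilon_hat - eps) < 3 * se

    def test_expected_false_labeled_arithmetic(self):
        bg = BackgroundModel(epsilon_hat=0.001, nbar_t=50.0)
        expected = 1000 * (1 - 0.999**50)
        assert bg.expected_false_labeled(np.array([1000.0]))[0] == pytest.approx(expected)
        assert expected == pytest.approx(48.8, abs=0.1)

    def test_no_informative_sites_raises(self):
        spec = pd.DataFrame(
            {"n_events": 0, "n_sites": 0},
            index=pd.Index([f"{a}>{b}" for a in "ACGT" for b in "ACGT" if a != b],
                           name="substitution"),
        )
        with pytest.raises(ValueError):
            estimate_background(spec)


class TestInjuryResponse:
    def test_identical_profiles_give_unit_ratio(self):
        rng = np.random.default_rng(0)
        lab = rand_counts(rng, (20, 10))
        unl = rand_counts(rng, (20, 10))
        pair = mk_pair(lab, unl, lab.copy(), unl.copy())
        res = injury_response(pair, cell_type="mac", n_perm=0)
        assert np.allclose(res["response_ratio"], 1.0)

    def test_ratio_arithmetic_small_pseudocount(self):
        # one library twice as deep, gene share 2x higher in injured
        lab_s = np.array([[100], [9900]])
        lab_i = np.array([[300], [14700]])
        unl = np.zeros((2, 1), dtype=int)
        pair = mk_pair(lab_s, unl, lab_i, unl)
        res = injury_response(pair, cell_type="mac", pi=1e-12, n_perm=0, min_cells=1)
        assert res["response_ratio"].iloc[0] == pytest.approx(2.0, rel=1e-6)

    def test_invariance_to_unlabeled_inflation(self):
        """Pre-existing RNA never moves R: bit-identical under 10x unlabeled."""
        rng = np.random.default_rng(1)
        lab_s, lab_i = rand_counts(rng, (30, 8)), rand_counts(rng, (30, 8))
        unl_s, unl_i = rand_counts(rng, (30, 8)), rand_counts(rng, (30, 8))
        base = mk_pair(lab_s, unl_s, lab_i, unl_i)
        inflated = mk_pair(lab_s, unl_s * 10, lab_i, unl_i)
        r0 = injury_response(base, cell_type="mac", n_perm=0)["response_ratio"]
        r1 = injury_response(inflated, cell_type="mac", n_perm=0)["response_ratio"]
        assert (r0.to_numpy() == r1.to_numpy()).all()

    def test_invariance_to_labeled_library_scaling(self):
        """Doubling every labeled count in one condition leaves R bit-identical."""
        rng = np.random.default_rng(2)
        lab_s, lab_i = rand_counts(rng, (30, 8)), rand_counts(rng, (30, 8))
        unl = rand_counts(rng, (30, 8))
        base = mk_pair(lab_s, unl, lab_i, unl)
        scaled = mk_pair(lab_s, unl, lab_i * 2, unl)
        r0 = injury_response(base, cell_type="mac", n_perm=0)["response_ratio"]
        r1 = injury_response(scaled, cell_type="mac", n_perm=0)["response_ratio"]
        assert (r0.to_numpy() == r1.to_numpy()).all()

    def test_zero_background_equals_uncorrected(self):
        rng = np.random.default_rng(3)
        pair = mk_pair(rand_counts(rng, (10, 5)), rand_counts(rng, (10, 5)),
                       rand_counts(rng, (10, 5)), rand_counts(rng, (10, 5)))
        a = injury_response(pair, ZERO_BACKGROUND, cell_type="mac", n_perm=0)
        b = injury_response(pair, BackgroundModel(0.0, 50.0), cell_type="mac", n_perm=0)
        assert (a["response_ratio"].to_numpy() == b["response_ratio"].to_numpy()).all()

    def test_low_count_genes_reported_untested(self):
        lab_s = np.array([[1], [500]])
        lab_i = np.array([[1], [500]])
        unl = np.zeros((2, 1), dtype=int)
        pair = mk_pair(lab_s, unl, lab_i, unl)
        res = injury_response(pair, cell_type="mac", n_perm=0, min_cells=1)
        assert not res["tested"].iloc[0] and res["tested"].iloc[1]
        assert len(res) == 2  # untested gene is reported, not dropped

    def test_absent_cell_type_errors(self):
        rng = np.random.default_rng(4)
        pair = mk_pair(rand_counts(rng, (5, 4)), rand_counts(rng, (5, 4)),
                       rand_counts(rng, (5, 4)), rand_counts(rng, (5, 4)))
        with pytest.raises(ValueError, match="absent"):
            injury_response(pair, cell_type="fibroblast", n_perm=0)


class TestPermutationTest:
    def test_matches_exhaustive_enumeration_2v2(self):
        """Monte-Carlo-free check: p over the 6 distinct 2v2 assignments."""
        rng = np.random.default_rng(5)
        lab_s, lab_i = rand_counts(rng, (12, 2), 20), rand_counts(rng, (12, 2), 20)
        unl = np.zeros((12, 2), dtype=int)
        pair = mk_pair(lab_s, unl, lab_i, unl)
        p = permutation_test(pair, "mac", exhaustive=True)
        # independent oracle: enumerate assignments by hand
        from itertools import combinations

        L = np.concatenate([lab_s, lab_i], axis=1).astype(float)

        def stat(idx):
            s = L[:, list(idx)].sum(axis=1)
            i = L[:, [c for c in range(4) if c not in idx]].sum(axis=1)
            ls = 1e4 * s / s.sum() + 1.0
            li = 1e4 * i / i.sum() + 1.0
            return np.abs(np.log2(li / ls))

        obs = stat((0, 1))
        expected = np.mean(
            [stat(idx) >= obs - 1e-12 for idx in combinations(range(4), 2)], axis=0
        )
        np.testing.assert_allclose(p, expected)

    def test_identical_cells_give_p_one(self):
        lab = np.tile([[7], [13]], (1, 4))
        unl = np.zeros((2, 4), dtype=int)
        pair = mk_pair(lab[:, :2], unl[:, :2], lab[:, 2:], unl[:, 2:])
        p = permutation_test(pair, "mac", n_perm=50)
        assert np.allclose(p, 1.0)

    def test_seed_determinism(self):
        rng = np.random.default_rng(6)
        lab_s, lab_i = rand_counts(rng, (10, 6), 10), rand_counts(rng, (10, 6), 10)
        unl = np.zeros((10, 6), dtype=int)
        pair = mk_pair(lab_s, unl, lab_i, unl)
        p1 = permutation_test(pair, "mac", n_perm=99, seed=42)
        p2 = permutation_test(pair, "mac", n_perm=99, seed=42)
        assert (p1 == p2).all()
        p3 = permutation_test(pair, "mac", n_perm=99, seed=43)
        assert np.max(np.abs(p3 - p1)) < 0.5  # different seed, same ballpark

    def test_too_few_permutations_rejected(self):
        rng = np.random.default_rng(7)
        lab = rand_counts(rng, (4, 4))
        unl = np.zeros((4, 4), dtype=int)
        pair = mk_pair(lab[:, :2], unl[:, :2], lab[:, 2:], unl[:, 2:])
        with pytest.raises(ValueError, match="n_perm"):
            permutation_test(pair, "mac", n_perm=5)

    def test_q_values_dominate_p_values(self):
        rng = np.random.default_rng(8)
        lab_s, lab_i = rand_counts(rng, (40, 6), 20), rand_counts(rng, (40, 6), 20)
        unl_s, unl_i = rand_counts(rng, (40, 6)), rand_counts(rng, (40, 6))
        pair = mk_pair(lab_s, unl_s, lab_i, unl_i)
        res = injury_response(pair, cell_type="mac", n_perm=99, seed=0)
        tested = res[res["tested"]]
        assert (tested["q"] >= tested["p_perm"] - 1e-12).all()


class TestPathwayLayerScore:
    def mk_matrix(self):
        return pd.DataFrame(
            [[5, 4], [95, 96]], index=["tlr1", "other"], columns=["c1", "c2"]
        )

    def test_percent_of_transcriptome(self):
        layer = GeneSetLayer("tlr_l1", ("tlr1",))
        out = pathway_layer_score(self.mk_matrix(), layer)
        assert out["mean_percent"].iloc[0] == pytest.approx(4.5)

    def test_all_genes_give_100_percent(self):
        layer = GeneSetLayer("all", ("tlr1", "other"))
        out = pathway_layer_score(self.mk_matrix(), layer)
        assert out["mean_percent"].iloc[0] == pytest.approx(100.0)

    def test_mean_and_sem(self):
        m = pd.DataFrame([[4, 6], [96, 94]], index=["a", "b"], columns=["c1", "c2"])
        out = pathway_layer_score(m, GeneSetLayer("s", ("a",)))
        assert out["mean_percent"].iloc[0] == pytest.approx(5.0)
        assert out["sem_percent"].iloc[0] == pytest.approx(1.0)

    def test_zero_count_cell_excluded_with_warning(self):
        m = pd.DataFrame([[5, 0], [95, 0]], index=["a", "b"], columns=["c1", "c2"])
        with pytest.warns(UserWarning, match="zero total"):
            out = pathway_layer_score(m, GeneSetLayer("s", ("a",)))
        assert out["n_cells"].iloc[0] == 1

    def test_missing_genes_warn(self):
        with pytest.warns(UserWarning, match="not in matrix"):
            pathway_layer_score(self.mk_matrix(), GeneSetLayer("s", ("tlr1", "ghost")))

    def test_empty_gene_set_rejected(self):
        with pytest.raises(ValueError):
            GeneSetLayer("s", ())
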