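import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from concordmeta.concordance import (
    ConcordanceMatrix,
    concordance_matrix,
    nearest_rank_quantile,
    null_subset_averages,
    null_threshold,
    pairwise_concordance,
    sample_size_regression,
    subset_average,
)
from concordmeta.signatures import ExpressionSignature, SignatureConfig, extract_signature
from concordmeta.study_io import DEProfile, GeneUniverse, ValidationError


def profile_and_sig(sid, entries, sig_genes):
    prof = DEProfile.from_entries(sid, entries)
    values = tuple(float(prof.logfc([g])[0]) for g in sig_genes)
    return prof, ExpressionSignature(sid, tuple(sig_genes), values)


class TestPairwiseConcordance:
    def test_self_correlation_is_one(self):
        entries = {"G1": (2.0, 0.01), "G2": (-1.0, 0.01), "G3": (1.5, 0.01), "G4": (0.1, 0.01)}
        p, s = profile_and_sig("a", entries, ["G1", "G2", "G3"])
        assert pairwise_concordance(p, p, s, s) == pytest.approx(1.0)

    def test_negated_profile_gives_minus_one(self):
        entries = {"G1": (2.0, 0.01), "G2": (-1.0, 0.01), "G3": (1.5, 0.01), "G4": (0.1, 0.01)}
        neg = {g: (-v, p) for g, (v, p) in entries.items()}
        p1, s1 = profile_and_sig("a", entries, ["G1", "G2", "G3"])
        p2, s2 = profile_and_sig("b", neg, ["G1", "G2", "G3"])
        assert pairwise_concordance(p1, p2, s1, s2) == pytest.approx(-1.0)

    def test_hand_pearson_on_union_support(self):
        # support = union {g1..g4}; independent oracle: scipy.stats.pearsonr
        x = {"G1": (2.0, 0.01), "G2": (-1.0, 0.01), "G3": (1.5, 0.01), "G4": (0.1, 0.01)}
        y = {"G1": (1.0, 0.01), "G2": (-0.5, 0.01), "G3": (0.2, 0.01), "G4": (1.8, 0.01)}
        p1, s1 = profile_and_sig("a", x, ["G1", "G2"])
        p2, s2 = profile_and_sig("b", y, ["G3", "G4"])
        expected = stats.pearsonr(
            [2.0, -1.0, 1.5, 0.1], [1.0, -0.5, 0.2, 1.8]
        ).statistic
        got = pairwise_concordance(p1, p2, s1, s2)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_small_support_and_constant_vector_give_zero(self):
        x = {"G1": (2.0, 0.01), "G2": (1.0, 0.01), "G3": (1.0, 0.01)}
        p1, s1 = profile_and_sig("a", x, ["G1", "G2"])
        p2, s2 = profile_and_sig("b", x, ["G1"])
        # union of {G1,G2} and {G1} has 2 genes -> degenerate
        assert pairwise_concordance(p1, p2, s1, s2) == 0.0
        const = {"G1": (1.0, 0.01), "G2": (1.0, 0.01), "G3": (1.0, 0.01)}
        p3, s3 = profile_and_sig("c", const, ["G1", "G2", "G3"])
        p4, s4 = profile_and_sig("d", x, ["G1", "G2", "G3"])
        assert pairwise_concordance(p3, p4, s3, s4) == 0.0

    def test_sign_mode_agrees_in_sign_with_logfc_mode(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i}" for i in range(40)]
        base = rng.normal(size=40) * 2
        x = {g: (float(b + rng.normal(0, 0.3)), 0.01) for g, b in zip(genes, base)}
        y = {g: (float(b + rng.normal(0, 0.3)), 0.01) for g, b in zip(genes, base)}
        p1, s1 = profile_and_sig("a", x, genes[:20])
        p2, s2 = profile_and_sig("b", y, genes[10:30])
        r_val = pairwise_concordance(p1, p2, s1, s2, mode="logfc")
        r_sign = pairwise_concordance(p1, p2, s1, s2, mode="sign")
        assert r_val > 0.5 and r_sign > 0

    def test_intersection_support_option(self):
        x = {"G1": (2.0, 0.01), "G2": (-1.0, 0.01), "G3": (1.5, 0.01), "G4": (0.1, 0.01)}
        p1, s1 = profile_and_sig("a", x, ["G1", "G2", "G3"])
        p2, s2 = profile_and_sig("b", x, ["G2", "G3", "G4"])
        # intersection has only 2 genes -> degenerate 0; union is fine
        assert pairwise_concordance(p1, p2, s1, s2, support="intersection") == 0.0
        assert pairwise_concordance(p1, p2, s1, s2) == pytest.approx(1.0)


class TestConcordanceMatrix:
    def test_identical_studies_all_ones(self):
        entries = {f"G{i}": (float(i - 2), 0.01) for i in range(5)}
        trio = [profile_and_sig(s, entries, ["G0", "G1", "G3", "G4"]) for s in "abc"]
        m = concordance_matrix([p for p, _ in trio], [s for _, s in trio])
        assert np.allclose(m.c, 1.0)

    def test_symmetry_diag_and_reorder_invariance(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i:02d}" for i in range(60)]
        uni = GeneUniverse(genes=tuple(genes))
        profs = [
            DEProfile.from_entries(
                f"s{i}", {g: (float(rng.normal()), float(rng.uniform())) for g in genes}
            )
            for i in range(4)
        ]
        sigs = [extract_signature(p, uni, SignatureConfig(k=10)) for p in profs]
        m = concordance_matrix(profs, sigs)
        assert np.allclose(m.c, m.c.T)
        assert np.allclose(np.diag(m.c), 1.0)
        perm = [2, 0, 3, 1]
        m2 = concordance_matrix([profs[i] for i in perm], [sigs[i] for i in perm])
        for a in range(4):
            for b in range(4):
                assert m2.c[a, b] == pytest.approx(m.c[perm[a], perm[b]])

    def test_independent_noise_mean_near_zero(self):
        rng = np.random.default_rng(11)
        genes = [f"G{i:03d}" for i in range(500)]
        uni = GeneUniverse(genes=tuple(genes))
        profs = [
            DEProfile.from_entries(
                f"s{i}", {g: (float(rng.normal()), float(rng.uniform())) for g in genes}
            )
            for i in range(10)
        ]
        sigs = [extract_signature(p, uni) for p in profs]
        m = concordance_matrix(profs, sigs)
        off = m.c[np.triu_indices(10, 1)]
        assert abs(off.mean()) < 0.05


class TestSubsetAverage:
    def matrix3(self):
        c = np.array([[1.0, 0.3, 0.6], [0.3, 1.0, 0.0], [0.6, 0.0, 1.0]])
        return ConcordanceMatrix(studies=("a", "b", "c"), c=c)

    def test_hand_arithmetic(self):
        a_s, a_i = subset_average(self.matrix3(), ["a", "b", "c"])
        assert a_i == pytest.approx({"a": 0.45, "b": 0.15, "c": 0.3})
        assert a_s == pytest.approx(0.3)

    def test_pair_subset_equals_single_entry(self):
        a_s, _ = subset_average(self.matrix3(), ["a", "b"])
        assert a_s == pytest.approx(0.3)

    def test_all_ones_matrix(self):
        m = ConcordanceMatrix(studies=("a", "b", "c"), c=np.ones((3, 3)))
        assert subset_average(m, ["a", "c"])[0] == pytest.approx(1.0)

    def test_equals_mean_upper_triangle(self):
        rng = np.random.default_rng(5)
        n = 7
        raw = rng.uniform(-1, 1, (n, n))
        c = (raw + raw.T) / 2
        np.fill_diagonal(c, 1.0)
        m = ConcordanceMatrix(studies=tuple(f"s{i}" for i in range(n)), c=c)
        a_s, _ = subset_average(m, m.studies)
        assert a_s == pytest.approx(float(c[np.triu_indices(n, 1)].mean()))

    def test_singleton_rejected(self):
        with pytest.raises(ValidationError):
            subset_average(self.matrix3(), ["a"])


class TestNullThreshold:
    def random_matrix(self, n, seed):
        rng = np.random.default_rng(seed)
        raw = rng.uniform(-0.5, 0.5, (n, n))
        c = (raw + raw.T) / 2
        np.fill_diagonal(c, 1.0)
        return ConcordanceMatrix(studies=tuple(f"s{i}" for i in range(n)), c=c)

    def test_enumeration_matches_bruteforce(self):
        m = self.random_matrix(5, 2)
        values = null_subset_averages(m, 2)
        brute = []
        for pair in combinations(range(5), 2):
            brute.append(m.c[pair[0], pair[1]])
        assert sorted(values.tolist()) == pytest.approx(sorted(brute))
        thr, n_null = null_threshold(m, 2)
        assert n_null == 10
        # nearest-rank 0.95 of 10 ordered values is the 10th
        assert thr == pytest.approx(max(brute))

    def test_full_size_subgroup_is_its_own_null(self):
        m = self.random_matrix(6, 3)
        thr, n_null = null_threshold(m, 6)
        a_s, _ = subset_average(m, m.studies)
        assert n_null == 1
        assert thr == pytest.approx(a_s)

    def test_sampled_mode_is_seeded_and_in_range(self):
        m = self.random_matrix(12, 4)
        thr1, n1 = null_threshold(m, 5, max_samples=300, seed=9)
        thr2, _ = null_threshold(m, 5, max_samples=300, seed=9)
        thr3, _ = null_threshold(m, 5, max_samples=300, seed=10)
        assert thr1 == thr2
        assert n1 == 300
        full = null_subset_averages(m, 5, max_samples=10**6)
        assert full.min() <= thr1 <= full.max()
        assert thr3 != thr1  # different seed, different draw (almost surely)

    def test_invalid_sizes_rejected(self):
        m = self.random_matrix(5, 6)
        with pytest.raises(ValidationError):
            null_threshold(m, 6)
        with pytest.raises(ValidationError):
            null_threshold(m, 1)

    def test_nearest_rank_convention(self):
        vals = np.arange(1, 11, dtype=float)  # 1..10
        assert nearest_rank_quantile(vals, 0.95) == 10.0
        assert nearest_rank_quantile(vals, 0.90) == 9.0
        assert nearest_rank_quantile(vals, 0.05) == 1.0


class TestSampleSizeRegression:
    def test_constant_response_flat(self):
        a_i = {f"s{i}": 0.2 for i in range(5)}
        sizes = {f"s{i}": 10 + i for i in range(5)}
        slope, _, p, r2 = sample_size_regression(a_i, sizes)
        assert slope == 0.0 and r2 == 0.0

    def test_perfectly_linear(self):
        sizes = {f"s{i}": 10 + 2 * i for i in range(5)}
        a_i = {s: 0.01 * n for s, n in sizes.items()}
        slope, intercept, p, r2 = sample_size_regression(a_i, sizes)
        assert slope == pytest.approx(0.01)
        assert r2 == pytest.approx(1.0)

    def test_matches_closed_form_normal_equations(self):
        sizes = {"a": 8, "b": 12, "c": 20, "d": 30, "e": 16}
        a_i = {"a": 0.02, "b": -0.01, "c": 0.11, "d": 0.05, "e": 0.07}
        slope, intercept, p, r2 = sample_size_regression(a_i, sizes)
        x = np.array([sizes[s] for s in sorted(sizes)], dtype=float)
        y = np.array([a_i[s] for s in sorted(sizes)])
        beta = (np.mean(x * y) - x.mean() * y.mean()) / (np.mean(x * x) - x.mean() ** 2)
        alpha = y.mean() - beta * x.mean()
        assert slope == pytest.approx(beta)
        assert intercept == pytest.approx(alpha)
        resid = y - alpha - beta * x
        ss_res, ss_tot = float(resid @ resid), float(((y - y.mean()) ** 2).sum())
        assert r2 == pytest.approx(1 - ss_res / ss_tot)
        se = math.sqrt(ss_res / 3 / ((x - x.mean()) @ (x - x.mean())))
        t = beta / se
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 3))

    def test_constant_sizes_rejected(self):
        with pytest.raises(ValidationError):
            sample_size_regression({"a": 0.1, "b": 0.2, "c": 0.3}, {"a": 10, "b": 10, "c": 10})
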