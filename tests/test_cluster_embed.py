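import numpy as np
import pytest
from scipy import stats

from oracle_utils import naive_agglomerate

from concordmeta.cluster_embed import (
    correlation_distance,
    hierarchical_cluster,
    multiscale_bootstrap,
    pca_embed,
)
from concordmeta.signatures import FeatureMatrix
from concordmeta.study_io import ValidationError


def fm_from(values, mode="logfc"):
    values = np.asarray(values, dtype=float)
    return FeatureMatrix(
        studies=tuple(f"s{i}" for i in range(values.shape[0])),
        genes=tuple(f"G{j:03d}" for j in range(values.shape[1])),
        values=values,
        mode=mode,
    )


class TestPcaEmbed:
    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(6, 9))
        emb = pca_embed(fm_from(x), center=True, scale=False)
        xc = x - x.mean(axis=0)
        evals, evecs = np.linalg.eigh(xc.T @ xc / (x.shape[0] - 1))
        evals, evecs = evals[::-1], evecs[:, ::-1]
        k = min(x.shape)
        assert np.allclose(
            emb.variance_explained, evals[:k] / evals.sum(), atol=1e-8
        )
        scores_oracle = xc @ evecs[:, :k]
        for comp in range(k - 1):  # last component may be numerically null
            assert np.allclose(
                np.abs(emb.scores[:, comp]), np.abs(scores_oracle[:, comp]), atol=1e-8
            )

    def test_duplicated_rows_get_identical_scores(self):
        rng = np.random.default_rng(1)
        row = rng.normal(size=12)
        x = np.vstack([row, row, rng.normal(size=12), rng.normal(size=12)])
        emb = pca_embed(fm_from(x))
        assert np.allclose(emb.scores[0], emb.scores[1], atol=1e-8)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(2)
        emb = pca_embed(fm_from(rng.normal(size=(5, 20))))
        assert emb.variance_explained.sum() == pytest.approx(1.0, abs=1e-8)

    def test_distances_preserved_in_full_component_space(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(7, 15))
        emb = pca_embed(fm_from(x), center=True, scale=True)
        xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        for i in range(7):
            for j in range(i + 1, 7):
                d_feat = np.linalg.norm(xs[i] - xs[j])
                d_comp = np.linalg.norm(emb.scores[i] - emb.scores[j])
                assert d_comp == pytest.approx(d_feat, abs=1e-8)

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 10))
        a = pca_embed(fm_from(x))
        b = pca_embed(fm_from(x.copy()))
        assert np.allclose(a.scores, b.scores)
        for comp in range(a.loadings.shape[1]):
            pivot = np.argmax(np.abs(a.loadings[:, comp]))
            assert a.loadings[pivot, comp] >= 0

    def test_all_constant_columns_rejected(self):
        with pytest.raises(ValidationError):
            pca_embed(fm_from(np.ones((4, 5))))


class TestCorrelationDistance:
    def test_identical_and_negated_rows(self):
        rng = np.random.default_rng(5)
        row = rng.normal(size=20)
        d = correlation_distance(fm_from(np.vstack([row, row, -row])))
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_pearson_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(4, 30))
        d = correlation_distance(fm_from(x))
        for i in range(4):
            for j in range(i + 1, 4):
                r = stats.pearsonr(x[i], x[j]).statistic
                assert d[i, j] == pytest.approx(1 - r, abs=1e-10)

    def test_constant_row_names_study(self):
        x = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValidationError, match="s0"):
            correlation_distance(fm_from(x))


class TestHierarchicalCluster:
    def test_two_duplicate_pairs_merge_first(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=30), rng.normal(size=30)
        x = np.vstack([a, a + rng.normal(0, 0.01, 30), b, b + rng.normal(0, 0.01, 30)])
        d = correlation_distance(fm_from(x))
        tree = hierarchical_cluster(d, [f"s{i}" for i in range(4)])
        first_two = tree.leafsets()[:2]
        assert {frozenset({"s0", "s1"}), frozenset({"s2", "s3"})} == set(first_two)

    def test_single_pair_merges_at_distance(self):
        d = np.array([[0.0, 0.37], [0.37, 0.0]])
        tree = hierarchical_cluster(d, ["x", "y"])
        assert tree.heights.tolist() == [0.37]

    @pytest.mark.parametrize("linkage", ["average", "complete"])
    def test_matches_naive_agglomeration_oracle(self, linkage):
        rng = np.random.default_rng(8)
        for _ in range(15):
            n = 6
            raw = rng.uniform(0.1, 2.0, (n, n))
            d = (raw + raw.T) / 2
            np.fill_diagonal(d, 0.0)
            tree = hierarchical_cluster(d, [f"s{i}" for i in range(n)], linkage)
            heights, leafsets = naive_agglomerate(d, linkage)
            assert np.allclose(np.sort(tree.heights), np.sort(heights), atol=1e-10)
            got = {frozenset(f"s{i}" for i in ls) for ls in leafsets}
            assert set(tree.leafsets()) == got

    def test_heights_monotone(self):
        rng = np.random.default_rng(9)
        raw = rng.uniform(0.1, 2.0, (8, 8))
        d = (raw + raw.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = hierarchical_cluster(d, [f"s{i}" for i in range(8)])
        assert (np.diff(tree.heights) >= -1e-12).all()

    def test_asymmetric_input_rejected(self):
        d = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValidationError):
            hierarchical_cluster(d, ["a", "b"])


def planted_two_groups(seed, n_per=4, n_genes=60, noise=0.15):
    rng = np.random.default_rng(seed)
    mu_a, mu_b = rng.normal(0, 1, n_genes), rng.normal(0, 1, n_genes)
    rows = [mu_a + rng.normal(0, noise, n_genes) for _ in range(n_per)]
    rows += [mu_b + rng.normal(0, noise, n_genes) for _ in range(n_per)]
    return fm_from(np.vstack(rows))


class TestMultiscaleBootstrap:
    def test_bit_reproducible(self):
        fm = planted_two_groups(10)
        t1 = multiscale_bootstrap(fm, n_boot=100, seed=3)
        t2 = multiscale_bootstrap(fm, n_boot=100, seed=3)
        assert [(n.leafset, n.bp, n.au) for n in t1.nodes] == [
            (n.leafset, n.bp, n.au) for n in t2.nodes
        ]

    def test_planted_groups_get_full_support(self):
        fm = planted_two_groups(11)
        tree = multiscale_bootstrap(fm, n_boot=200, seed=4)
        group_a = frozenset(f"s{i}" for i in range(4))
        group_b = frozenset(f"s{i}" for i in range(4, 8))
        by_set = {n.leafset: n for n in tree.nodes}
        assert by_set[group_a].au >= 0.95
        assert by_set[group_b].au >= 0.95
        cut = tree.cut(2)
        labels_a = {cut[s] for s in group_a}
        labels_b = {cut[s] for s in group_b}
        assert len(labels_a) == 1 and len(labels_b) == 1 and labels_a != labels_b

    def test_bp_at_scale_one_matches_plain_bootstrap_oracle(self):
        from scipy.cluster import hierarchy as hier
        from scipy.spatial.distance import squareform

        fm = planted_two_groups(12, noise=0.6)
        tree = multiscale_bootstrap(fm, scales=(0.8, 1.0, 1.2), n_boot=300, seed=5)
        target = frozenset(f"s{i}" for i in range(4))
        bp = {n.leafset: n.bp for n in tree.nodes}[target]
        # independent plain bootstrap at full size
        rng = np.random.default_rng(99)
        hits = 0
        b = 300
        x = fm.values
        for _ in range(b):
            xb = x[:, rng.integers(0, x.shape[1], x.shape[1])]
            d = np.clip(1 - np.corrcoef(xb), 0, 2)
            np.fill_diagonal(d, 0)
            z = hier.linkage(squareform((d + d.T) / 2, checks=False), "average")
            sets = [frozenset([s]) for s in fm.studies]
            found = False
            for a_, b_ in z[:, :2].astype(int):
                merged = sets[a_] | sets[b_]
                sets.append(merged)
                if merged == target:
                    found = True
            hits += found
        oracle = hits / b
        se = np.sqrt(max(oracle * (1 - oracle), bp * (1 - bp)) / b)
        assert abs(bp - oracle) < 4 * se + 1e-9

    def test_newick_export_parses(self):
        import dendropy

        fm = planted_two_groups(13)
        tree = multiscale_bootstrap(fm, n_boot=50, seed=6)
        newick = tree.newick()
        parsed = dendropy.Tree.get(data=newick, schema="newick")
        assert len(parsed.leaf_nodes()) == 8

    def test_too_few_studies_rejected(self):
        rng = np.random.default_rng(14)
        fm = fm_from(rng.normal(size=(3, 20)))
        with pytest.raises(ValidationError):
            multiscale_bootstrap(fm, n_boot=10, seed=1)
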