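import numpy as np
import pandas as pd
import pytest

from conftest import make_pathway_matrix, random_instance
from digs.exceptions import ValidationError
from digs.io import ExpressionProfile, GeneSetCollection
from digs.methods import (
    corgs_activity,
    fit_activity_method,
    mean_activity,
    median_activity,
    pca_activity,
    rank_genes_pairwise_distance,
    score_samples,
)
from digs.model import DigsConfig


class TestMeanMedian:
    def test_mean_rows(self):
        mat = make_pathway_matrix([[1.0, 2.0, 3.0], [1.0, 2.0, 10.0]], ["A", "B"])
        act = mean_activity(mat)
        assert act.iloc[0] == pytest.approx(2.0)
        assert act.iloc[1] == pytest.approx(4.3333, abs=1e-4)

    def test_median_even_uses_midpoint(self):
        mat = make_pathway_matrix([[1.0, 3.0], [1.0, 2.0]], ["A", "B"])
        act = median_activity(mat)
        assert act.iloc[0] == pytest.approx(2.0)

    def test_single_gene_identity(self):
        mat = make_pathway_matrix([[7.0], [-1.0]], ["A", "B"])
        assert mean_activity(mat).tolist() == [7.0, -1.0]
        assert median_activity(mat).tolist() == [7.0, -1.0]


class TestPca:
    def test_duplicated_gene_symmetry(self):
        rng = np.random.default_rng(0)
        g = rng.normal(size=6)
        mat = make_pathway_matrix(np.column_stack([g, g]), ["A", "B"] * 3)
        loading, act = pca_activity(mat)
        np.testing.assert_allclose(loading, [np.sqrt(0.5)] * 2, atol=1e-9)
        np.testing.assert_allclose(act.to_numpy(), np.sqrt(2) * g, atol=1e-9)

    def test_single_gene_identity(self):
        g = np.array([-1.0, 0.0, 1.0])
        mat = make_pathway_matrix(g[:, None], ["A", "B", "A"])
        loading, act = pca_activity(mat)
        assert loading.tolist() == [1.0]
        np.testing.assert_allclose(act.to_numpy(), g)

    def test_matches_dense_eigendecomposition(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(4, 3))
        mat = make_pathway_matrix(X, ["A", "B", "A", "B"])
        loading, act = pca_activity(mat)
        cov = np.cov(X, rowvar=False, ddof=1)
        vals, vecs = np.linalg.eigh(cov)
        ref = vecs[:, np.argmax(vals)]
        if ref[np.argmax(np.abs(ref))] < 0:
            ref = -ref
        np.testing.assert_allclose(loading, ref, atol=1e-8)
        np.testing.assert_allclose(act.to_numpy(), X @ ref, atol=1e-8)

    def test_zero_covariance_warns_and_zeroes(self):
        mat = make_pathway_matrix(np.zeros((4, 2)), ["A", "B", "A", "B"])
        with pytest.warns(UserWarning, match="zero covariance"):
            _, act = pca_activity(mat)
        assert (act == 0).all()

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(6, 4))
        mat = make_pathway_matrix(X, ["A", "B"] * 3)
        l1, _ = pca_activity(mat)
        l2, _ = pca_activity(mat)
        assert l1[np.argmax(np.abs(l1))] > 0
        np.testing.assert_array_equal(l1, l2)


class TestCorgs:
    @staticmethod
    def strong_gene_instance(seed=0, n_noise=5, n_per_class=10):
        rng = np.random.default_rng(seed)
        S = 2 * n_per_class
        signal = np.concatenate(
            [rng.normal(-3.0, 0.1, n_per_class), rng.normal(3.0, 0.1, n_per_class)]
        )
        noise = rng.normal(0.0, 1.0, size=(S, n_noise))
        G = np.column_stack([signal, noise])
        G = (G - G.mean(0)) / G.std(0)
        labels = ["A"] * n_per_class + ["B"] * n_per_class
        return make_pathway_matrix(G, labels)

    def test_selects_exactly_the_separating_gene(self):
        mat = self.strong_gene_instance()
        fit, act = corgs_activity(mat)
        assert fit.genes == ["g0"]
        # verify by exhaustive prefix search: no prefix of the t-ranked list
        # beats the single separating gene's |t|
        from scipy import stats

        X = mat.values.to_numpy()
        y = mat.label_array()
        t_single = abs(
            stats.ttest_ind(act[y == "A"], act[y == "B"], equal_var=True).statistic
        )
        tstats = stats.ttest_ind(
            X[y == "A"], X[y == "B"], axis=0, equal_var=True
        ).statistic
        for order in (np.argsort(-tstats), np.argsort(tstats)):
            for k in range(2, X.shape[1] + 1):
                prefix = X[:, order[:k]].sum(axis=1) / np.sqrt(k)
                t_k = abs(
                    stats.ttest_ind(
                        prefix[y == "A"], prefix[y == "B"], equal_var=True
                    ).statistic
                )
                assert t_k <= t_single

    def test_single_gene_pathway(self):
        g = np.array([-1.0, -0.5, 0.5, 1.0])
        mat = make_pathway_matrix(g[:, None], ["A", "A", "B", "B"])
        fit, act = corgs_activity(mat)
        assert fit.genes == ["g0"]
        np.testing.assert_allclose(act.to_numpy(), g)

    def test_multiclass_rejected(self):
        rng = np.random.default_rng(1)
        mat = random_instance(rng, 9, 3, 3)
        with pytest.raises(ValidationError, match="two-class"):
            corgs_activity(mat)

    def test_invariant_to_duplicated_noise_gene(self):
        mat = self.strong_gene_instance()
        G = mat.values.to_numpy()
        dup = np.column_stack([G, G[:, -1]])  # duplicate a non-selected gene
        mat2 = make_pathway_matrix(dup, list(mat.label_array()))
        fit1, _ = corgs_activity(mat)
        fit2, _ = corgs_activity(mat2)
        assert fit1.genes == fit2.genes == ["g0"]


class TestPairwiseDistanceRanking:
    def test_separating_gene_ranks_first(self):
        samples = [f"s{i}" for i in range(6)]
        labels = dict(zip(samples, ["A"] * 3 + ["B"] * 3))
        std = pd.DataFrame(
            [[-1, -1, -1, 1, 1, 1], [0, 0, 0, 0, 0, 0]],
            index=["sep", "flat"],
            columns=samples,
            dtype=float,
        )
        top = rank_genes_pairwise_distance(std, labels, ["A", "B"], 2)
        assert top == ["sep", "flat"]

    def test_ties_keep_input_order(self):
        samples = [f"s{i}" for i in range(4)]
        labels = dict(zip(samples, ["A", "A", "B", "B"]))
        std = pd.DataFrame(
            np.zeros((3, 4)), index=["gz", "ga", "gm"], columns=samples
        )
        assert rank_genes_pairwise_distance(std, labels, ["A", "B"], 3) == [
            "gz", "ga", "gm",
        ]

    def test_three_class_score_is_pairwise_sum(self):
        samples = [f"s{i}" for i in range(6)]
        labels = dict(zip(samples, ["A", "A", "B", "B", "C", "C"]))
        std = pd.DataFrame(
            [[0, 0, 1, 1, 2, 2], [0, 0, 0, 0, 0, 0]],
            index=["g1", "g2"],
            columns=samples,
            dtype=float,
        )
        # score(g1) = |0−1| + |0−2| + |1−2| = 4 > 0 = score(g2)
        assert rank_genes_pairwise_distance(std, labels, ["A", "B", "C"], 1) == ["g1"]

    def test_clipping_warns(self):
        samples = ["s0", "s1", "s2", "s3"]
        labels = dict(zip(samples, ["A", "A", "B", "B"]))
        std = pd.DataFrame(np.zeros((2, 4)), index=["g1", "g2"], columns=samples)
        with pytest.warns(UserWarning, match="clipping"):
            top = rank_genes_pairwise_distance(std, labels, ["A", "B"], 10)
        assert len(top) == 2


class TestFitScoreContract:
    @pytest.fixture()
    def data(self, worked):
        return worked

    def test_mean_train_equals_direct(self, data):
        profile, gene_sets, _ = data
        fitted = fit_activity_method("mean", profile, gene_sets)
        act = score_samples(fitted, profile)
        from digs.preprocess import (
            apply_standardization,
            extract_pathway_matrix,
            fit_standardization,
        )

        params = fit_standardization(profile)
        std = apply_standardization(profile, params)
        for pw in act.pathway_names:
            mat = extract_pathway_matrix(
                std, gene_sets[pw], pw, profile.labels, profile.class_names, params
            )
            np.testing.assert_allclose(
                act.values[pw].to_numpy(), mean_activity(mat).to_numpy(), atol=1e-12
            )

    def test_digs_training_activities_enclosed(self, data):
        profile, gene_sets, truth = data
        fitted = fit_activity_method(
            "digs", profile, gene_sets, DigsConfig(nog=2, time_limit_s=30)
        )
        pw = truth.informative_pathways[0]
        res = fitted.digs_results[pw]
        assert res.objective == 0
        act = res.activity()
        for s, a in act.items():
            assert res.predict_enclosure(a) == profile.labels[s]

    def test_identical_raw_values_identical_scores(self, data):
        profile, gene_sets, _ = data
        fitted = fit_activity_method("mean", profile, gene_sets)
        clone = ExpressionProfile(
            values=profile.values.rename(columns={"s001": "sNEW"}),
        )
        act_orig = score_samples(fitted, profile)
        act_clone = score_samples(fitted, clone)
        np.testing.assert_allclose(
            act_clone.values.loc["sNEW"].to_numpy(),
            act_orig.values.loc["s001"].to_numpy(),
        )

    def test_sample_permutation_equivariance(self, data):
        profile, gene_sets, _ = data
        for method in ("mean", "median", "pca"):
            fitted = fit_activity_method(method, profile, gene_sets)
            act = score_samples(fitted, profile)
            perm = list(reversed(profile.sample_ids))
            act_perm = score_samples(fitted, profile.subset_samples(perm))
            np.testing.assert_allclose(
                act_perm.values.loc[profile.sample_ids].to_numpy(),
                act.values.to_numpy(),
                atol=1e-12,
            )

    def test_gene_order_invariance_of_simple_methods(self, data):
        profile, gene_sets, _ = data
        shuffled = GeneSetCollection(
            sets={n: list(reversed(g)) for n, g in gene_sets.sets.items()},
            descriptions=gene_sets.descriptions,
        )
        for method in ("mean", "median", "pca"):
            a1 = score_samples(
                fit_activity_method(method, profile, gene_sets), profile
            )
            a2 = score_samples(
                fit_activity_method(method, profile, shuffled), profile
            )
            np.testing.assert_allclose(
                np.abs(a1.values.to_numpy()), np.abs(a2.values.to_numpy()), atol=1e-9
            )

    def test_unknown_method_rejected(self, data):
        profile, gene_sets, _ = data
        with pytest.raises(ValidationError, match="unknown"):
            fit_activity_method("bogus", profile, gene_sets)
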