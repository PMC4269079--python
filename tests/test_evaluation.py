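import numpy as np
import pandas as pd
import pytest

from digs.evaluation import (
    EvaluationReport,
    active_gene_frequency,
    information_gain,
    mdl_discretize,
    nog_sensitivity,
    normalize_rates,
    rank_pathways_information_gain,
    run_comparison,
    significant_pathways,
    split_train_test,
)
from digs.exceptions import ValidationError
from digs.methods import PathwayActivityProfile
from digs.model import DigsConfig
from digs.synthetic import SynthSpec, generate


class TestSplit:
    def test_70_30_on_balanced_ten(self):
        labels = {f"s{i}": ("A" if i < 5 else "B") for i in range(10)}
        train, test = split_train_test(labels, fraction=0.7, seed=0)
        assert len(train) == 7 and len(test) == 3
        n_a = sum(labels[s] == "A" for s in train)
        assert n_a in (3, 4)
        assert set(train) | set(test) == set(labels)
        assert not set(train) & set(test)

    def test_half_split_of_two_and_two(self):
        labels = {"s1": "A", "s2": "A", "s3": "B", "s4": "B"}
        train, test = split_train_test(labels, fraction=0.5, seed=3)
        assert sorted(labels[s] for s in train) == ["A", "B"]
        assert sorted(labels[s] for s in test) == ["A", "B"]

    def test_singleton_class_rejected(self):
        labels = {"s1": "A", "s2": "B", "s3": "B"}
        with pytest.raises(ValidationError, match="A"):
            split_train_test(labels)

    def test_deterministic_given_seed(self):
        labels = {f"s{i}": f"c{i % 3}" for i in range(30)}
        a = split_train_test(labels, seed=11)
        b = split_train_test(labels, seed=11)
        c = split_train_test(labels, seed=12)
        assert a == b
        assert a != c

    def test_every_class_on_both_sides(self):
        labels = {f"s{i}": f"c{i % 4}" for i in range(17)}
        train, test = split_train_test(labels, seed=5)
        for c in {f"c{j}" for j in range(4)}:
            assert any(labels[s] == c for s in train)
            assert any(labels[s] == c for s in test)


class TestInformationGain:
    def test_constant_activity_scores_zero(self):
        assert information_gain([1.0] * 10, ["A"] * 5 + ["B"] * 5) == 0.0

    def test_perfect_two_class_separation_is_one_bit(self):
        x = list(np.linspace(-1, -0.5, 6)) + list(np.linspace(0.5, 1, 6))
        y = ["A"] * 6 + ["B"] * 6
        assert information_gain(x, y) == pytest.approx(1.0)

    def test_four_separated_classes_two_bits(self):
        x, y = [], []
        for i, c in enumerate(["A", "B", "C", "D"]):
            x += list(np.linspace(i * 10, i * 10 + 1, 8))
            y += [c] * 8
        assert information_gain(x, y) == pytest.approx(2.0)

    def test_mdl_rejects_noise_cuts(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = rng.choice(["A", "B"], size=40)
        assert len(mdl_discretize(x, y)) <= 1  # essentially no reliable cut

    def test_ranking_sorts_and_breaks_ties_by_name(self):
        samples = [f"s{i}" for i in range(12)]
        labels = dict(zip(samples, ["A"] * 6 + ["B"] * 6))
        sep = np.r_[np.linspace(-1, -0.5, 6), np.linspace(0.5, 1, 6)]
        flat = np.zeros(12)
        prof = PathwayActivityProfile(
            values=pd.DataFrame(
                {"Pz": flat, "Pgood": sep, "Pa": flat}, index=samples
            ),
            method="mean",
        )
        ranked = rank_pathways_information_gain(prof, labels)
        assert ranked[0][0] == "Pgood"
        assert [n for n, _ in ranked[1:]] == ["Pa", "Pz"]  # tie → name order


class TestNormalizeRates:
    def test_worked_example(self):
        rates = {"corgs": 75.13, "digs": 80.14}
        out = normalize_rates(rates)
        assert round(out["corgs"], 4) == 0.9375
        assert out["digs"] == 1.0

    def test_per_classifier_grouping(self):
        rates = {
            ("m1", "knn"): 0.5,
            ("m2", "knn"): 1.0,
            ("m1", "log"): 0.9,
            ("m2", "log"): 0.3,
        }
        out = normalize_rates(rates)
        assert out[("m1", "knn")] == 0.5
        assert out[("m2", "knn")] == 1.0
        assert out[("m1", "log")] == 1.0
        assert out[("m2", "log")] == pytest.approx(1 / 3)

    def test_single_method_all_ones(self):
        assert normalize_rates({("m", "c"): 0.42}) == {("m", "c"): 1.0}

    def test_scale_invariance(self):
        rates = {"a": 10.0, "b": 25.0, "c": 50.0}
        out1 = normalize_rates(rates)
        out2 = normalize_rates({k: 3.7 * v for k, v in rates.items()})
        for k in rates:
            assert out1[k] == pytest.approx(out2[k])

    def test_zero_maximum_rejected(self):
        with pytest.raises(ValidationError):
            normalize_rates({"a": 0.0, "b": 0.0})


def _tiny_report():
    rep = EvaluationReport(
        methods=["digs"], classifiers=["knn5"], n_repeats=50, seeds=[], k_top=1
    )
    # pathway X top-ranked in 30 repeats, Y in 20 repeats exactly
    for r in range(50):
        rep.pathway_rankings[r] = (
            ["X", "Y", "Z"] if r < 30 else ["Y", "X", "Z"] if r < 50 else []
        )
    rep.active_gene_counts = {("X", "g1"): 50, ("X", "g2"): 10, ("Y", "g3"): 11}
    return rep


class TestFrequencyAnalyses:
    def test_strictly_more_than_threshold(self):
        rep = _tiny_report()
        sig = significant_pathways(rep, k_top=1, min_count=20)
        assert sig == [("X", 30)]  # Y hit exactly 20 → excluded

    def test_k_top_widens_window(self):
        rep = _tiny_report()
        sig = dict(significant_pathways(rep, k_top=2, min_count=20))
        assert sig == {"X": 50, "Y": 50}

    def test_k_top_validation(self):
        with pytest.raises(ValidationError):
            significant_pathways(_tiny_report(), k_top=0)

    def test_active_gene_strict_threshold(self):
        out = active_gene_frequency(_tiny_report(), min_count=10)
        assert out == {"X": [("g1", 50)], "Y": [("g3", 11)]}


@pytest.fixture(scope="module")
def small_dataset():
    spec = SynthSpec(
        n_classes=3,
        class_sizes=(10, 10, 10),
        n_pathways=3,
        genes_per_pathway=(4, 6),
        n_informative_pathways=1,
        signal_genes_per_pathway=2,
        seed=17,
    )
    return generate(spec)


class TestRunComparison:
    def test_separable_fixture_scores_perfectly(self, small_dataset):
        from digs.io import GeneSetCollection

        profile, gene_sets, truth = small_dataset
        pw = truth.informative_pathways[0]
        separable = GeneSetCollection(sets={pw: gene_sets[pw]})
        rep = run_comparison(
            profile,
            separable,
            methods=("digs",),
            classifiers=("knn5",),
            n_repeats=1,
            seed=4,
            config=DigsConfig(nog=2, time_limit_s=2),
        )
        assert rep.mean_accuracy[("digs", "knn5")] == 1.0

    def test_repeat_determinism(self, small_dataset):
        profile, gene_sets, _ = small_dataset
        kwargs = dict(
            methods=("mean", "sg"),
            classifiers=("knn5",),
            n_repeats=2,
            seed=9,
        )
        r1 = run_comparison(profile, gene_sets, **kwargs)
        r2 = run_comparison(profile, gene_sets, **kwargs)
        assert r1.accuracies == r2.accuracies
        assert r1.seeds == r2.seeds

    def test_per_pathway_averages_over_pathways(self, small_dataset):
        """One pathway: the average is that pathway's accuracy — so a
        collection repeating the same pathway twice scores identically."""
        profile, gene_sets, truth = small_dataset
        from digs.io import GeneSetCollection

        pw = truth.informative_pathways[0]
        single = GeneSetCollection(sets={pw: gene_sets[pw]})
        doubled = GeneSetCollection(
            sets={pw: gene_sets[pw], "COPY": gene_sets[pw]}
        )
        kwargs = dict(
            methods=("per_pathway",), classifiers=("knn5",), n_repeats=2, seed=1
        )
        rep1 = run_comparison(profile, single, **kwargs)
        rep2 = run_comparison(profile, doubled, **kwargs)
        assert rep1.mean_accuracy == rep2.mean_accuracy

    def test_majority_dummy_matches_majority_fraction(self, small_dataset):
        profile, gene_sets, _ = small_dataset
        rep = run_comparison(
            profile,
            gene_sets,
            methods=("mean",),
            classifiers=("majority",),
            n_repeats=2,
            seed=2,
        )
        for (m, clf, r), acc in rep.accuracies.items():
            # balanced 3-class data: stratified test sets are near-balanced
            assert acc <= 0.5

    def test_corgs_dropped_on_multiclass(self, small_dataset):
        profile, gene_sets, _ = small_dataset
        rep = run_comparison(
            profile,
            gene_sets,
            methods=("mean", "corgs"),
            classifiers=("knn5",),
            n_repeats=1,
            seed=3,
        )
        assert "corgs" not in rep.methods

    def test_fitting_blind_to_test_data(self, small_dataset):
        """Corrupting test samples must not change any fitted parameters."""
        from digs.evaluation import split_train_test
        from digs.methods import fit_activity_method

        profile, gene_sets, _ = small_dataset
        train, test = split_train_test(profile.labels, seed=6)
        f1 = fit_activity_method("mean", profile.subset_samples(train), gene_sets)
        corrupted = profile.values.copy()
        corrupted.loc[:, test] += 500.0
        from digs.io import ExpressionProfile

        p2 = ExpressionProfile(
            values=corrupted, labels=profile.labels, class_names=profile.class_names
        )
        f2 = fit_activity_method("mean", p2.subset_samples(train), gene_sets)
        pd.testing.assert_series_equal(f1.params.mean, f2.params.mean)
        pd.testing.assert_series_equal(f1.params.sd, f2.params.sd)
        assert f1.members == f2.members

    def test_report_json_roundtrip(self, small_dataset, tmp_path):
        profile, gene_sets, _ = small_dataset
        rep = run_comparison(
            profile,
            gene_sets,
            methods=("digs", "mean"),
            classifiers=("knn5",),
            n_repeats=1,
            seed=8,
            config=DigsConfig(nog=2, time_limit_s=2),
        )
        out = tmp_path / "report.json"
        rep.to_json(out)
        back = EvaluationReport.from_json(out)
        assert back.accuracies == rep.accuracies
        assert back.pathway_rankings == rep.pathway_rankings
        assert back.active_gene_counts == rep.active_gene_counts


def test_nog_sensitivity_separable_fixture(small_dataset):
    from digs.io import GeneSetCollection

    profile, gene_sets, truth = small_dataset
    pw = truth.informative_pathways[0]
    table, _ = nog_sensitivity(
        profile,
        GeneSetCollection(sets={pw: gene_sets[pw]}),
        nog_values=(2, "all"),
        classifier="knn5",
        n_repeats=1,
        seed=13,
        config=DigsConfig(nog=2, time_limit_s=2),
    )
    assert list(table.index) == ["2", "all"]
    assert (table["mean_accuracy"] == 1.0).all()
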