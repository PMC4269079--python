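"""Repeated-split evaluation protocol and downstream pathway analysis.

The comparison protocol: repeat a stratified 70/30 train/test split, fit each
pathway-activity method on the training samples, train classifiers on the
training activity profile, and score accuracy on the held-out samples; mean
accuracies over repeats are then normalised per classifier by the best
method's rate.  On top of that sit the NoG sensitivity sweep, the
information-gain pathway ranking (Fayyad–Irani MDL discretisation) with
frequency-based significant-pathway selection, and the active-gene frequency
analysis of the MILP solutions.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.dummy import DummyClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier

from .exceptions import ValidationError
from .io import ExpressionProfile, GeneSetCollection
from .methods import (
    ACTIVITY_METHODS,
    PathwayActivityProfile,
    fit_activity_method,
    rank_genes_pairwise_distance,
    score_samples,
)
from .model import ACTIVE_TOL, DigsConfig
from .preprocess import apply_standardization, extract_pathway_matrix, fit_standardization

__all__ = [
    "EvaluationReport",
    "split_train_test",
    "run_comparison",
    "normalize_rates",
    "information_gain",
    "mdl_discretize",
    "rank_pathways_information_gain",
    "significant_pathways",
    "active_gene_frequency",
    "nog_sensitivity",
    "CLASSIFIERS",
]

logger = logging.getLogger(__name__)

#: classifier registry; values are factories taking the training-set size.
#: The published protocol also used SMO, a 2-hidden-layer neural network
#: (learning rate 0.1, momentum 0.2, 10000 epochs) and the Hyperbox MILP
#: classifier; those remain pluggable rather than shipped defaults.
CLASSIFIERS = {
    "knn5": lambda n_train: KNeighborsClassifier(n_neighbors=min(5, n_train)),
    "logistic": lambda n_train: LogisticRegression(max_iter=2000),
    "majority": lambda n_train: DummyClassifier(strategy="most_frequent"),
}


def split_train_test(
    labels: Mapping[str, str],
    fraction: float = 0.7,
    seed: int = 0,
    class_names: Sequence[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Stratified random train/test split of the labelled samples.

    Per class, ``floor(fraction · n_c)`` samples (never fewer than 1, never
    all) go to train; leftover slots are then topped up one class at a time,
    in class order, until the global ``round(fraction · S)`` target is met.
    Deterministic for a fixed seed.
    """
    if not 0 < fraction < 1:
        raise ValidationError("fraction must be in (0, 1)")
    sample_ids = list(labels)
    if class_names is None:
        seen: dict[str, None] = {}
        for s in sample_ids:
            seen.setdefault(labels[s], None)
        class_names = list(seen)
    by_class = {c: [s for s in sample_ids if labels[s] == c] for c in class_names}
    for c, members in by_class.items():
        if len(members) < 2:
            raise ValidationError(f"class {c!r} has {len(members)} sample(s); need ≥ 2")
    rng = np.random.default_rng(seed)
    train: set[str] = set()
    n_train_c: dict[str, int] = {}
    shuffled = {c: [m[i] for i in rng.permutation(len(m))] for c, m in ((c, by_class[c]) for c in class_names)}
    for c in class_names:
        n_c = len(by_class[c])
        n_train_c[c] = min(max(int(math.floor(fraction * n_c)), 1), n_c - 1)
    target = int(math.floor(fraction * len(sample_ids) + 0.5))
    while sum(n_train_c.values()) < target:
        grew = False
        for c in class_names:
            if sum(n_train_c.values()) >= target:
                break
            if n_train_c[c] < len(by_class[c]) - 1:
                n_train_c[c] += 1
                grew = True
        if not grew:
            break
    for c in class_names:
        train.update(shuffled[c][: n_train_c[c]])
    train_ids = [s for s in sample_ids if s in train]
    test_ids = [s for s in sample_ids if s not in train]
    return train_ids, test_ids


# ---------------------------------------------------------------------------
# information gain with Fayyad–Irani MDL discretisation
# ---------------------------------------------------------------------------

def _entropy(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _best_cut(x: np.ndarray, y: np.ndarray):
    """Best binary cut of sorted (x, y): (cut_index, weighted entropy)."""
    n = len(x)
    best = None
    for i in range(1, n):
        if x[i] == x[i - 1]:
            continue
        e = (i * _entropy(y[:i]) + (n - i) * _entropy(y[i:])) / n
        if best is None or e < best[1]:
            best = (i, e)
    return best


def _mdl_cuts(x: np.ndarray, y: np.ndarray, cuts: list[float]) -> None:
    n = len(x)
    if n < 2:
        return
    found = _best_cut(x, y)
    if found is None:
        return
    i, e_split = found
    e_full = _entropy(y)
    gain = e_full - e_split
    k = len(np.unique(y))
    k1, k2 = len(np.unique(y[:i])), len(np.unique(y[i:]))
    delta = math.log2(3**k - 2) - (k * e_full - k1 * _entropy(y[:i]) - k2 * _entropy(y[i:]))
    threshold = (math.log2(n - 1) + delta) / n
    if gain <= threshold:
        return
    cuts.append((x[i - 1] + x[i]) / 2.0)
    _mdl_cuts(x[:i], y[:i], cuts)
    _mdl_cuts(x[i:], y[i:], cuts)


def mdl_discretize(values: Sequence[float], labels: Sequence) -> list[float]:
    """Fayyad–Irani recursive MDL cut points for one continuous attribute."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    order = np.argsort(x, kind="stable")
    cuts: list[float] = []
    _mdl_cuts(x[order], y[order], cuts)
    return sorted(cuts)


def information_gain(values: Sequence[float], labels: Sequence) -> float:
    """H(class) − H(class | MDL-discretised attribute), in bits."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    cuts = mdl_discretize(x, y)
    if not cuts:
        return 0.0
    bins = np.digitize(x, cuts)
    h_cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_cond += mask.mean() * _entropy(y[mask])
    return _entropy(y) - h_cond


def rank_pathways_information_gain(
    activity: PathwayActivityProfile | pd.DataFrame,
    labels: Mapping[str, str],
) -> list[tuple[str, float]]:
    """Pathways sorted by information gain of their activity, descending.

    Ties are broken by pathway name so the ranking is deterministic.
    """
    values = activity.values if isinstance(activity, PathwayActivityProfile) else activity
    y = [labels[s] for s in values.index]
    scored = [
        (name, information_gain(values[name].to_numpy(), y)) for name in values.columns
    ]
    return sorted(scored, key=lambda item: (-item[1], item[0]))


# ---------------------------------------------------------------------------
# the repeated-split comparison protocol
# ---------------------------------------------------------------------------

GENE_LEVEL_METHODS = ("per_pathway", "sg")


@dataclass
class EvaluationReport:
    """Results of the repeated-split comparison.

    ``accuracies`` maps (method, classifier, repeat) to the fraction of
    correctly predicted test samples; ``pathway_rankings`` keeps, per repeat,
    the full information-gain ordering of pathways from the DIGS training
    profile, and ``active_gene_counts`` how often each gene carried non-zero
    MILP weight.
    """

    methods: list[str]
    classifiers: list[str]
    n_repeats: int
    seeds: list[int]
    k_top: int
    accuracies: dict = field(default_factory=dict)
    mean_accuracy: dict = field(default_factory=dict)
    normalized: dict = field(default_factory=dict)
    pathway_rankings: dict = field(default_factory=dict)
    pathway_top_counts: dict = field(default_factory=dict)
    active_gene_counts: dict = field(default_factory=dict)
    invalid_repeats: list[int] = field(default_factory=list)

    def finalize(self) -> None:
        """Compute means over valid repeats, normalised rates and top counts."""
        valid = [r for r in range(self.n_repeats) if r not in self.invalid_repeats]
        self.mean_accuracy = {}
        for m in self.methods:
            for clf in self.classifiers:
                vals = [
                    self.accuracies[(m, clf, r)]
                    for r in valid
                    if (m, clf, r) in self.accuracies
                ]
                if vals:
                    self.mean_accuracy[(m, clf)] = float(np.mean(vals))
        self.normalized = normalize_rates(self.mean_accuracy)
        self.pathway_top_counts = {}
        for ranking in self.pathway_rankings.values():
            for name in ranking[: self.k_top]:
                self.pathway_top_counts[name] = self.pathway_top_counts.get(name, 0) + 1

    def accuracy_table(self) -> pd.DataFrame:
        """Mean accuracies as a methods × classifiers DataFrame."""
        return pd.DataFrame(
            {
                clf: [self.mean_accuracy.get((m, clf), np.nan) for m in self.methods]
                for clf in self.classifiers
            },
            index=self.methods,
        )

    def summary(self) -> str:
        lines = [
            "Pathway-activity method comparison",
            "=" * 60,
            f"repeats: {self.n_repeats}  (invalid: {len(self.invalid_repeats)})",
            "",
            "mean test accuracy:",
            self.accuracy_table().round(4).to_string(),
            "",
            "normalised rates (per classifier, best method = 1):",
            pd.DataFrame(
                {
                    clf: [self.normalized.get((m, clf), np.nan) for m in self.methods]
                    for clf in self.classifiers
                },
                index=self.methods,
            ).round(4).to_string(),
        ]
        if self.pathway_top_counts:
            lines += ["", f"pathways most often top-{self.k_top} by information gain:"]
            for name, cnt in sorted(
                self.pathway_top_counts.items(), key=lambda kv: (-kv[1], kv[0])
            ):
                lines.append(f"  {name:<30s} {cnt}/{self.n_repeats}")
        return "\n".join(lines)

    # -- JSON round-trip (tuple keys flattened with '|') -------------------
    def to_json(self, path) -> None:
        def flat(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                    for k, v in d.items()}

        payload = {
            "methods": self.methods,
            "classifiers": self.classifiers,
            "n_repeats": self.n_repeats,
            "seeds": self.seeds,
            "k_top": self.k_top,
            "accuracies": flat(self.accuracies),
            "mean_accuracy": flat(self.mean_accuracy),
            "normalized": flat(self.normalized),
            "pathway_rankings": {str(k): v for k, v in self.pathway_rankings.items()},
            "pathway_top_counts": self.pathway_top_counts,
            "active_gene_counts": flat(self.active_gene_counts),
            "invalid_repeats": self.invalid_repeats,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EvaluationReport":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        rep = cls(
            methods=p["methods"],
            classifiers=p["classifiers"],
            n_repeats=p["n_repeats"],
            seeds=p["seeds"],
            k_top=p["k_top"],
            invalid_repeats=p["invalid_repeats"],
        )
        rep.accuracies = {
            (m, c, int(r)): v
            for key, v in p["accuracies"].items()
            for m, c, r in [key.split("|")]
        }
        rep.mean_accuracy = {
            tuple(k.split("|")): v for k, v in p["mean_accuracy"].items()
        }
        rep.normalized = {tuple(k.split("|")): v for k, v in p["normalized"].items()}
        rep.pathway_rankings = {int(k): v for k, v in p["pathway_rankings"].items()}
        rep.pathway_top_counts = p["pathway_top_counts"]
        rep.active_gene_counts = {
            tuple(k.split("|")): v for k, v in p["active_gene_counts"].items()
        }
        return rep


def _fit_predict_accuracy(clf_name, X_train, y_train, X_test, y_test) -> float:
    clf = CLASSIFIERS[clf_name](len(y_train))
    clf.fit(np.asarray(X_train, dtype=float), np.asarray(y_train))
    pred = clf.predict(np.asarray(X_test, dtype=float))
    return float(np.mean(pred == np.asarray(y_test)))


def run_comparison(
    profile: ExpressionProfile,
    gene_sets: GeneSetCollection,
    methods: Sequence[str] = ("digs", "mean", "median", "pca"),
    classifiers: Sequence[str] = ("knn5", "logistic"),
    n_repeats: int = 50,
    fraction: float = 0.7,
    seed: int = 0,
    config: DigsConfig | None = None,
    k_top: int = 1,
    n_top_genes: int | None = None,
) -> EvaluationReport:
    """Run the full repeated-split comparison protocol.

    *methods* may include the activity methods (``digs``, ``mean``,
    ``median``, ``pca``, ``corgs``) and the gene-level baselines
    (``per_pathway``, ``sg``).  CORGs is dropped automatically on problems
    with more than two classes.  A failing repeat is logged, marked invalid
    and excluded from the means.
    """
    if profile.labels is None:
        raise ValidationError("profile needs labels for evaluation")
    if not methods or not classifiers:
        raise ValidationError("methods and classifiers must be non-empty")
    unknown = [m for m in methods if m not in ACTIVITY_METHODS + GENE_LEVEL_METHODS]
    if unknown:
        raise ValidationError(f"unknown methods {unknown}")
    unknown_clf = [c for c in classifiers if c not in CLASSIFIERS]
    if unknown_clf:
        raise ValidationError(f"unknown classifiers {unknown_clf}")
    methods = list(methods)
    if profile.n_classes > 2 and "corgs" in methods:
        logger.info("dropping CORGs: only applicable to two-class problems")
        methods = [m for m in methods if m != "corgs"]
    config = config or DigsConfig()
    if n_top_genes is None:
        n_top_genes = len(gene_sets)

    rng = np.random.default_rng(seed)
    repeat_seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_repeats)]
    report = EvaluationReport(
        methods=methods,
        classifiers=list(classifiers),
        n_repeats=n_repeats,
        seeds=repeat_seeds,
        k_top=k_top,
    )
    for r, rseed in enumerate(repeat_seeds):
        try:
            _run_one_repeat(
                report, r, rseed, profile, gene_sets, methods, classifiers,
                fraction, config, n_top_genes,
            )
        except Exception:
            logger.exception("repeat %d failed; excluded from means", r)
            report.invalid_repeats.append(r)
    report.finalize()
    return report


def _run_one_repeat(
    report, r, rseed, profile, gene_sets, methods, classifiers,
    fraction, config, n_top_genes,
):
    train_ids, test_ids = split_train_test(
        profile.labels, fraction=fraction, seed=rseed, class_names=profile.class_names
    )
    train_prof = profile.subset_samples(train_ids)
    test_prof = profile.subset_samples(test_ids)
    y_train = train_prof.label_array()
    y_test = test_prof.label_array()

    for m in methods:
        if m in ACTIVITY_METHODS:
            fitted = fit_activity_method(m, train_prof, gene_sets, config)
            train_act = score_samples(fitted, train_prof)
            test_act = score_samples(fitted, test_prof)
            for clf in classifiers:
                report.accuracies[(m, clf, r)] = _fit_predict_accuracy(
                    clf, train_act.values, y_train, test_act.values, y_test
                )
            if m == "digs":
                ranking = rank_pathways_information_gain(train_act, train_prof.labels)
                report.pathway_rankings[r] = [name for name, _ in ranking]
                for pw, res in fitted.digs_results.items():
                    for g in res.active_genes:
                        key = (pw, g)
                        report.active_gene_counts[key] = (
                            report.active_gene_counts.get(key, 0) + 1
                        )
        elif m in ("per_pathway", "sg"):
            params = fit_standardization(train_prof)
            std_train = apply_standardization(train_prof, params)
            std_test = apply_standardization(test_prof, params)
            if m == "per_pathway":
                for clf in classifiers:
                    accs = []
                    for name, genes in gene_sets.sets.items():
                        mat = extract_pathway_matrix(
                            std_train, genes, name, train_prof.labels,
                            train_prof.class_names, params,
                        )
                        if mat is None:
                            continue
                        accs.append(
                            _fit_predict_accuracy(
                                clf,
                                mat.values,
                                y_train,
                                std_test.loc[mat.member_gene_ids].T,
                                y_test,
                            )
                        )
                    if accs:
                        report.accuracies[(m, clf, r)] = float(np.mean(accs))
            else:  # single-gene baseline on train-selected top genes
                top = rank_genes_pairwise_distance(
                    std_train, train_prof.labels, train_prof.class_names, n_top_genes
                )
                X_train = std_train.loc[top].T
                X_test = std_test.loc[top].T
                for clf in classifiers:
                    report.accuracies[(m, clf, r)] = _fit_predict_accuracy(
                        clf, X_train, y_train, X_test, y_test
                    )


def normalize_rates(mean_accuracy: Mapping) -> dict:
    """Divide each method's rate by the best rate of its classifier group.

    Keys may be plain method names (one group) or (method, classifier)
    tuples (one group per classifier).  The best method in each group maps
    to exactly 1.
    """
    if not mean_accuracy:
        raise ValidationError("empty rate table")
    items = list(mean_accuracy.items())
    tupled = isinstance(items[0][0], tuple)
    groups: dict = {}
    for k, v in items:
        g = k[1] if tupled else None
        groups.setdefault(g, []).append((k, float(v)))
    out = {}
    for g, pairs in groups.items():
        best = max(v for _, v in pairs)
        if best <= 0:
            raise ValidationError(f"zero maximum rate in classifier group {g!r}")
        for k, v in pairs:
            out[k] = v / best
    return out


def significant_pathways(
    report: EvaluationReport, k_top: int = 1, min_count: int = 20
) -> list[tuple[str, int]]:
    """Pathways appearing among the top-k ranked in more than *min_count* repeats.

    Counts are recomputed from the stored per-repeat rankings, so *k_top*
    may differ from the one used during the run.  The threshold is strict
    (count must exceed *min_count*).
    """
    if k_top < 1:
        raise ValidationError("k_top must be ≥ 1")
    counts: dict[str, int] = {}
    for ranking in report.pathway_rankings.values():
        for name in ranking[:k_top]:
            counts[name] = counts.get(name, 0) + 1
    selected = [(n, c) for n, c in counts.items() if c > min_count]
    return sorted(selected, key=lambda item: (-item[1], item[0]))


def active_gene_frequency(
    report: EvaluationReport, min_count: int = 10
) -> dict[str, list[tuple[str, int]]]:
    """Genes with non-zero MILP weight in more than *min_count* repeats.

    Returns pathway → [(gene, count)], counts strictly above the threshold.
    """
    out: dict[str, list[tuple[str, int]]] = {}
    for (pw, gene), cnt in report.active_gene_counts.items():
        if cnt > min_count:
            out.setdefault(pw, []).append((gene, cnt))
    for pw in out:
        out[pw].sort(key=lambda item: (-item[1], item[0]))
    return out


def nog_sensitivity(
    profile: ExpressionProfile,
    gene_sets: GeneSetCollection,
    nog_values: Sequence = (5, 10, 15, 20, "all"),
    classifier: str = "knn5",
    n_repeats: int = 10,
    seed: int = 0,
    config: DigsConfig | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Mean DIGS accuracy at each NoG value (``"all"`` lifts the cap).

    Returns the per-NoG table and the underlying reports.
    """
    if not nog_values:
        raise ValidationError("nog_values must be non-empty")
    base = config or DigsConfig()
    rows, reports = {}, {}
    for nog in nog_values:
        cfg = DigsConfig(
            nog=nog, u=base.u, epsilon=base.epsilon, mip_gap=base.mip_gap,
            time_limit_s=base.time_limit_s, solver_seed=base.solver_seed,
        )
        rep = run_comparison(
            profile, gene_sets, methods=("digs",), classifiers=(classifier,),
            n_repeats=n_repeats, seed=seed, config=cfg,
        )
        rows[str(nog)] = rep.mean_accuracy.get(("digs", classifier), np.nan)
        reports[str(nog)] = rep
    table = pd.DataFrame({"mean_accuracy": rows})
    table.index.name = "nog"
    return table, reports
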