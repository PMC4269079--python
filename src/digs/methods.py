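"""Pathway-activity inference methods and the shared fit/score contract.

Besides the MILP model this module implements the standard comparison
methods: per-pathway mean and median of standardised member-gene expression,
the first-principal-component score, the CORGs greedy t-statistic search
(two-class only), and the single-gene pairwise-class-distance ranking used by
the gene-level baseline.  ``fit_activity_method`` / ``score_samples`` give
every method the same train/score life cycle: all fitting statistics
(including standardisation) come from training samples only, and held-out
samples are scored with the stored parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import SolverTimeoutError, ValidationError
from .io import ExpressionProfile, GeneSetCollection
from .model import DigsConfig, DigsResults, compute_activity, solve_digs
from .preprocess import (
    StandardizationParams,
    StandardizedPathwayMatrix,
    apply_standardization,
    extract_pathway_matrix,
    fit_standardization,
)

__all__ = [
    "PathwayActivityProfile",
    "FittedActivityMethod",
    "ACTIVITY_METHODS",
    "mean_activity",
    "median_activity",
    "pca_activity",
    "corgs_activity",
    "rank_genes_pairwise_distance",
    "fit_activity_method",
    "score_samples",
]

logger = logging.getLogger(__name__)

ACTIVITY_METHODS = ("digs", "mean", "median", "pca", "corgs")


@dataclass
class PathwayActivityProfile:
    """Samples × pathways activity matrix plus the method that produced it."""

    values: pd.DataFrame  # samples × pathways
    method: str

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("activity profile contains non-finite values")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)


def mean_activity(matrix: StandardizedPathwayMatrix) -> pd.Series:
    """Mean standardised expression over member genes, per sample."""
    return matrix.values.mean(axis=1).rename(matrix.pathway_name)


def median_activity(matrix: StandardizedPathwayMatrix) -> pd.Series:
    """Median standardised expression over member genes, per sample.

    An even number of members uses the midpoint of the two central values.
    """
    return matrix.values.median(axis=1).rename(matrix.pathway_name)


def pca_activity(matrix: StandardizedPathwayMatrix) -> tuple[np.ndarray, pd.Series]:
    """First-principal-component pathway score.

    Returns the unit-norm loading vector (sign fixed so that the entry of
    largest magnitude is positive) and the per-sample projection.  The
    gene-gene covariance is estimated on the training samples with divisor
    n − 1.
    """
    X = matrix.values.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValidationError("PCA activity needs at least two samples")
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    if not np.any(cov):
        warnings.warn(
            f"pathway {matrix.pathway_name!r}: zero covariance; PCA activity is all zeros",
            stacklevel=2,
        )
        loading = np.zeros(X.shape[1])
        loading[0] = 1.0
        return loading, pd.Series(0.0, index=matrix.sample_ids, name=matrix.pathway_name)
    eigval, eigvec = np.linalg.eigh(cov)
    loading = eigvec[:, -1]
    pivot = int(np.argmax(np.abs(loading)))
    if loading[pivot] < 0:
        loading = -loading
    act = pd.Series(X @ loading, index=matrix.sample_ids, name=matrix.pathway_name)
    return loading, act


@dataclass
class CorgsFit:
    genes: list[str]
    direction: int  # +1: descending-t ordering won, −1: ascending
    sqrt_k: bool = True


def _corgs_score(X: np.ndarray, y01: np.ndarray, sqrt_k: bool) -> float:
    """|t| of the running activity for the currently selected gene columns."""
    k = X.shape[1]
    act = X.sum(axis=1) / (np.sqrt(k) if sqrt_k else k)
    t = stats.ttest_ind(act[y01 == 0], act[y01 == 1], equal_var=True).statistic
    return abs(float(t))


def corgs_activity(
    matrix: StandardizedPathwayMatrix,
    sqrt_k_scaling: bool = True,
    bidirectional: bool = True,
) -> tuple[CorgsFit, pd.Series]:
    """Condition-responsive-genes activity (two-class problems only).

    Genes are ranked by two-sample t-statistic; starting from the top of the
    descending ordering (and, when *bidirectional*, also the ascending one)
    genes are added greedily while the |t| of the running summed activity
    keeps increasing.  The running activity of k genes is their summed
    standardised expression scaled by 1/√k.  The ordering whose final
    activity reaches the larger |t| wins.
    """
    if matrix.n_classes != 2:
        raise ValidationError(
            "CORGs is only applicable to two-class problems "
            f"(got {matrix.n_classes} classes)"
        )
    labels = matrix.label_array()
    y01 = (labels == matrix.class_names[1]).astype(int)
    X = matrix.values.to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstats = stats.ttest_ind(X[y01 == 0], X[y01 == 1], axis=0, equal_var=True).statistic
    tstats = np.nan_to_num(tstats, nan=0.0)

    def greedy(order: np.ndarray) -> tuple[list[int], float]:
        chosen = [int(order[0])]
        best = _corgs_score(X[:, chosen], y01, sqrt_k_scaling)
        for g in order[1:]:
            cand = chosen + [int(g)]
            score = _corgs_score(X[:, cand], y01, sqrt_k_scaling)
            if score > best:
                chosen, best = cand, score
            else:
                break
        return chosen, best

    desc = np.argsort(-tstats, kind="stable")
    candidates = [(greedy(desc), 1)]
    if bidirectional and matrix.n_genes > 1:
        asc = np.argsort(tstats, kind="stable")
        candidates.append((greedy(asc), -1))
    (chosen, _), direction = max(candidates, key=lambda item: item[0][1])
    genes = [matrix.member_gene_ids[i] for i in chosen]
    k = len(chosen)
    act = X[:, chosen].sum(axis=1) / (np.sqrt(k) if sqrt_k_scaling else k)
    fit = CorgsFit(genes=genes, direction=direction, sqrt_k=sqrt_k_scaling)
    return fit, pd.Series(act, index=matrix.sample_ids, name=matrix.pathway_name)


def rank_genes_pairwise_distance(
    standardized: pd.DataFrame,
    labels: Mapping[str, str],
    class_names: Sequence[str],
    n_top: int,
) -> list[str]:
    """Rank genes by aggregated pairwise class-mean distance, return top n.

    Per-gene score = Σ_{k<c} |mean_k − mean_c| of the standardised values;
    ties keep input (file) order.  This is the simple multiclass filter used
    by the single-gene baseline.
    """
    if n_top < 1:
        raise ValidationError("n_top must be ≥ 1")
    if n_top > standardized.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds gene count {standardized.shape[0]}; clipping",
            stacklevel=2,
        )
        n_top = standardized.shape[0]
    lab = np.asarray([labels[s] for s in standardized.columns])
    X = standardized.to_numpy(dtype=float)
    class_means = np.column_stack(
        [X[:, lab == c].mean(axis=1) for c in class_names]
    )
    C = len(class_names)
    score = np.zeros(standardized.shape[0])
    for k in range(C):
        for c in range(k + 1, C):
            score += np.abs(class_means[:, k] - class_means[:, c])
    order = np.argsort(-score, kind="stable")  # stable: ties keep input order
    return [standardized.index[i] for i in order[:n_top]]


@dataclass
class FittedActivityMethod:
    """Everything needed to score new samples for one activity method.

    Per pathway the stored scorer is: DIGS — the signed weight vector;
    mean/median — the member-gene list; PCA — the loading vector; CORGs —
    the selected gene subset.  Standardisation parameters are the ones
    fitted on the training samples.
    """

    method: str
    params: StandardizationParams
    class_names: list[str]
    members: dict[str, list[str]]  # pathway → member genes present at fit
    scorers: dict[str, object]
    digs_results: dict[str, DigsResults] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def pathway_names(self) -> list[str]:
        return list(self.members)


def _pathway_score(method: str, scorer, values: pd.DataFrame) -> np.ndarray:
    if method == "digs":
        return compute_activity(scorer, values).to_numpy()
    if method in ("mean", "median"):
        agg = values.mean(axis=1) if method == "mean" else values.median(axis=1)
        return agg.to_numpy()
    if method == "pca":
        return values.to_numpy(dtype=float) @ scorer
    if method == "corgs":
        sub = values.loc[:, scorer.genes].to_numpy(dtype=float)
        k = sub.shape[1]
        return sub.sum(axis=1) / (np.sqrt(k) if scorer.sqrt_k else k)
    raise ValidationError(f"unknown activity method {method!r}")


def fit_activity_method(
    method: str,
    train_profile: ExpressionProfile,
    gene_sets: GeneSetCollection,
    config: DigsConfig | None = None,
) -> FittedActivityMethod:
    """Fit one activity-inference method on raw training samples.

    Standardisation is fitted here, on the training samples only.  Pathways
    with no member genes in the profile are skipped; a DIGS solve that times
    out without an incumbent skips that pathway as well.
    """
    if method not in ACTIVITY_METHODS:
        raise ValidationError(f"unknown activity method {method!r}")
    if train_profile.labels is None:
        raise ValidationError("training profile needs labels")
    config = config or DigsConfig()
    params = fit_standardization(train_profile)
    standardized = apply_standardization(train_profile, params)
    members: dict[str, list[str]] = {}
    scorers: dict[str, object] = {}
    digs_results: dict[str, DigsResults] = {}
    skipped: dict[str, str] = {}
    for name, genes in gene_sets.sets.items():
        mat = extract_pathway_matrix(
            standardized, genes, name, train_profile.labels,
            train_profile.class_names, params,
        )
        if mat is None:
            skipped[name] = "no member genes in profile"
            continue
        try:
            if method == "digs":
                res = solve_digs(mat, config)
                scorers[name] = res.weight
                digs_results[name] = res
            elif method in ("mean", "median"):
                scorers[name] = mat.member_gene_ids
            elif method == "pca":
                loading, _ = pca_activity(mat)
                scorers[name] = loading
            elif method == "corgs":
                fit, _ = corgs_activity(mat)
                scorers[name] = fit
        except SolverTimeoutError:
            logger.warning("pathway %r: solver timeout with no incumbent; skipped", name)
            skipped[name] = "solver timeout"
            continue
        members[name] = mat.member_gene_ids
    return FittedActivityMethod(
        method=method,
        params=params,
        class_names=list(train_profile.class_names),
        members=members,
        scorers=scorers,
        digs_results=digs_results,
        skipped=skipped,
    )


def score_samples(
    fitted: FittedActivityMethod, profile: ExpressionProfile
) -> PathwayActivityProfile:
    """Score (possibly held-out) raw samples with a fitted activity method.

    Samples are standardised with the training parameters, then each stored
    per-pathway scorer is applied; pathways skipped at fit time are absent.
    """
    standardized = apply_standardization(profile, fitted.params).T  # samples × genes
    cols = {}
    for name, genes in fitted.members.items():
        values = standardized.loc[:, genes]
        cols[name] = _pathway_score(fitted.method, fitted.scorers[name], values)
    frame = pd.DataFrame(cols, index=standardized.index)
    return PathwayActivityProfile(values=frame, method=fitted.method)
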