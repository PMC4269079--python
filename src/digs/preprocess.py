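"""Per-gene standardisation and pathway submatrix extraction.

Raw expression A_sm is standardised gene-wise to G_sm by subtracting the mean
and dividing by the standard deviation; the population convention (divisor n)
is the default, with ``ddof`` exposed for the sample convention.  In the
evaluation pipeline the statistics are always fitted on training samples only
and re-applied to held-out samples, so inference stays blind to the test set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionProfile, GeneSetCollection

__all__ = [
    "StandardizationParams",
    "StandardizedPathwayMatrix",
    "fit_standardization",
    "apply_standardization",
    "extract_pathway_matrix",
    "iter_pathway_matrices",
]

logger = logging.getLogger(__name__)


@dataclass
class StandardizationParams:
    """Per-gene location/scale estimates used to z-score expression values."""

    mean: pd.Series
    sd: pd.Series
    ddof: int = 0

    def __post_init__(self) -> None:
        if (self.sd < 0).any():
            raise ValidationError("standard deviations must be non-negative")


@dataclass
class StandardizedPathwayMatrix:
    """The S × M standardised expression submatrix of one pathway.

    ``values`` is samples × member genes (G_sm); ``member_gene_ids`` keeps
    the gene-set order filtered to genes present in the profile.
    """

    pathway_name: str
    member_gene_ids: list[str]
    values: pd.DataFrame  # samples × genes
    params: StandardizationParams
    sample_ids: list[str]
    labels: dict[str, str]
    class_names: list[str]

    def __post_init__(self) -> None:
        if len(self.member_gene_ids) < 1:
            raise ValidationError(
                f"pathway {self.pathway_name!r} has no member genes in the profile"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def label_array(self) -> np.ndarray:
        return np.asarray([self.labels[s] for s in self.sample_ids])

    def class_sample_counts(self) -> dict[str, int]:
        lab = self.label_array()
        return {c: int((lab == c).sum()) for c in self.class_names}


def fit_standardization(
    profile: ExpressionProfile,
    sample_subset: Sequence[str] | None = None,
    ddof: int = 0,
) -> StandardizationParams:
    """Fit per-gene mean and standard deviation over *sample_subset*.

    ``ddof=0`` gives the population standard deviation (divisor n), the
    package default; ``ddof=1`` the sample convention.
    """
    if sample_subset is None:
        sample_subset = profile.sample_ids
    sample_subset = list(sample_subset)
    if not sample_subset:
        raise ValidationError("sample subset for standardisation is empty")
    sub = profile.values.loc[:, sample_subset]
    mean = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=ddof)
    return StandardizationParams(mean=mean, sd=sd, ddof=ddof)


def apply_standardization(
    profile: ExpressionProfile, params: StandardizationParams
) -> pd.DataFrame:
    """Return the genes × samples z-score matrix (A − mean) / sd.

    Genes with zero fitted variance map to 0 for every sample — a constant
    gene carries no discriminative signal, and this keeps pathway membership
    stable instead of dropping the gene.
    """
    missing = profile.values.index.difference(params.mean.index)
    if len(missing):
        raise ValidationError(
            f"no standardisation parameters for genes {list(missing[:5])}"
        )
    mean = params.mean.loc[profile.values.index]
    sd = params.sd.loc[profile.values.index]
    safe_sd = sd.replace(0.0, np.nan)
    g = profile.values.sub(mean, axis=0).div(safe_sd, axis=0)
    return g.fillna(0.0)


def extract_pathway_matrix(
    standardized: pd.DataFrame,
    gene_set: Sequence[str],
    pathway_name: str,
    labels: Mapping[str, str],
    class_names: Sequence[str],
    params: StandardizationParams,
) -> StandardizedPathwayMatrix | None:
    """Carve the pathway-specific submatrix out of a standardised profile.

    Member order is the gene-set order filtered to genes present in the
    profile (exact, case-sensitive matching).  An empty intersection returns
    ``None`` after logging a warning, so callers can skip the pathway.
    """
    present = [g for g in gene_set if g in standardized.index]
    if not present:
        logger.warning(
            "pathway %r: no member genes found in the expression profile; skipped",
            pathway_name,
        )
        return None
    sample_ids = list(standardized.columns)
    return StandardizedPathwayMatrix(
        pathway_name=pathway_name,
        member_gene_ids=present,
        values=standardized.loc[present].T,
        params=params,
        sample_ids=sample_ids,
        labels={s: labels[s] for s in sample_ids},
        class_names=list(class_names),
    )


def iter_pathway_matrices(
    standardized: pd.DataFrame,
    gene_sets: GeneSetCollection,
    labels: Mapping[str, str],
    class_names: Sequence[str],
    params: StandardizationParams,
):
    """Yield ``(pathway_name, StandardizedPathwayMatrix)`` skipping empty ones."""
    for name, genes in gene_sets.sets.items():
        mat = extract_pathway_matrix(
            standardized, genes, name, labels, class_names, params
        )
        if mat is not None:
            yield name, mat
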