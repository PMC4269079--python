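import numpy as np
import pandas as pd
import pytest

from digs.preprocess import StandardizationParams, StandardizedPathwayMatrix
from digs.synthetic import worked_fixture


def make_pathway_matrix(G, labels, class_names=None, name="P"):
    """Wrap a raw S × M array (already on the standardised scale) for the MILP."""
    G = np.asarray(G, dtype=float)
    S, M = G.shape
    sample_ids = [f"s{i}" for i in range(S)]
    gene_ids = [f"g{j}" for j in range(M)]
    if class_names is None:
        seen = {}
        for lab in labels:
            seen.setdefault(lab, None)
        class_names = list(seen)
    params = StandardizationParams(
        mean=pd.Series(0.0, index=gene_ids), sd=pd.Series(1.0, index=gene_ids)
    )
    return StandardizedPathwayMatrix(
        pathway_name=name,
        member_gene_ids=gene_ids,
        values=pd.DataFrame(G, index=sample_ids, columns=gene_ids),
        params=params,
        sample_ids=sample_ids,
        labels=dict(zip(sample_ids, labels)),
        class_names=list(class_names),
    )


def random_instance(rng, n_samples, n_genes, n_classes, standardise=True):
    """A random labelled instance with round-robin class assignment."""
    classes = [f"c{j}" for j in range(n_classes)]
    labels = [classes[i % n_classes] for i in range(n_samples)]
    G = rng.normal(0.0, 1.0, size=(n_samples, n_genes))
    if standardise:
        G = (G - G.mean(axis=0)) / G.std(axis=0)
    return make_pathway_matrix(G, labels, classes)


def assert_solution_invariants(res, tol=1e-6):
    """Assert every formulation invariant of a solved pathway MILP."""
    rep = res.constraint_report(tol=tol)
    assert rep["abs_weight_sum_err"] <= tol, rep
    assert rep["two_sided_weight_max"] <= tol, rep
    assert rep["n_active"] <= rep["nog"], rep
    assert rep["enclosure_violation"] <= 1e-5, rep
    assert rep["separation_violation"] <= tol, rep
    assert rep["objective_mismatch"] == 0, rep


@pytest.fixture(scope="session")
def worked():
    """The committed tiny instance: profile, gene sets, planted truth."""
    return worked_fixture()
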