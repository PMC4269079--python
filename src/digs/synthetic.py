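"""Synthetic expression data with planted signed-subset pathway signals.

The generator emulates exactly the structure the pathway MILP is designed to
recover: each informative pathway carries a 1-D latent axis on which the
phenotype classes sit at distinct offsets, and a small subset of member genes
loads on that axis with random signs.  All remaining genes are independent
noise.  The raw matrix is then corrupted gene-wise by random affine maps so
that the standardisation step is exercised non-trivially.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .io import ExpressionProfile, GeneSetCollection

__all__ = ["SynthSpec", "GroundTruth", "generate", "worked_fixture"]


@dataclass
class SynthSpec:
    """Parameters of the planted-signal generator.

    Defaults plant a clearly separable three-class signal: class offsets
    (−3, 0, +3) on the latent axis against latent noise sd 0.3 and gene-level
    background sd 0.1, i.e. a separation margin far wider than the noise, so
    the MILP objective on informative pathways is 0 by construction.
    """

    n_classes: int = 3
    class_sizes: tuple = (20, 20, 20)
    n_pathways: int = 8
    genes_per_pathway: tuple = (5, 30)
    n_informative_pathways: int = 3
    signal_genes_per_pathway: int = 3
    class_offsets: tuple = (-3.0, 0.0, 3.0)
    noise_sd: float = 0.3
    background_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValidationError("need at least two classes")
        if len(self.class_sizes) != self.n_classes:
            raise ValidationError("class_sizes length must equal n_classes")
        if len(self.class_offsets) != self.n_classes:
            raise ValidationError("class_offsets length must equal n_classes")
        if len(set(self.class_offsets)) != self.n_classes:
            raise ValidationError("class offsets must be pairwise distinct")
        if self.n_informative_pathways > self.n_pathways:
            raise ValidationError("n_informative_pathways exceeds n_pathways")
        if self.signal_genes_per_pathway < 1:
            raise ValidationError("signal_genes_per_pathway must be ≥ 1")
        lo, hi = self.genes_per_pathway
        if lo < 1 or hi < lo:
            raise ValidationError("genes_per_pathway must be a valid (min, max) range")
        if self.signal_genes_per_pathway > lo:
            raise ValidationError("signal genes cannot exceed the smallest pathway size")
        if self.noise_sd <= 0 or self.background_sd <= 0:
            raise ValidationError("noise_sd and background_sd must be positive")


@dataclass
class GroundTruth:
    """What was planted: informative pathways and their signed signal genes."""

    informative_pathways: list[str]
    signal_genes: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "informative_pathways": self.informative_pathways,
                    "signal_genes": self.signal_genes,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            p = json.load(fh)
        return cls(
            informative_pathways=p["informative_pathways"],
            signal_genes={
                pw: {g: int(s) for g, s in genes.items()}
                for pw, genes in p["signal_genes"].items()
            },
        )


def generate(spec: SynthSpec) -> tuple[ExpressionProfile, GeneSetCollection, GroundTruth]:
    """Generate a labelled profile, gene sets and the planted ground truth.

    Per informative pathway, sample s gets a latent value
    ``z_s = offset(class_s) + N(0, noise_sd)``; its signal genes read
    ``sign_g · z_s + N(0, background_sd)`` and every other gene is standard
    normal.  Each gene row is finally passed through a random affine map
    ``a·x + b`` (a > 0), which standardisation must undo.  Byte-identical
    output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    class_names = [f"c{i + 1}" for i in range(spec.n_classes)]
    sample_ids, labels = [], {}
    for c, size in zip(class_names, spec.class_sizes):
        for j in range(size):
            sid = f"s{len(sample_ids) + 1:03d}"
            sample_ids.append(sid)
            labels[sid] = c
    S = len(sample_ids)
    offsets = dict(zip(class_names, spec.class_offsets))
    offset_vec = np.asarray([offsets[labels[s]] for s in sample_ids])

    lo, hi = spec.genes_per_pathway
    pathway_sizes = rng.integers(lo, hi + 1, size=spec.n_pathways)
    pathway_names = [f"PW{i + 1:02d}" for i in range(spec.n_pathways)]
    informative = pathway_names[: spec.n_informative_pathways]

    gene_rows: list[np.ndarray] = []
    gene_ids: list[str] = []
    sets: dict[str, list[str]] = {}
    truth = GroundTruth(informative_pathways=list(informative))
    for name, size in zip(pathway_names, pathway_sizes):
        members = []
        is_informative = name in informative
        if is_informative:
            z = offset_vec + rng.normal(0.0, spec.noise_sd, size=S)
            signal_idx = rng.choice(size, size=spec.signal_genes_per_pathway, replace=False)
            signs = rng.choice([-1, 1], size=spec.signal_genes_per_pathway)
            signal = dict(zip(signal_idx.tolist(), signs.tolist()))
            truth.signal_genes[name] = {}
        for j in range(size):
            gid = f"g{len(gene_ids) + 1:04d}"
            gene_ids.append(gid)
            members.append(gid)
            if is_informative and j in signal:
                row = signal[j] * z + rng.normal(0.0, spec.background_sd, size=S)
                truth.signal_genes[name][gid] = int(signal[j])
            else:
                row = rng.normal(0.0, 1.0, size=S)
            gene_rows.append(row)
        sets[name] = members

    raw = np.vstack(gene_rows)
    scale = rng.uniform(0.5, 2.0, size=raw.shape[0])[:, None]
    shift = rng.uniform(-5.0, 5.0, size=raw.shape[0])[:, None]
    raw = scale * raw + shift

    profile = ExpressionProfile(
        values=pd.DataFrame(raw, index=gene_ids, columns=sample_ids),
        labels=labels,
        class_names=class_names,
    )
    gene_sets = GeneSetCollection(
        sets=sets, descriptions={n: "synthetic pathway" for n in pathway_names}
    )
    return profile, gene_sets, truth


def _fixture_dir() -> Path:
    return Path(resources.files("digs.data") / "worked_fixture")


def worked_fixture() -> tuple[ExpressionProfile, GeneSetCollection, GroundTruth]:
    """The tiny committed instance used in examples and docs.

    Three classes × three samples, two pathways of 3 and 5 genes, one
    informative pathway with two signal genes of opposite sign.  Loaded from
    the text files shipped with the package so the same instance also
    exercises the format readers.
    """
    from .io import attach_labels, read_expression_matrix, read_gmt

    d = _fixture_dir()
    profile = read_expression_matrix(d / "expr.tsv", dialect="tsv")
    profile = attach_labels(profile, d / "labels.cls", dialect="cls")
    gene_sets = read_gmt(d / "sets.gmt")
    truth = GroundTruth.from_json(d / "truth.json")
    return profile, gene_sets, truth
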