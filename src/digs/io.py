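"""Readers and writers for the external text formats.

Supported formats:

* expression matrices — plain TSV (first column gene identifiers, header row
  sample identifiers) or the GCT dialect (``#1.2`` preamble, dimension line,
  ``Description`` column);
* phenotype labels — GSEA-style CLS files or a two-column TSV;
* gene-set collections — GMT (one pathway per line: name, description,
  member gene symbols);
* pathway-activity profiles — TSV with pathways as rows, written so that they
  round-trip exactly through :func:`read_expression_matrix`.

All files are UTF-8, tab-separated text.  Gene matching against GMT entries is
exact, case-sensitive string equality throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

__all__ = [
    "ExpressionProfile",
    "GeneSetCollection",
    "read_expression_matrix",
    "read_labels",
    "attach_labels",
    "read_gmt",
    "write_activity_profile",
]


@dataclass
class ExpressionProfile:
    """A genes × samples expression matrix with optional phenotype labels.

    ``values`` holds the raw expression values A_sm, one row per gene and one
    column per sample.  ``labels`` maps every sample identifier to exactly one
    class name; ``class_names`` fixes the class order (order of first
    appearance in the label file).
    """

    values: pd.DataFrame
    labels: dict[str, str] | None = None
    class_names: list[str] | None = None

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        dup_g = idx[idx.duplicated()]
        if len(dup_g):
            raise FormatError(f"duplicate gene identifier {dup_g[0]!r}")
        dup_s = cols[cols.duplicated()]
        if len(dup_s):
            raise FormatError(f"duplicate sample identifier {dup_s[0]!r}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.labels is not None:
            missing = [s for s in cols if s not in self.labels]
            if missing:
                raise ValidationError(
                    f"samples without a class label: {missing[:5]}"
                )
            extra = [s for s in self.labels if s not in cols]
            if extra:
                raise ValidationError(
                    f"labels reference samples absent from the matrix: {extra[:5]}"
                )
            if self.class_names is None:
                seen: dict[str, None] = {}
                for s in cols:
                    seen.setdefault(self.labels[s], None)
                self.class_names = list(seen)
            unknown = set(self.labels.values()) - set(self.class_names)
            if unknown:
                raise ValidationError(f"labels outside class_names: {sorted(unknown)}")
            if len(self.class_names) < 2:
                raise ValidationError("at least two phenotype classes are required")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        if self.class_names is None:
            raise ValidationError("profile has no labels attached")
        return len(self.class_names)

    def label_array(self) -> np.ndarray:
        """Labels in sample (column) order."""
        if self.labels is None:
            raise ValidationError("profile has no labels attached")
        return np.asarray([self.labels[s] for s in self.sample_ids])

    def with_labels(
        self,
        labels: Mapping[str, str],
        class_names: Sequence[str] | None = None,
    ) -> "ExpressionProfile":
        """Return a copy with labels attached (validated against the matrix)."""
        return ExpressionProfile(
            values=self.values,
            labels=dict(labels),
            class_names=list(class_names) if class_names is not None else None,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionProfile":
        labels = (
            {s: self.labels[s] for s in sample_ids} if self.labels is not None else None
        )
        return ExpressionProfile(
            values=self.values.loc[:, list(sample_ids)],
            labels=labels,
            class_names=list(self.class_names) if self.class_names else None,
        )


@dataclass
class GeneSetCollection:
    """An ordered pathway → member-gene-symbols map (GMT contents)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate symbols")

    @property
    def pathway_names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


def _parse_float(token: str, gene: str, sample: str) -> float:
    try:
        v = float(token)
    except ValueError:
        raise FormatError(
            f"non-numeric expression value {token!r} at gene {gene!r}, sample {sample!r}"
        ) from None
    if not math.isfinite(v):
        raise FormatError(
            f"non-finite expression value {token!r} at gene {gene!r}, sample {sample!r}"
        )
    return v


def _parse_matrix_lines(
    lines: list[str], *, skip_description: bool
) -> pd.DataFrame:
    header = lines[0].rstrip("\n").split("\t")
    offset = 2 if skip_description else 1
    sample_ids = header[offset:]
    seen_s: set[str] = set()
    for s in sample_ids:
        if s in seen_s:
            raise FormatError(f"duplicate sample identifier {s!r}")
        seen_s.add(s)
    genes: list[str] = []
    rows: list[list[float]] = []
    seen_g: set[str] = set()
    for line in lines[1:]:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        gene = fields[0]
        if gene in seen_g:
            raise FormatError(f"duplicate gene identifier {gene!r}")
        seen_g.add(gene)
        cells = fields[offset:]
        if len(cells) != len(sample_ids):
            raise FormatError(
                f"gene {gene!r}: {len(cells)} values for {len(sample_ids)} samples"
            )
        rows.append(
            [_parse_float(tok, gene, sample_ids[j]) for j, tok in enumerate(cells)]
        )
        genes.append(gene)
    return pd.DataFrame(rows, index=genes, columns=sample_ids, dtype=float)


def read_expression_matrix(path: str | Path, dialect: str = "tsv") -> ExpressionProfile:
    """Read a genes × samples expression matrix (without labels).

    ``dialect="tsv"``: header row of sample ids, first column gene ids.
    ``dialect="gct"``: ``#1.2`` preamble, a ``<n_genes>\\t<n_samples>``
    dimension line, then a header with a ``Description`` column which is
    discarded.  Row and column order is preserved from the file.
    """
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines:
        raise FormatError(f"{path}: empty file")
    if dialect == "tsv":
        df = _parse_matrix_lines(lines, skip_description=False)
    elif dialect == "gct":
        if not lines[0].startswith("#1."):
            raise FormatError(f"{path}: missing GCT version preamble '#1.2'")
        if len(lines) < 3:
            raise FormatError(f"{path}: truncated GCT file")
        dims = lines[1].split("\t")
        try:
            n_genes, n_samples = int(dims[0]), int(dims[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed GCT dimension line {lines[1]!r}") from None
        df = _parse_matrix_lines(lines[2:], skip_description=True)
        if df.shape != (n_genes, n_samples):
            raise FormatError(
                f"{path}: GCT dimension line declares {n_genes}×{n_samples} "
                f"but body has {df.shape[0]}×{df.shape[1]}"
            )
    else:
        raise ValidationError(f"unknown expression dialect {dialect!r}")
    return ExpressionProfile(values=df)


def read_labels(
    path: str | Path,
    dialect: str = "cls",
    sample_ids: Sequence[str] | None = None,
) -> tuple[dict, list[str]]:
    """Read phenotype labels; returns ``(labels, class_names)``.

    CLS dialect: line 1 ``<S> <C> 1``; line 2 ``# name1 name2 ...``; line 3
    one token per sample (class names, or 0-based class indices).  Labels are
    keyed by ``sample_ids`` when given, else by 0-based position.  TSV
    dialect: two columns ``sample_id<TAB>class``; class order is order of
    first appearance.
    """
    path = Path(path)
    lines = [ln for ln in path.read_text(encoding="utf-8").splitlines() if ln.strip()]
    if dialect == "cls":
        if len(lines) < 3:
            raise FormatError(f"{path}: CLS file needs 3 lines")
        head = lines[0].split()
        try:
            n_samples, n_classes = int(head[0]), int(head[1])
        except (ValueError, IndexError):
            raise FormatError(f"{path}: malformed CLS header {lines[0]!r}") from None
        if n_classes < 2:
            raise ValidationError(f"{path}: CLS declares {n_classes} classes; need ≥ 2")
        name_line = lines[1].split()
        if not name_line or name_line[0].lstrip("#"):
            # allow "#A B" as well as "# A B"
            if not name_line[0].startswith("#"):
                raise FormatError(f"{path}: CLS class-name line must start with '#'")
            name_line[0] = name_line[0][1:]
        else:
            name_line = name_line[1:]
        class_names = [n for n in name_line if n]
        if len(class_names) != n_classes:
            raise FormatError(
                f"{path}: {len(class_names)} class names for declared C={n_classes}"
            )
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise FormatError(
                f"{path}: {len(tokens)} label tokens for declared S={n_samples}"
            )
        resolved: list[str] = []
        for tok in tokens:
            if tok in class_names:
                resolved.append(tok)
            elif tok.isdigit() and int(tok) < n_classes:
                resolved.append(class_names[int(tok)])
            else:
                raise FormatError(f"{path}: unknown class token {tok!r}")
        keys: Sequence = sample_ids if sample_ids is not None else range(n_samples)
        if sample_ids is not None and len(sample_ids) != n_samples:
            raise ValidationError(
                f"{path}: CLS declares {n_samples} samples but matrix has {len(sample_ids)}"
            )
        return dict(zip(keys, resolved)), class_names
    if dialect == "tsv":
        labels: dict[str, str] = {}
        class_names = []
        start = 0
        first = lines[0].split("\t")
        if len(first) >= 2 and first[1].lower() in {"class", "label", "phenotype"}:
            start = 1  # tolerate a header row
        for ln in lines[start:]:
            fields = ln.split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}: label line {ln!r} needs 2 columns")
            sid, cls = fields[0], fields[1]
            if sid in labels:
                raise FormatError(f"{path}: duplicate sample {sid!r} in label file")
            labels[sid] = cls
            if cls not in class_names:
                class_names.append(cls)
        if len(class_names) < 2:
            raise ValidationError(f"{path}: need ≥ 2 classes, found {len(class_names)}")
        return labels, class_names
    raise ValidationError(f"unknown label dialect {dialect!r}")


def attach_labels(
    profile: ExpressionProfile, path: str | Path, dialect: str = "cls"
) -> ExpressionProfile:
    """Read a label file and attach it to *profile* (CLS maps by position)."""
    labels, class_names = read_labels(
        path, dialect=dialect, sample_ids=profile.sample_ids if dialect == "cls" else None
    )
    if dialect == "tsv":
        labels = {str(k): v for k, v in labels.items()}
    return profile.with_labels(labels, class_names)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set collection (pathway, description, member symbols).

    Duplicate symbols within one line are dropped keeping the first
    occurrence; empty trailing fields are ignored.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(fields)} fields; need ≥ 3")
        name, desc = fields[0], fields[1]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate pathway name {name!r}")
        genes: list[str] = []
        for g in fields[2:]:
            if g and g not in genes:
                genes.append(g)
        if not genes:
            raise FormatError(f"{path}:{lineno}: pathway {name!r} has no member genes")
        sets[name] = genes
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_activity_profile(profile, path: str | Path) -> None:
    """Write a pathway-activity profile as TSV, pathways as rows.

    Values are written with full ``repr`` precision so the file round-trips
    through :func:`read_expression_matrix` bit-exactly.
    """
    values = profile.values  # samples × pathways
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValidationError("cannot write an empty activity profile")
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("pathway\t" + "\t".join(map(str, values.index)) + "\n")
        for pw in values.columns:
            row = "\t".join(repr(float(v)) for v in values[pw].to_numpy())
            fh.write(f"{pw}\t{row}\n")
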