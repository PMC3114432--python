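"""Expression-matrix, annotation and sequence I/O plus preprocessing.

Abundance conventions: transcript abundance is absolute fluorescence
intensity; protein abundance is the peptide-hit count, where a detected
protein has at least one hit — zeros and ``NA`` cells are both treated as
*undetected* (missing), never as measured zeros.

Preprocessing implemented here: quantile normalization across samples,
log2 transformation, and collapse of replicate columns to per-condition
means with a minimum-presence rule.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GeneAnnotation",
    "ExpressionMatrix",
    "CollapsedExpression",
    "read_expression",
    "write_expression",
    "quantile_normalize",
    "collapse_replicates",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_annotation_gff3",
    "read_cds_fasta",
    "write_cds_fasta",
]

ANNOTATION_COLUMNS = [
    "gene_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "cellular_role",
    "product",
]


class FormatError(ValueError):
    """A file does not conform to the documented layout."""


@dataclasses.dataclass(frozen=True)
class GeneAnnotation:
    """A gene's genomic location and descriptive attributes.

    Coordinates are 1-based inclusive base pairs on ``replicon_id``;
    ``strand`` is ``'+'`` or ``'-'``.
    """

    gene_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    cellular_role: str = ""
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: illegal strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclasses.dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with explicit missingness.

    ``values`` holds nonnegative reals with ``NaN`` as the missing marker;
    ``samples`` maps each column to a ``(condition, replicate)`` pair.
    ``kind`` is ``"transcript_fluorescence"`` or ``"peptide_counts"``.
    """

    gene_ids: list[str]
    samples: list[tuple[str, int]]
    values: np.ndarray
    kind: str = "transcript_fluorescence"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.samples)):
            raise ValueError("values shape inconsistent with labels")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene_ids")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample labels")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("negative abundance value")

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for cond, _ in self.samples:
            seen.setdefault(cond)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{c}.{r}" for c, r in self.samples]
        return pd.DataFrame(self.values, index=self.gene_ids, columns=cols)


@dataclasses.dataclass
class CollapsedExpression:
    """Per-condition log2 abundances after replicate collapse.

    ``values`` is genes x conditions on the log2 scale (``NaN`` missing);
    ``n_replicates_used`` counts the non-missing replicates behind each
    entry.
    """

    gene_ids: list[str]
    conditions: list[str]
    values: np.ndarray
    n_replicates_used: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.conditions
        )

    def series(self, condition: str) -> pd.Series:
        """Log2 abundances for one condition, indexed by gene."""
        j = self.conditions.index(condition)
        return pd.Series(self.values[:, j], index=self.gene_ids)


def _parse_sample_label(label: str) -> tuple[str, int]:
    label = label.strip()
    if not label:
        raise FormatError("empty sample label in header")
    cond, dot, rep = label.rpartition(".")
    if dot and rep.isdigit():
        return cond, int(rep)
    return label, 1


def read_expression(path: str | Path, kind: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene id, header
    ``condition.replicate``; empty cells or ``NA`` are missing)."""
    df = pd.read_csv(
        path, sep="\t", dtype={0: str}, na_values=["NA"], keep_default_na=False
    )
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene_id plus >=1 sample column")
    gene_ids = df.iloc[:, 0].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        raise ValueError(f"{path}: duplicate gene_id rows")
    samples = [_parse_sample_label(c) for c in df.columns[1:]]
    body = df.iloc[:, 1:].mask(lambda x: x == "")
    try:
        values = body.astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric abundance cell: {exc}") from exc
    if np.nanmin(values, initial=0.0) < 0:
        raise ValueError(f"{path}: negative abundance value")
    return ExpressionMatrix(gene_ids, samples, values, kind)


def write_expression(m: ExpressionMatrix, path: str | Path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def _column_sorted_quantiles(col: np.ndarray, grid_len: int) -> np.ndarray:
    """Sorted non-missing values of one column interpolated to a common grid."""
    v = np.sort(col[~np.isnan(col)])
    if v.size == grid_len:
        return v
    src = np.linspace(0.0, 1.0, v.size)
    dst = np.linspace(0.0, 1.0, grid_len)
    return np.interp(dst, src, v)


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto a common empirical distribution.

    The reference distribution is the mean of the per-column sorted values
    (interpolated to a grid of length = the largest non-missing column
    count). Ties within a column receive the mean reference value over their
    tied rank span; missing cells stay missing.
    """
    values = m.values
    if values.shape[1] < 2:
        raise ValueError("quantile normalization needs >=2 samples")
    n_present = (~np.isnan(values)).sum(axis=0)
    if np.any(n_present < 2):
        bad = [f"{c}.{r}" for (c, r), n in zip(m.samples, n_present) if n < 2]
        raise ValueError(f"columns with <2 non-missing values: {bad}")
    grid_len = int(n_present.max())
    reference = np.mean(
        [_column_sorted_quantiles(values[:, j], grid_len) for j in range(values.shape[1])],
        axis=0,
    )
    out = np.full_like(values, np.nan)
    for j in range(values.shape[1]):
        col = values[:, j]
        mask = ~np.isnan(col)
        v = col[mask]
        n = v.size
        # per-column reference quantiles at integer ranks 1..n
        if n == grid_len:
            ref = reference
        else:
            ref = np.interp(
                np.linspace(0.0, 1.0, n), np.linspace(0.0, 1.0, grid_len), reference
            )
        order = np.argsort(v, kind="mergesort")
        normalized = np.empty(n)
        sorted_v = v[order]
        # walk tie groups in rank order; each group gets the mean reference
        # value over its rank span
        i = 0
        while i < n:
            k = i + 1
            while k < n and sorted_v[k] == sorted_v[i]:
                k += 1
            normalized[order[i:k]] = ref[i:k].mean()
            i = k
        out[mask, j] = normalized
    return ExpressionMatrix(list(m.gene_ids), list(m.samples), out, m.kind)


def collapse_replicates(
    m: ExpressionMatrix, min_present: int | None = None
) -> CollapsedExpression:
    """Collapse replicate columns to per-condition mean log2 abundances.

    A gene/condition entry is kept only when at least ``min_present``
    replicates are non-missing (default: 3, capped at the condition's
    replicate count, so single-replicate designs default to 1).
    """
    conditions = m.conditions
    n_genes = len(m.gene_ids)
    out = np.full((n_genes, len(conditions)), np.nan)
    n_used = np.zeros((n_genes, len(conditions)), dtype=int)
    with np.errstate(invalid="ignore"):
        if np.any(m.values <= 0):
            bad = np.argwhere(m.values <= 0)[0]
            raise ValueError(
                f"non-positive abundance for gene {m.gene_ids[bad[0]]} "
                f"sample {m.samples[bad[1]]}: log2 undefined"
            )
    for jc, cond in enumerate(conditions):
        cols = [j for j, (c, _) in enumerate(m.samples) if c == cond]
        need = min(min_present, len(cols)) if min_present is not None else min(3, len(cols))
        if need < 1:
            raise ValueError("min_present must be >= 1")
        block = m.values[:, cols]
        present = ~np.isnan(block)
        count = present.sum(axis=1)
        ok = count >= need
        logs = np.where(present, np.log2(np.where(present, block, 1.0)), np.nan)
        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.filterwarnings("ignore", message="Mean of empty slice")
            means = np.nanmean(logs, axis=1)
        out[ok, jc] = means[ok]
        n_used[:, jc] = np.where(ok, count, 0)
    return CollapsedExpression(list(m.gene_ids), conditions, out, n_used)


def read_annotation_tsv(path: str | Path) -> list[GeneAnnotation]:
    """Read the documented 7-column annotation TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing annotation columns {missing}")
    anns = [
        GeneAnnotation(
            gene_id=row.gene_id,
            replicon_id=row.replicon_id,
            start=int(row.start),
            end=int(row.end),
            strand=row.strand,
            cellular_role=row.cellular_role,
            product=row.product,
        )
        for row in df.itertuples()
    ]
    ids = [a.gene_id for a in anns]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene_id")
    return anns


def write_annotation_tsv(annotations: Iterable[GeneAnnotation], path: str | Path) -> None:
    rows = [dataclasses.asdict(a) for a in annotations]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, sep="\t", index=False)


def read_annotation_gff3(path: str | Path) -> list[GeneAnnotation]:
    """Read gene features from a GFF3 file (1-based inclusive coordinates).

    ``ID`` (or ``locus_tag``) names the gene; ``product`` and
    ``cellular_role`` are taken from same-named attributes when present.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    anns = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        attrs = feat.attributes
        gene_id = (attrs.get("ID") or attrs.get("locus_tag") or [feat.id])[0]
        anns.append(
            GeneAnnotation(
                gene_id=gene_id,
                replicon_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                cellular_role=(attrs.get("cellular_role") or [""])[0],
                product=(attrs.get("product") or [""])[0],
            )
        )
    ids = [a.gene_id for a in anns]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate gene ids in GFF3")
    return anns


def read_cds_fasta(path: str | Path) -> dict[str, str]:
    """Read coding sequences; record ids must match annotation gene ids."""
    from Bio import SeqIO

    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ValueError(f"{path}: duplicate FASTA id {rec.id}")
        out[rec.id] = str(rec.seq).upper()
    return out


def write_cds_fasta(cds: Mapping[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene_id, seq in cds.items():
            fh.write(f">{gene_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
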