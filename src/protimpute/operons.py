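"""Distance-only operon prediction.

Consecutive same-strand genes on the same replicon whose intergenic gaps
are below a base-pair threshold (default: strictly less than 15 bp) are
merged into one operon. This deliberately permissive rule trades precision
for coverage; runs of length one are not operons.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd

from .data_io import GeneAnnotation

__all__ = ["OperonSet", "detect_operons", "intergenic_gap"]


@dataclasses.dataclass
class OperonSet:
    """Ordered operon membership: each operon is a list of gene ids in
    genomic order; every operon has at least two genes."""

    operons: list[list[str]]

    def __post_init__(self) -> None:
        if any(len(op) < 2 for op in self.operons):
            raise ValueError("operons must contain >=2 genes")
        self.index: dict[str, int] = {}
        for i, op in enumerate(self.operons):
            for g in op:
                if g in self.index:
                    raise ValueError(f"gene {g} assigned to two operons")
                self.index[g] = i

    def __len__(self) -> int:
        return len(self.operons)

    def operon_of(self, gene_id: str) -> int | None:
        return self.index.get(gene_id)

    def sizes(self) -> list[int]:
        return [len(op) for op in self.operons]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"operon_id": i, "gene_id": g, "position_in_operon": j}
            for i, op in enumerate(self.operons)
            for j, g in enumerate(op)
        ]
        return pd.DataFrame(rows, columns=["operon_id", "gene_id", "position_in_operon"])

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "OperonSet":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
        ops = [
            grp.sort_values("position_in_operon")["gene_id"].tolist()
            for _, grp in df.groupby("operon_id", sort=True)
        ]
        return cls(ops)


def intergenic_gap(prev: GeneAnnotation, nxt: GeneAnnotation) -> int:
    """Bases strictly between two genes; <= 0 when they overlap or abut."""
    return nxt.start - prev.end - 1


def detect_operons(
    annotations: Sequence[GeneAnnotation], max_gap_bp: int = 15
) -> OperonSet:
    """Predict operons as maximal same-strand runs with gaps < ``max_gap_bp``.

    Genes are sorted by (replicon, start); overlapping same-strand genes
    count as gap <= 0 and are merged. The threshold is strict: a gap of
    exactly ``max_gap_bp`` breaks the run. Membership is invariant to the
    input ordering.
    """
    ordered = sorted(annotations, key=lambda a: (a.replicon_id, a.start, a.end))
    operons: list[list[str]] = []
    run: list[GeneAnnotation] = []

    def flush() -> None:
        if len(run) >= 2:
            operons.append([a.gene_id for a in run])

    for ann in ordered:
        if run and (
            ann.replicon_id != run[-1].replicon_id
            or ann.strand != run[-1].strand
            or intergenic_gap(run[-1], ann) >= max_gap_bp
        ):
            flush()
            run = []
        run.append(ann)
    flush()
    return OperonSet(operons)
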