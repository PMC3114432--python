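"""Per-gene sequence and protein features used by the imputation and
missingness models.

All codon statistics use the bacterial genetic code (NCBI table 11). Stop
codons are excluded from every usage statistic; methionine and tryptophan
(single-codon amino acids) are excluded from CAI, Nc families, reference
weights and synonymous third-position composition, following the CodonW
convention. Protein indices follow the ExPASy ProtParam definitions, with
the Kyte-Doolittle hydropathy and Guruprasad dipeptide-instability tables
taken from ``Bio.SeqUtils.ProtParamData``.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id
from Bio.SeqUtils import molecular_weight as _bio_molecular_weight
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KD

__all__ = [
    "CodonProfile",
    "ReferenceCodonWeights",
    "codon_counts",
    "translate_cds",
    "rscu",
    "build_reference_weights",
    "cai",
    "effective_number_of_codons",
    "third_position_composition",
    "gc_content",
    "protein_indices",
    "correspondence_axes",
    "correspondence_analysis",
    "assemble_features",
    "SENSE_CODONS",
    "SYNONYMOUS_FAMILIES",
]

_TABLE = unambiguous_dna_by_id[11]
STOP_CODONS = tuple(sorted(_TABLE.stop_codons))
#: the 61 sense codons of the bacterial code, sorted
SENSE_CODONS = tuple(sorted(_TABLE.forward_table))
_AA_OF = dict(_TABLE.forward_table)

#: amino acid -> sorted tuple of its codons (six-fold families kept whole)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(_AA_OF.items()):
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)

#: amino acids whose codon choice is synonymously variable (not Met/Trp)
VARIABLE_AAS = tuple(
    aa for aa, fam in SYNONYMOUS_FAMILIES.items() if len(fam) >= 2
)
_STANDARD_AAS = set("ACDEFGHIKLMNPQRSTVWY")


@dataclasses.dataclass
class CodonProfile:
    """In-frame codon counts of one coding sequence."""

    gene_id: str
    counts: dict[str, int]
    length_codons: int
    has_terminal_stop: bool = False

    def total(self, codons: Iterable[str]) -> int:
        return sum(self.counts.get(c, 0) for c in codons)


@dataclasses.dataclass
class ReferenceCodonWeights:
    """Relative-adaptiveness weights w for CAI, from a reference gene set.

    ``w[c]`` is the pooled RSCU of codon ``c`` divided by the maximum RSCU
    in its synonymous family, so the preferred codon of every family has
    w = 1. Zero-count reference codons receive a pseudo-count of 0.5 before
    normalization and all weights are floored at 1e-3, so log(w) is always
    finite.
    """

    w: dict[str, float]
    reference_gene_ids: list[str]


def codon_counts(
    cds: str, gene_id: str = "", max_ambiguous_fraction: float = 0.01
) -> CodonProfile:
    """Count in-frame codons of a coding sequence.

    Codons containing ambiguous bases are dropped with a warning when they
    make up at most ``max_ambiguous_fraction`` of the gene; beyond that the
    sequence is rejected. An internal stop codon is always an error; a
    single terminal stop is counted and flagged.
    """
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene_id or 'CDS'}: length {len(seq)} not a multiple of 3")
    if len(seq) == 0:
        raise ValueError(f"{gene_id or 'CDS'}: empty sequence")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    clean: list[str] = []
    n_ambiguous = 0
    for idx, codon in enumerate(codons):
        if set(codon) <= set("ACGT"):
            if codon in STOP_CODONS and idx != len(codons) - 1:
                raise ValueError(
                    f"{gene_id or 'CDS'}: internal stop codon {codon} at codon {idx + 1}"
                )
            clean.append(codon)
        else:
            n_ambiguous += 1
    if n_ambiguous > max_ambiguous_fraction * len(codons):
        raise ValueError(
            f"{gene_id or 'CDS'}: {n_ambiguous}/{len(codons)} codons contain "
            "ambiguous bases"
        )
    if n_ambiguous:
        warnings.warn(
            f"{gene_id or 'CDS'}: dropped {n_ambiguous} codon(s) with ambiguous bases",
            stacklevel=2,
        )
    counts: dict[str, int] = {}
    for codon in clean:
        counts[codon] = counts.get(codon, 0) + 1
    return CodonProfile(
        gene_id=gene_id,
        counts=counts,
        length_codons=len(clean),
        has_terminal_stop=codons[-1] in STOP_CODONS,
    )


def translate_cds(cds: str, gene_id: str = "") -> str:
    """Translate a CDS (table 11), dropping a terminal stop."""
    seq = cds.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"{gene_id or 'CDS'}: length not a multiple of 3")
    aas = []
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if codon in STOP_CODONS:
            if i != len(seq) - 3:
                raise ValueError(f"{gene_id or 'CDS'}: internal stop codon")
            break
        aa = _AA_OF.get(codon)
        if aa is None:
            continue  # ambiguous codon, mirrored by codon_counts drop rule
        aas.append(aa)
    return "".join(aas)


def rscu(profile: CodonProfile) -> dict[str, float]:
    """Relative synonymous codon usage for all 61 sense codons.

    RSCU of a codon is its count divided by the mean count over its
    synonymous family; families with zero total usage give ``NaN``.
    """
    out: dict[str, float] = {}
    for fam in SYNONYMOUS_FAMILIES.values():
        total = profile.total(fam)
        if total == 0:
            for c in fam:
                out[c] = math.nan
        else:
            mean = total / len(fam)
            for c in fam:
                out[c] = profile.counts.get(c, 0) / mean
    return out


def build_reference_weights(
    profiles: Sequence[CodonProfile], floor: float = 1e-3
) -> ReferenceCodonWeights:
    """CAI relative-adaptiveness weights from pooled reference-gene counts.

    The reference set is conventionally a panel of highly expressed genes
    (ribosomal proteins). Weights are defined only for synonymously
    variable codons; a family never observed in the pool gets neutral
    weights of 1.
    """
    if not profiles:
        raise ValueError("empty reference gene set")
    pooled: dict[str, int] = {}
    for p in profiles:
        for c, n in p.counts.items():
            if c not in STOP_CODONS:
                pooled[c] = pooled.get(c, 0) + n
    w: dict[str, float] = {}
    for aa in VARIABLE_AAS:
        fam = SYNONYMOUS_FAMILIES[aa]
        counts = np.array([pooled.get(c, 0) for c in fam], dtype=float)
        if counts.max() == 0:
            for c in fam:
                w[c] = 1.0
            continue
        counts[counts == 0] = 0.5
        for c, n in zip(fam, counts):
            w[c] = max(n / counts.max(), floor)
    return ReferenceCodonWeights(w=w, reference_gene_ids=[p.gene_id for p in profiles])


def _eligible_codons() -> tuple[str, ...]:
    return tuple(c for aa in VARIABLE_AAS for c in SYNONYMOUS_FAMILIES[aa])


def cai(profile: CodonProfile, weights: ReferenceCodonWeights) -> float:
    """Codon adaptation index: count-weighted geometric mean of w over the
    gene's synonymously variable codons (Met, Trp and stops excluded)."""
    log_sum = 0.0
    n = 0
    for c in _eligible_codons():
        k = profile.counts.get(c, 0)
        if k:
            log_sum += k * math.log(weights.w[c])
            n += k
    if n == 0:
        raise ValueError(f"{profile.gene_id}: no CAI-eligible codons")
    return math.exp(log_sum / n)


#: Nc model: degeneracy class -> (coefficient in Wright's formula, amino acids)
_NC_CLASSES: dict[int, tuple[float, tuple[str, ...]]] = {}
for _aa in VARIABLE_AAS:
    _k = len(SYNONYMOUS_FAMILIES[_aa])
    coef = {2: 9.0, 3: 1.0, 4: 5.0, 6: 3.0}[_k]
    prev = _NC_CLASSES.get(_k, (coef, ()))
    _NC_CLASSES[_k] = (coef, prev[1] + (_aa,))


def effective_number_of_codons(profile: CodonProfile) -> float:
    """Wright's effective number of codons (Nc), clamped to [20, 61].

    Per synonymous family with n >= 2 observations the codon homozygosity
    is F = (n * sum(p^2) - 1)/(n - 1); the class mean F̄k is weighted by
    family counts. Nc = 2 + 9/F̄2 + 1/F̄3 + 5/F̄4 + 3/F̄6. A missing
    three-fold class (Ile unobserved) is imputed as (F̄2 + F̄4)/2; any other
    missing class leaves Nc undefined (NaN).
    """
    f_bar: dict[int, float] = {}
    for k, (_, aas) in _NC_CLASSES.items():
        fs, weights_ = [], []
        for aa in aas:
            fam = SYNONYMOUS_FAMILIES[aa]
            counts = np.array([profile.counts.get(c, 0) for c in fam], dtype=float)
            n = counts.sum()
            if n < 2:
                continue
            p = counts / n
            fs.append((n * np.sum(p**2) - 1.0) / (n - 1.0))
            weights_.append(n)
        if fs:
            f_bar[k] = float(np.average(fs, weights=weights_))
    if 3 not in f_bar:
        if 2 in f_bar and 4 in f_bar:
            f_bar[3] = (f_bar[2] + f_bar[4]) / 2.0
        else:
            return math.nan
    if any(k not in f_bar or f_bar[k] <= 0 for k in _NC_CLASSES):
        return math.nan
    nc = 2.0 + sum(coef / f_bar[k] for k, (coef, _) in _NC_CLASSES.items())
    return float(min(max(nc, 20.0), 61.0))


def third_position_composition(profile: CodonProfile) -> dict[str, float]:
    """Base frequencies at synonymous third codon positions.

    Only synonymously variable codons count (Met, Trp, stops excluded);
    A3s + T3s + C3s + G3s = 1 and GC3s = C3s + G3s.
    """
    totals = {b: 0 for b in "ACGT"}
    for c in _eligible_codons():
        totals[c[2]] += profile.counts.get(c, 0)
    n = sum(totals.values())
    if n == 0:
        raise ValueError(f"{profile.gene_id}: no synonymously variable codons")
    comp = {f"{b}3s": totals[b] / n for b in "ATCG"}
    comp["GC3s"] = comp["C3s"] + comp["G3s"]
    return comp


def gc_content(cds: str) -> float:
    seq = cds.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def protein_indices(protein: str) -> dict[str, float]:
    """ExPASy-ProtParam-style indices of a protein sequence.

    Returns GRAVY (mean Kyte-Doolittle hydropathy), AROMO (mole fraction
    F+Y+W), the aliphatic index, the Guruprasad instability index, average
    molecular weight in Da, and residue length.
    """
    protein = protein.upper()
    if len(protein) < 2:
        raise ValueError("protein shorter than 2 residues: instability undefined")
    bad = set(protein) - _STANDARD_AAS
    if bad:
        raise ValueError(f"non-standard amino acid letters {sorted(bad)}")
    length = len(protein)
    gravy = sum(_KD[a] for a in protein) / length
    aromo = sum(protein.count(a) for a in "FYW") / length
    mole_percent = {a: 100.0 * protein.count(a) / length for a in "AVIL"}
    aliphatic = (
        mole_percent["A"]
        + 2.9 * mole_percent["V"]
        + 3.9 * (mole_percent["I"] + mole_percent["L"])
    )
    instability = (10.0 / length) * sum(
        _DIWV[protein[i]][protein[i + 1]] for i in range(length - 1)
    )
    return {
        "GRAVY": gravy,
        "AROMO": aromo,
        "AliphaticIndex": aliphatic,
        "InstabilityIndex": instability,
        "MolecularWeight": _bio_molecular_weight(protein, seq_type="protein"),
        "length": float(length),
    }


def correspondence_analysis(
    table: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Symmetric correspondence analysis of a nonnegative table.

    Returns (row principal coordinates, column principal coordinates,
    per-axis inertias). Zero-margin columns are dropped; each axis is
    oriented so that its largest-|loading| column has a positive loading.
    """
    X = table.to_numpy(dtype=float)
    if np.any(X < 0) or not np.all(np.isfinite(X)):
        raise ValueError("table must be finite and nonnegative")
    col_keep = X.sum(axis=0) > 0
    X = X[:, col_keep]
    cols = table.columns[col_keep]
    row_margin = X.sum(axis=1)
    if np.any(row_margin <= 0):
        bad = table.index[np.asarray(row_margin <= 0)].tolist()[:5]
        raise ValueError(f"rows with zero margin: {bad}")
    grand = X.sum()
    P = X / grand
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    # orient axes: largest-|loading| column positive
    col_pc = (Vt.T / np.sqrt(c)[:, None]) * sv[None, :]
    for a in range(sv.size):
        j = int(np.argmax(np.abs(col_pc[:, a])))
        if col_pc[j, a] < 0:
            U[:, a] *= -1
            col_pc[:, a] *= -1
    row_pc = (U / np.sqrt(r)[:, None]) * sv[None, :]
    names = [f"axis{i + 1}" for i in range(sv.size)]
    return (
        pd.DataFrame(row_pc, index=table.index, columns=names),
        pd.DataFrame(col_pc, index=cols, columns=names),
        sv**2,
    )


def correspondence_axes(usage_matrix: pd.DataFrame, n_axes: int) -> pd.DataFrame:
    """First ``n_axes`` row scores of symmetric correspondence analysis,
    ordered by decreasing inertia."""
    row_pc, _, inertia = correspondence_analysis(usage_matrix)
    achievable = int(np.sum(inertia > 1e-12 * max(inertia.max(), 1.0)))
    if achievable < n_axes:
        raise ValueError(
            f"table supports only {achievable} CA axes, {n_axes} requested"
        )
    return row_pc.iloc[:, :n_axes]


def _amino_acid_counts(profile: CodonProfile) -> dict[str, int]:
    out = {aa: 0 for aa in SYNONYMOUS_FAMILIES}
    for c, n in profile.counts.items():
        aa = _AA_OF.get(c)
        if aa is not None:
            out[aa] += n
    return out


def assemble_features(
    annotations: Sequence["GeneAnnotation"],
    cds: Mapping[str, str],
    collapsed: "CollapsedExpression | None" = None,
    reference_gene_ids: Sequence[str] | None = None,
    weights: ReferenceCodonWeights | None = None,
    external_columns: pd.DataFrame | None = None,
    n_axes: int = 4,
    include_codon_counts: bool = True,
) -> pd.DataFrame:
    """Assemble the per-gene feature table from annotation + sequences.

    Columns: gene_length_log2 (log2 CDS length in bp), CAI, Nc, GC, third
    position composition, protein indices, AA_axis1..n / CR_axis1..n
    correspondence scores, one-hot ``role_*`` block, per-codon counts, any
    user-supplied external columns (e.g. an RNA minimal-free-energy column,
    which is never computed internally) and, when a collapsed transcriptome
    is given, one ``mRNA_log2_<condition>`` column per condition. Genes
    without a CDS are excluded with a warning.
    """
    from .data_io import GeneAnnotation  # noqa: F401  (type reference only)

    ann_by_id = {a.gene_id: a for a in annotations}
    usable = [a.gene_id for a in annotations if a.gene_id in cds]
    dropped = [a.gene_id for a in annotations if a.gene_id not in cds]
    if dropped:
        warnings.warn(
            f"{len(dropped)} annotated gene(s) lack a CDS and were excluded "
            f"(first: {dropped[:3]})",
            stacklevel=2,
        )
    if not usable:
        raise ValueError("no gene id shared between annotation and FASTA")

    profiles = {g: codon_counts(cds[g], gene_id=g) for g in usable}
    if weights is None:
        ref_ids = list(reference_gene_ids or [])
        ref_profiles = [profiles[g] for g in ref_ids if g in profiles]
        if not ref_profiles:
            raise ValueError(
                "reference_gene_ids (or explicit weights) required for CAI"
            )
        weights = build_reference_weights(ref_profiles)

    rows = {}
    for g in usable:
        p = profiles[g]
        protein = translate_cds(cds[g], gene_id=g)
        idx = protein_indices(protein)
        feats = {
            "gene_length_log2": math.log2(len(cds[g])),
            "CAI": cai(p, weights),
            "Nc": effective_number_of_codons(p),
            "GC": gc_content(cds[g]),
            **third_position_composition(p),
            "GRAVY": idx["GRAVY"],
            "AROMO": idx["AROMO"],
            "AliphaticIndex": idx["AliphaticIndex"],
            "InstabilityIndex": idx["InstabilityIndex"],
            "MolecularWeight": idx["MolecularWeight"],
            "ProteinLength": idx["length"],
        }
        rows[g] = feats
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene_id"

    # correspondence axes of amino-acid usage and of RSCU
    aa_usage = pd.DataFrame.from_dict(
        {g: _amino_acid_counts(profiles[g]) for g in usable}, orient="index"
    )
    aa_axes = correspondence_axes(aa_usage, n_axes)
    for i in range(n_axes):
        table[f"AA_axis{i + 1}"] = aa_axes.iloc[:, i]
    rscu_mat = pd.DataFrame.from_dict(
        {g: rscu(profiles[g]) for g in usable}, orient="index"
    ).fillna(0.0)
    cr_axes = correspondence_axes(rscu_mat, n_axes)
    for i in range(n_axes):
        table[f"CR_axis{i + 1}"] = cr_axes.iloc[:, i]

    roles = sorted(
        {ann_by_id[g].cellular_role for g in usable if ann_by_id[g].cellular_role}
    )
    for role in roles:
        table[f"role_{role}"] = [
            1.0 if ann_by_id[g].cellular_role == role else 0.0 for g in usable
        ]

    if include_codon_counts:
        for c in SENSE_CODONS:
            table[f"codon_{c}"] = [float(profiles[g].counts.get(c, 0)) for g in usable]

    if external_columns is not None:
        table = table.join(external_columns, how="left")

    if collapsed is not None:
        cf = collapsed.to_frame()
        for cond in collapsed.conditions:
            table[f"mRNA_log2_{cond}"] = cf[cond].reindex(table.index)

    return table
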