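"""Synthetic cognate transcriptome/proteome datasets with known truth.

The generator emulates the statistical structure the analysis assumes for
a sulfate-reducing bacterium profiled by microarray and shotgun LC-MS:

* a single-replicon genome laid out in operons (sizes 1..13, within-operon
  gaps 0..14 bp, between-operon gaps 50..500 bp) whose coding sequences
  carry a per-gene codon-bias gradient, so CAI and Nc vary by construction;
* log-normal transcript fluorescence with condition effects, a shared
  operon-level factor controlling within-operon coherence, replicate noise
  and a small completely-random missing fraction;
* latent log2 protein abundance linked to log2 mRNA through a smooth
  saturating ramp plus sequence-feature terms, observed as overdispersed
  negative-binomial peptide counts (detected proteins have >= 1 hit);
* a logistic missingness mechanism with known coefficients on the
  display-scaled features (negative on log2 mRNA, positive on instability
  index by default), with the intercept calibrated to a target missing
  fraction.

Every draw derives from one master seed through labelled substreams, so a
dataset regenerates bit-identically from (config, seed) and adding genes
does not reshuffle existing ones.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import substream
from .data_io import (
    CollapsedExpression,
    ExpressionMatrix,
    GeneAnnotation,
    collapse_replicates,
    write_annotation_tsv,
    write_cds_fasta,
    write_expression,
)
from .operons import OperonSet
from .seqfeatures import SENSE_CODONS, SYNONYMOUS_FAMILIES, assemble_features

__all__ = [
    "GeneratorConfig",
    "Genome",
    "SyntheticDataset",
    "generate_genome",
    "simulate_transcriptome",
    "simulate_proteome",
    "apply_missingness",
    "generate_dataset",
    "saturating_ramp",
]

#: one fixed "optimal" codon per amino acid (first of each family, sorted)
OPTIMAL_CODONS: dict[str, str] = {aa: fam[0] for aa, fam in SYNONYMOUS_FAMILIES.items()}

_ROLES = (
    "Energy metabolism",
    "Protein synthesis",
    "Transport and binding proteins",
    "Cell envelope",
    "Regulatory functions",
    "Unknown function",
)


@dataclasses.dataclass
class GeneratorConfig:
    """All tunable knobs of the generator, with dataset-1-like defaults
    (~3500 genes, 3 conditions, 4 replicates, ~30% of proteins detected)."""

    n_genes: int = 3500
    conditions: tuple[str, ...] = ("LL", "LS", "FL")
    n_replicates: int = 4
    # genome
    operon_geom_p: float = 0.45
    max_operon_size: int = 13
    within_operon_gap: tuple[int, int] = (0, 14)
    between_operon_gap: tuple[int, int] = (50, 500)
    codon_bias_beta: tuple[float, float] = (2.0, 2.0)
    median_length_codons: int = 300
    length_log_sd: float = 0.35
    n_reference_genes: int = 30
    # transcriptome (log2 fluorescence scale)
    transcript_mu: float = 9.5
    transcript_sigma_g: float = 1.6
    operon_rho: float = 0.8
    replicate_sigma: float = 0.4
    condition_sigma: float = 0.8
    bias_expression_weight: float = 2.0
    missing_rate_transcript: float = 0.02
    # proteome link
    protein_intercept: float = 2.5
    protein_slope: float = 0.6
    ramp_span: float = 6.0
    protein_sigma: float = 0.5
    nb_size: float | None = 4.0
    #: peptide hits scale with protein length (more observable peptides per
    #: protein), which molar normalization later cancels
    length_log2_coef: float = 1.0
    feature_coefs: tuple[tuple[str, float], ...] = (
        ("CAI", 1.0),
        ("InstabilityIndex", -0.01),
    )
    # missingness mechanism on display-scaled features
    beta_star: tuple[tuple[str, float], ...] = (
        ("mRNA_log2", -0.8),
        ("InstabilityIndex", 0.5),
    )
    target_missing_rate: float = 0.70

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "GeneratorConfig":
        doc = json.loads(text)
        for key in ("conditions", "within_operon_gap", "between_operon_gap",
                    "codon_bias_beta"):
            if key in doc:
                doc[key] = tuple(doc[key])
        for key in ("feature_coefs", "beta_star"):
            if key in doc:
                doc[key] = tuple((k, v) for k, v in doc[key])
        return cls(**doc)


@dataclasses.dataclass
class Genome:
    """A generated genome: annotation, CDS set, true operon structure."""

    annotations: list[GeneAnnotation]
    cds: dict[str, str]
    operons: OperonSet  # true co-transcribed groups of size >= 2
    group_of_gene: dict[str, int]  # every gene -> transcription-unit index
    codon_bias: pd.Series  # per-gene mixing weight b in [0, 1]
    reference_gene_ids: list[str]  # highest-bias genes (CAI reference panel)


def _truncated_geometric_sizes(
    total: int, p: float, max_size: int, rng: np.random.Generator
) -> list[int]:
    sizes: list[int] = []
    assigned = 0
    while assigned < total:
        if p >= 1.0:
            s = 1
            rng.random()  # keep the stream aligned across configs
        else:
            s = 1 + int(np.floor(np.log1p(-rng.random()) / np.log1p(-p)))
        s = min(s, max_size, total - assigned)
        sizes.append(s)
        assigned += s
    return sizes


def generate_genome(
    config: GeneratorConfig | None = None, seed: int = 0, **overrides
) -> Genome:
    """Generate annotation + coding sequences with known operon structure.

    Codons are drawn per gene from a mixture of the uniform distribution
    over the 61 sense codons and a point mass on one fixed optimal codon
    per amino acid, with per-gene mixing weight b ~ Beta; b = 1 forces
    maximal bias (Nc near 20, CAI near 1 against a high-b reference) and
    b = 0 uniform usage (Nc near 61).
    """
    cfg = dataclasses.replace(config or GeneratorConfig(), **overrides)
    if cfg.n_genes < 10:
        raise ValueError("n_genes must be >= 10")
    if cfg.within_operon_gap[0] < 0 or cfg.between_operon_gap[0] < 0:
        raise ValueError("gaps must be nonnegative")
    rng_layout = substream(seed, "genome-layout")
    sizes = _truncated_geometric_sizes(
        cfg.n_genes, cfg.operon_geom_p, cfg.max_operon_size, rng_layout
    )
    n = cfg.n_genes
    ids = [f"SYN{i:04d}" for i in range(n)]
    # codon bias is a property of the transcription unit: co-expressed genes
    # share codon adaptation (ribosomal operons are the canonical example)
    group_bias = substream(seed, "codon-bias").beta(
        *cfg.codon_bias_beta, size=len(sizes)
    )
    bias = np.repeat(group_bias, sizes)
    lengths = np.maximum(
        np.rint(
            cfg.median_length_codons
            * np.exp(substream(seed, "gene-length").normal(0.0, cfg.length_log_sd, n))
        ).astype(int),
        30,
    )

    sense = np.array(SENSE_CODONS)
    optimal_of_sense = np.array(
        [OPTIMAL_CODONS[SYNONYMOUS_FAMILIES_AA[c]] for c in SENSE_CODONS]
    )
    annotations: list[GeneAnnotation] = []
    cds: dict[str, str] = {}
    group_of_gene: dict[str, int] = {}
    operon_groups: list[list[str]] = []
    pos = 1
    gene_idx = 0
    for group_id, size in enumerate(sizes):
        strand = "+" if rng_layout.random() < 0.5 else "-"
        role = _ROLES[int(rng_layout.integers(len(_ROLES)))]
        members: list[str] = []
        for k in range(size):
            g = ids[gene_idx]
            rng_seq = substream(seed, "cds", g)
            L = int(lengths[gene_idx])
            b = float(bias[gene_idx])
            base = sense[rng_seq.integers(0, sense.size, size=L)]
            use_opt = rng_seq.random(L) < b
            codons = np.where(use_opt, optimal_of_sense[
                np.searchsorted(sense, base)
            ], base)
            seq = "".join(codons.tolist()) + "TAA"
            nt_len = len(seq)
            if k > 0:
                gap = int(rng_layout.integers(cfg.within_operon_gap[0],
                                              cfg.within_operon_gap[1] + 1))
            elif gene_idx > 0:
                gap = int(rng_layout.integers(cfg.between_operon_gap[0],
                                              cfg.between_operon_gap[1] + 1))
            else:
                gap = 0
            start = pos + gap
            end = start + nt_len - 1
            pos = end + 1
            annotations.append(
                GeneAnnotation(
                    gene_id=g,
                    replicon_id="chr",
                    start=start,
                    end=end,
                    strand=strand,
                    cellular_role=role,
                    product=f"synthetic protein {g}",
                )
            )
            cds[g] = seq
            group_of_gene[g] = group_id
            members.append(g)
            gene_idx += 1
        if size >= 2:
            operon_groups.append(members)
    order = np.argsort(-bias)
    reference = [ids[i] for i in order[: cfg.n_reference_genes]]
    return Genome(
        annotations=annotations,
        cds=cds,
        operons=OperonSet(operon_groups),
        group_of_gene=group_of_gene,
        codon_bias=pd.Series(bias, index=ids, name="codon_bias"),
        reference_gene_ids=reference,
    )


#: codon -> amino acid lookup used when vectorizing CDS generation
SYNONYMOUS_FAMILIES_AA = {
    c: aa for aa, fam in SYNONYMOUS_FAMILIES.items() for c in fam
}


def simulate_transcriptome(
    genome: Genome, config: GeneratorConfig | None = None, seed: int = 0, **overrides
) -> ExpressionMatrix:
    """Replicate-structured transcript fluorescence intensities.

    log2 intensity = gene effect + rho * operon factor + condition effect
    + replicate noise; the gene effect is coupled to codon bias so highly
    biased genes are more expressed (the codon-adaptation/expression link).
    """
    cfg = dataclasses.replace(config or GeneratorConfig(), **overrides)
    if not 0.0 <= cfg.operon_rho <= 1.0:
        raise ValueError("operon_rho must be in [0, 1]")
    ids = [a.gene_id for a in genome.annotations]
    n = len(ids)
    rho = cfg.operon_rho
    z_gene = substream(seed, "transcript-gene").normal(0.0, 1.0, n)
    n_groups = max(genome.group_of_gene.values()) + 1
    z_group = substream(seed, "transcript-operon").normal(0.0, 1.0, n_groups)
    group_idx = np.array([genome.group_of_gene[g] for g in ids])
    core = np.sqrt(1.0 - rho**2) * z_gene + rho * z_group[group_idx]
    base = (
        cfg.transcript_mu
        + cfg.transcript_sigma_g * core
        + cfg.bias_expression_weight * (genome.codon_bias[ids].to_numpy() - 0.5)
    )
    samples = [
        (cond, rep + 1)
        for cond in cfg.conditions
        for rep in range(cfg.n_replicates)
    ]
    values = np.empty((n, len(samples)))
    for jc, cond in enumerate(cfg.conditions):
        # condition response is coherent within a transcription unit to the
        # same degree rho as the baseline (co-regulation of operon genes)
        z_cg = substream(seed, "condition-effect", cond).normal(0.0, 1.0, n)
        z_co = substream(seed, "condition-effect-operon", cond).normal(
            0.0, 1.0, n_groups
        )
        cond_eff = cfg.condition_sigma * (
            np.sqrt(1.0 - rho**2) * z_cg + rho * z_co[group_idx]
        )
        for rep in range(cfg.n_replicates):
            noise = substream(seed, "replicate-noise", cond, rep).normal(
                0.0, cfg.replicate_sigma, n
            )
            values[:, jc * cfg.n_replicates + rep] = np.exp2(base + cond_eff + noise)
    if cfg.missing_rate_transcript > 0:
        mask = substream(seed, "transcript-missing").random(values.shape)
        values[mask < cfg.missing_rate_transcript] = np.nan
    return ExpressionMatrix(ids, samples, values, kind="transcript_fluorescence")


def saturating_ramp(t: np.ndarray, anchor: float, span: float) -> np.ndarray:
    """Smooth saturating link: identity slope near ``anchor``, flattening
    to ``anchor + span`` — the plateau seen at high mRNA abundance."""
    t = np.asarray(t, dtype=float)
    if span <= 0:
        return t.copy()
    return anchor + span * np.tanh((t - anchor) / span)


def simulate_proteome(
    collapsed: CollapsedExpression,
    features: pd.DataFrame | None = None,
    config: GeneratorConfig | None = None,
    seed: int = 0,
    **overrides,
) -> tuple[pd.DataFrame, ExpressionMatrix, pd.DataFrame]:
    """Latent log2 protein abundance and observed peptide counts.

    latent = intercept + slope * s(log2 mRNA) + sum_j c_j * feature_j
    + N(0, sigma_p^2), with s the saturating ramp anchored at the 10th
    percentile of the pooled mRNA values. Counts are negative binomial
    with mean 2^latent (or exactly 2^latent when ``nb_size`` is None),
    floored at 1 hit. Returns (latent log2, peptide-count matrix before
    missingness, noise-free signal component).
    """
    cfg = dataclasses.replace(config or GeneratorConfig(), **overrides)
    ids = list(collapsed.gene_ids)
    t = collapsed.to_frame()
    anchor = float(np.nanquantile(t.to_numpy(), 0.10))
    feat_term = np.zeros(len(ids))
    if cfg.length_log2_coef and features is not None and "gene_length_log2" in features:
        col = features["gene_length_log2"].reindex(ids)
        feat_term = feat_term + cfg.length_log2_coef * (
            col - col.mean()
        ).fillna(0.0).to_numpy()
    for name, coef in cfg.feature_coefs:
        if features is None or name not in features.columns:
            if coef != 0.0:
                raise ValueError(f"feature {name!r} needed by the link is missing")
            continue
        col = features[name].reindex(ids)
        feat_term = feat_term + coef * (col - col.mean()).fillna(0.0).to_numpy()
    latent = {}
    signal = {}
    for cond in collapsed.conditions:
        s = saturating_ramp(t[cond].to_numpy(), anchor, cfg.ramp_span)
        mu = cfg.protein_intercept + cfg.protein_slope * (s - anchor) + feat_term
        noise = substream(seed, "protein-noise", cond).normal(
            0.0, cfg.protein_sigma, len(ids)
        )
        signal[cond] = mu
        latent[cond] = mu + noise
    latent_df = pd.DataFrame(latent, index=ids)
    signal_df = pd.DataFrame(signal, index=ids)
    counts = np.empty(latent_df.shape)
    for j, cond in enumerate(collapsed.conditions):
        mean = np.exp2(latent_df[cond].to_numpy())
        mean = np.where(np.isfinite(mean), mean, np.nan)
        if cfg.nb_size is None:
            c = mean
        else:
            rng = substream(seed, "peptide-counts", cond)
            r = cfg.nb_size
            with np.errstate(invalid="ignore"):
                p = r / (r + np.nan_to_num(mean, nan=1.0))
            c = rng.negative_binomial(r, p).astype(float)
            c[np.isnan(mean)] = np.nan
        counts[:, j] = np.where(np.isnan(c), np.nan, np.maximum(c, 1.0))
    count_matrix = ExpressionMatrix(
        ids,
        [(cond, 1) for cond in collapsed.conditions],
        counts,
        kind="peptide_counts",
    )
    return latent_df, count_matrix, signal_df


def _calibrate_intercept(eta_no_intercept: np.ndarray, target: float) -> float:
    lo, hi = -50.0, 50.0
    from scipy.stats import logistic as _logistic

    for _ in range(200):
        mid = (lo + hi) / 2.0
        if _logistic.cdf(eta_no_intercept + mid).mean() < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def apply_missingness(
    counts: ExpressionMatrix,
    standardized_features: pd.DataFrame,
    beta_star: Mapping[str, float],
    intercept: float | None = None,
    target_missing_rate: float = 0.70,
    mrna_log2: pd.DataFrame | None = None,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    """Mask peptide counts by the logistic mechanism with known
    coefficients.

    ``standardized_features`` must already be on the display scale used by
    the missingness model (instability/10, CAI*10, ...); a per-condition
    ``mRNA_log2`` coefficient draws its column from ``mrna_log2``. When
    ``intercept`` is None it is calibrated per condition by bisection so
    the expected missing fraction equals ``target_missing_rate``. Returns
    (observed matrix with NaN for masked cells, boolean mask frame,
    per-cell missingness probabilities).
    """
    ids = list(counts.gene_ids)
    conditions = [c for c, _ in counts.samples]
    values = counts.values.copy()
    probs = np.zeros_like(values)
    masked = np.zeros(values.shape, dtype=bool)
    from scipy.stats import logistic as _logistic

    for j, cond in enumerate(conditions):
        eta = np.zeros(len(ids))
        for name, coef in beta_star.items():
            if name == "mRNA_log2":
                if mrna_log2 is None:
                    raise ValueError("mRNA_log2 coefficient needs mrna_log2 frame")
                col = mrna_log2[cond].reindex(ids)
            else:
                if name not in standardized_features.columns:
                    raise ValueError(f"feature {name!r} absent from features")
                col = standardized_features[name].reindex(ids)
            eta = eta + coef * col.fillna(col.mean()).to_numpy()
        b0 = intercept if intercept is not None else _calibrate_intercept(
            eta, target_missing_rate
        )
        p = _logistic.cdf(eta + b0)
        draw = substream(seed, "protein-missing", cond).random(len(ids))
        mask = draw < p
        values[mask, j] = np.nan
        probs[:, j] = p
        masked[:, j] = mask
    observed = ExpressionMatrix(ids, list(counts.samples), values, counts.kind)
    mask_df = pd.DataFrame(masked, index=ids, columns=conditions)
    prob_df = pd.DataFrame(probs, index=ids, columns=conditions)
    return observed, mask_df, prob_df


@dataclasses.dataclass
class SyntheticDataset:
    """A full generated dataset plus its ground truth."""

    config: GeneratorConfig
    seed: int
    genome: Genome
    transcripts: ExpressionMatrix
    collapsed_transcripts: CollapsedExpression
    features: pd.DataFrame
    latent_protein_log2: pd.DataFrame
    peptide_counts: ExpressionMatrix  # before missingness
    observed_proteome: ExpressionMatrix  # after missingness (NaN = undetected)
    missing_mask: pd.DataFrame
    missing_probability: pd.DataFrame
    signal_log2: pd.DataFrame  # noise-free component of the latent protein

    def write(self, outdir: str | Path) -> None:
        """Emit the exact input formats the pipeline consumes, plus truth."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_annotation_tsv(self.genome.annotations, outdir / "annotation.tsv")
        write_cds_fasta(self.genome.cds, outdir / "cds.fasta")
        write_expression(self.transcripts, outdir / "transcripts.tsv")
        write_expression(self.observed_proteome, outdir / "proteome.tsv")
        self.genome.operons.write_tsv(outdir / "true_operons.tsv")
        truth = {
            "config": dataclasses.asdict(self.config),
            "seed": self.seed,
            "reference_gene_ids": self.genome.reference_gene_ids,
            "beta_star": dict(self.config.beta_star),
            "n_operons": len(self.genome.operons),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        self.latent_protein_log2.rename_axis("gene_id").to_csv(
            outdir / "latent_protein_log2.tsv", sep="\t"
        )


def generate_dataset(
    config: GeneratorConfig | None = None, seed: int = 0, **overrides
) -> SyntheticDataset:
    """Run the whole generator: genome -> transcripts -> proteome -> mask."""
    cfg = dataclasses.replace(config or GeneratorConfig(), **overrides)
    genome = generate_genome(cfg, seed)
    transcripts = simulate_transcriptome(genome, cfg, seed)
    collapsed = collapse_replicates(transcripts, min_present=min(3, cfg.n_replicates))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = assemble_features(
            genome.annotations,
            genome.cds,
            collapsed=collapsed,
            reference_gene_ids=genome.reference_gene_ids,
        )
    latent, counts, signal = simulate_proteome(collapsed, features, cfg, seed)
    from .missingness import standardize

    std = standardize(
        features.drop(columns=[c for c in features.columns if c.startswith("mRNA_")]),
        pd.Series(0, index=features.index),
    )
    mrna = collapsed.to_frame()
    observed, mask, prob = apply_missingness(
        counts,
        std.X,
        dict(cfg.beta_star),
        target_missing_rate=cfg.target_missing_rate,
        mrna_log2=mrna,
        seed=seed,
    )
    return SyntheticDataset(
        config=cfg,
        seed=seed,
        genome=genome,
        transcripts=transcripts,
        collapsed_transcripts=collapsed,
        features=features,
        latent_protein_log2=latent,
        peptide_counts=counts,
        observed_proteome=observed,
        missing_mask=mask,
        missing_probability=prob,
        signal_log2=signal,
    )
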