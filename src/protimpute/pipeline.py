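"""End-to-end orchestration: features -> operons -> per-condition MLP ->
imputation -> operon validation -> missingness model -> differential report.

Every stage writes its artifact under the run's output directory together
with the resolved configuration and seed, and reruns with the same config
and seed are numerically identical.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._seeds import subseed
from .data_io import (
    collapse_replicates,
    quantile_normalize,
    read_annotation_gff3,
    read_annotation_tsv,
    read_cds_fasta,
    read_expression,
)
from .imputer import HIDDEN_SIZE_RANGE, impute, select_hidden_size, train
from .missingness import odds_ratio_table, standardize, stepwise_select
from .operon_validation import validate
from .operons import detect_operons
from .seqfeatures import assemble_features

__all__ = [
    "RunConfig",
    "StageError",
    "DEFAULT_PREDICTORS",
    "fit_condition_model",
    "differential_report",
    "load_energy_metabolism_example",
    "run_all",
]

#: default MLP predictor panel (mRNA_log2 resolves per condition)
DEFAULT_PREDICTORS = (
    "mRNA_log2",
    "gene_length_log2",
    "CAI",
    "Nc",
    "GC",
    "GRAVY",
    "InstabilityIndex",
    "AliphaticIndex",
    "AA_axis1",
    "CR_axis1",
)


class StageError(RuntimeError):
    """A pipeline stage failed; partial artifacts are retained."""


@dataclasses.dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    annotation: str
    cds_fasta: str
    transcripts: str
    proteome: str
    outdir: str
    reference_genes: list[str] = dataclasses.field(default_factory=list)
    predictors: list[str] = dataclasses.field(
        default_factory=lambda: list(DEFAULT_PREDICTORS)
    )
    conditions: list[str] | None = None
    k_folds: int = 10
    hidden_sizes: list[int] = dataclasses.field(
        default_factory=lambda: list(HIDDEN_SIZE_RANGE)
    )
    n_permutations: int = 2000
    alpha: float = 0.05
    seed: int = 0
    min_present_transcript: int = 3
    min_present_protein: int = 1
    max_gap_bp: int = 15
    quantile_normalize: bool = True
    condition_pair: list[str] | None = None
    category_filter: str | None = None
    mlp_hyper: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    def validate_paths(self) -> None:
        for key in ("annotation", "cds_fasta", "transcripts", "proteome"):
            p = getattr(self, key)
            if not p or not Path(p).exists():
                raise StageError(f"config: input path {key!r} missing or absent: {p}")


def _read_annotation(path: str | Path):
    text = Path(path).read_text().lstrip()
    if text.startswith("##gff") or "\tgene\t" in text.partition("\n")[0]:
        return read_annotation_gff3(path)
    return read_annotation_tsv(path)


def fit_condition_model(
    features: pd.DataFrame,
    protein_log2: pd.Series,
    condition: str,
    predictors: Sequence[str] = DEFAULT_PREDICTORS,
    sizes: Sequence[int] = HIDDEN_SIZE_RANGE,
    K: int = 10,
    seed: int = 0,
    **hyper,
):
    """Select the hidden size by K-fold CV and refit on all training genes.

    Training genes are those with a measured protein in the condition and
    a complete predictor row; ``mRNA_log2`` resolves to the condition's
    ``mRNA_log2_<condition>`` column.
    """
    X = _predictor_frame(features, condition, predictors)
    y = protein_log2.reindex(X.index)
    keep = y.notna() & ~X.isna().any(axis=1)
    Xt, yt = X.loc[keep], y.loc[keep]
    if len(Xt) < 2 * K:
        raise ValueError(
            f"{condition}: only {len(Xt)} training genes for {K}-fold CV"
        )
    best, cv = select_hidden_size(
        Xt.to_numpy(), yt.to_numpy(), sizes=sizes, K=K,
        seed=subseed(seed, "model", condition),
        predictor_names=list(predictors), **hyper,
    )
    model = train(
        Xt.to_numpy(), yt.to_numpy(), best,
        subseed(seed, "model-final", condition),
        predictor_names=list(predictors), **hyper,
    )
    model.cv_r_squared = 1.0 - cv.mean_errors[best] / np.var(
        2.0 * (yt - model.target_min) / (model.target_max - model.target_min) - 1.0
    )
    return model, cv


def _predictor_frame(
    features: pd.DataFrame, condition: str, predictors: Sequence[str]
) -> pd.DataFrame:
    cols = {}
    for p in predictors:
        if p == "mRNA_log2":
            col = f"mRNA_log2_{condition}"
            if col not in features.columns:
                raise ValueError(f"features lack column {col}")
            cols[p] = features[col]
        else:
            if p not in features.columns:
                raise ValueError(f"features lack predictor {p}")
            cols[p] = features[p]
    return pd.DataFrame(cols, index=features.index)


def differential_report(
    predictions: Mapping[str, pd.DataFrame],
    rna: Mapping[str, pd.Series],
    measured_protein: Mapping[str, pd.Series],
    descriptions: pd.Series,
    condition_pair: tuple[str, str],
    category_filter: str | None = None,
) -> pd.DataFrame:
    """Per-gene cross-condition report on imputed data.

    For each condition: predicted linear abundance, measured RNA, and the
    measured protein rendered ``"x"`` when undetected. The fold change is
    second condition over first on predicted linear abundance;
    ``detected_count`` counts conditions with a measured protein. Rows may
    be restricted to genes whose description contains ``category_filter``.
    """
    conditions = list(predictions)
    for cond in condition_pair:
        if cond not in conditions:
            raise ValueError(f"unknown condition {cond!r}; have {conditions}")
    genes = sorted(
        set().union(*(predictions[c].index for c in conditions))
    )
    out = pd.DataFrame(index=pd.Index(genes, name="gene_id"))
    out["description"] = descriptions.reindex(genes).fillna("")
    detected = pd.Series(0, index=out.index)
    for cond in conditions:
        pred = predictions[cond]["linear_abundance"].reindex(genes)
        out[f"predicted_{cond}"] = pred.round(2)
        out[f"rna_{cond}"] = rna[cond].reindex(genes)
        meas = measured_protein[cond].reindex(genes)
        out[f"protein_{cond}"] = [
            "x" if pd.isna(v) else v for v in meas
        ]
        detected += meas.notna().astype(int)
    out["detected_count"] = detected
    c1, c2 = condition_pair
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = (
            predictions[c2]["linear_abundance"].reindex(genes)
            / predictions[c1]["linear_abundance"].reindex(genes)
        )
    out["fold_change"] = fc
    out["log2_fold_change"] = np.log2(fc)
    if category_filter is not None:
        out = out[out["description"].str.contains(category_filter, regex=False)]
    return out


def load_energy_metabolism_example() -> dict:
    """The bundled *D. vulgaris* energy-metabolism example table.

    Predicted protein abundance (peptide-count scale), measured RNA
    fluorescence and measured protein hits for 50 energy-metabolism genes
    under three growth conditions (LL: lactate/exponential, LS:
    lactate/stationary, FL: formate/exponential); ``x`` marks proteins
    undetected experimentally. Returns the mappings consumed by
    :func:`differential_report`.
    """
    src = importlib.resources.files("protimpute") / "data/energy_metabolism_dataset1.tsv"
    with importlib.resources.as_file(src) as path:
        df = pd.read_csv(path, sep="\t", index_col="gene_id",
                         na_values=["NA"], keep_default_na=False)
    conditions = ["LL", "LS", "FL"]
    predictions, rna, protein = {}, {}, {}
    for cond in conditions:
        predictions[cond] = pd.DataFrame(
            {"linear_abundance": pd.to_numeric(df[f"predicted_{cond}"], errors="coerce")}
        )
        rna[cond] = pd.to_numeric(df[f"rna_{cond}"], errors="coerce")
        protein[cond] = pd.to_numeric(
            df[f"protein_{cond}"].replace("x", np.nan), errors="coerce"
        )
    return {
        "predictions": predictions,
        "rna": rna,
        "measured_protein": protein,
        "descriptions": df["description"],
        "conditions": conditions,
    }


def run_all(config: RunConfig) -> Path:
    """Run every stage, writing artifacts under ``config.outdir``."""
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrap

    annotations = stage("annotation")(_read_annotation, config.annotation)
    cds = stage("sequences")(read_cds_fasta, config.cds_fasta)
    transcripts = stage("transcripts")(
        read_expression, config.transcripts, "transcript_fluorescence"
    )
    proteome = stage("proteome")(read_expression, config.proteome, "peptide_counts")

    if config.quantile_normalize:
        transcripts = stage("normalize")(quantile_normalize, transcripts)
    collapsed_t = stage("collapse-transcripts")(
        collapse_replicates, transcripts, config.min_present_transcript
    )
    collapsed_p = stage("collapse-proteome")(
        collapse_replicates, proteome, config.min_present_protein
    )
    conditions = config.conditions or collapsed_p.conditions
    collapsed_t.to_frame().rename_axis("gene_id").to_csv(
        outdir / "collapsed_transcripts_log2.tsv", sep="\t", na_rep="NA"
    )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        features = stage("features")(
            assemble_features,
            annotations,
            cds,
            collapsed=collapsed_t,
            reference_gene_ids=config.reference_genes or None,
        )
    features.to_csv(outdir / "features.tsv", sep="\t", na_rep="NA")

    operon_set = stage("operons")(detect_operons, annotations, config.max_gap_bp)
    operon_set.write_tsv(outdir / "operons.tsv")

    (outdir / "models").mkdir(exist_ok=True)
    predictions: dict[str, pd.DataFrame] = {}
    validation_summaries = {}
    missingness_blocks = []
    descriptions = pd.Series(
        {a.gene_id: a.product for a in annotations}, name="description"
    )
    for cond in conditions:
        protein_log2 = collapsed_p.series(cond)
        model, cv = stage(f"model-{cond}")(
            fit_condition_model,
            features, protein_log2, cond,
            predictors=config.predictors, sizes=config.hidden_sizes,
            K=config.k_folds, seed=config.seed, **config.mlp_hyper,
        )
        model.to_json(outdir / "models" / f"{cond}.json")
        X = _predictor_frame(features, cond, config.predictors)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred = impute(model, X, measured_log2=protein_log2)
        pred.to_csv(outdir / f"predictions_{cond}.tsv", sep="\t")
        predictions[cond] = pred

        # validation uses pure model predictions for every gene (measured
        # included), matching the per-gene predicted-abundance convention
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pred_all = impute(model, X, measured_log2=None)
        report = stage(f"validate-{cond}")(
            validate,
            pred_all["linear_abundance"],
            features["MolecularWeight"],
            operon_set,
            config.n_permutations,
            subseed(config.seed, "validate", cond),
        )
        report.write(outdir / f"validation_{cond}.tsv")
        validation_summaries[cond] = report.summary()

        outcome = protein_log2.reindex(features.index).isna().astype(int)
        feat_cols = features.drop(
            columns=[c for c in features.columns if c.startswith("mRNA_log2_")]
        )
        feat_cols = feat_cols.assign(
            mRNA_log2=features[f"mRNA_log2_{cond}"]
        ).dropna(subset=["mRNA_log2"])
        std = stage(f"missingness-{cond}")(
            standardize, feat_cols, outcome
        )
        from .missingness import DEFAULT_CANDIDATES

        # one-hot role block as a single candidate, dropping one level as
        # the reference so the block is estimable next to the intercept
        role_cols = sorted(c for c in std.X.columns if c.startswith("role_"))[1:]
        candidates: list = [c for c in DEFAULT_CANDIDATES if c in std.X.columns]
        if role_cols:
            candidates.append(("cellular_role", role_cols))
        miss_model = stage(f"missingness-{cond}")(
            stepwise_select, std, candidates=candidates,
            alpha_enter=config.alpha, alpha_stay=config.alpha,
        )
        miss_model.to_json(outdir / f"missingness_{cond}.json")
        block = odds_ratio_table(miss_model)
        block.insert(0, "condition", cond)
        missingness_blocks.append(block)

    (outdir / "validation_summary.json").write_text(
        json.dumps(validation_summaries, indent=1)
    )
    pd.concat(missingness_blocks).to_csv(
        outdir / "missingness_odds_ratios.tsv", sep="\t"
    )

    pair = tuple(config.condition_pair or conditions[:2])
    rna_linear = {c: np.exp2(collapsed_t.series(c)) for c in conditions}
    protein_linear = {c: np.exp2(collapsed_p.series(c)) for c in conditions}
    report_df = stage("report")(
        differential_report,
        predictions, rna_linear, protein_linear, descriptions,
        pair, config.category_filter,
    )
    report_df.to_csv(outdir / "differential_report.tsv", sep="\t", na_rep="NA")

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "conditions": list(conditions),
        "n_genes_features": int(len(features)),
        "n_operons": len(operon_set),
        "validation": validation_summaries,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
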