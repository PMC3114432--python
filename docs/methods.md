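# Methods

This note documents the models, conventions, numerical choices and known
limitations of `protimpute`, in the order the pipeline runs them.

## Preprocessing (`data_io`)

Transcript abundance is absolute fluorescence intensity; protein
abundance is the peptide-hit count. A detected protein has ≥1 hit, so
zeros and `NA` cells are both treated as *undetected* (missing), never as
measured zeros.

**Quantile normalization.** The reference distribution is the mean of the
per-column sorted values; with missing data, each column's sorted values
are linearly interpolated to a common grid whose length is the largest
non-missing column count, ranks are computed among non-missing entries
only, and missing cells stay missing. Ties receive the mean reference
value over their tied rank span (the rank-average dialect), which makes
the transform deterministic, symmetric and idempotent on complete data.
Nothing is imputed before normalizing.

**Replicate collapse.** Per gene and condition, the collapsed value is
the mean of log2 over non-missing replicates, kept only when at least
`min_present` replicates are measured (default 3, capped at the
condition's replicate count, so single-replicate designs default to 1).
Log base 2 is used everywhere; no pseudocount is added because detected
peptide counts are ≥1.

## Sequence features (`seqfeatures`)

All codon statistics use the bacterial code (table 11). Stops are
excluded from every statistic; Met and Trp are excluded from CAI, Nc
families, reference weights and synonymous third-position composition.
The three six-fold families (Leu, Ser, Arg) are treated whole, not split
2+4. Codons containing ambiguous bases are dropped with a warning when
they are ≤1% of a gene, otherwise the gene is rejected.

- **RSCU**: count over the mean count of the synonymous family;
  unobserved families give NaN (set to 0 when building CA input).
- **CAI**: count-weighted geometric mean of relative adaptiveness w over
  synonymously variable codons. Weights come from pooled reference-gene
  counts (highly expressed genes, conventionally ribosomal proteins);
  zero-count reference codons get a 0.5 pseudo-count before
  normalization and all weights are floored at 1e-3 so log w is finite.
- **Nc**: Wright's statistic. Family homozygosity
  F = (nΣp² − 1)/(n − 1) needs n ≥ 2; class means F̄_k are weighted by
  family counts; Nc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, clamped to
  [20, 61]. A missing three-fold class (Ile unobserved) is imputed as
  (F̄₂+F̄₄)/2; any other missing class (or a zero class mean) leaves Nc
  undefined for that gene.
- **Protein indices** follow the ExPASy ProtParam definitions, with the
  Kyte–Doolittle hydropathy and Guruprasad DIWV dipeptide tables taken
  from biopython's published-data module and molecular weight from
  `Bio.SeqUtils`. The aliphatic index is
  X_Ala + 2.9·X_Val + 3.9·(X_Ile + X_Leu) in mole percent.
- **Correspondence analysis** is the symmetric variant: SVD of the
  standardized residuals of the row/column-normalized table, both rows
  and columns in principal coordinates, axes ordered by inertia (total
  inertia equals χ²/n). CA is sign-indeterminate, so each axis is
  oriented to make the largest-|loading| column positive — a fixed rule
  that makes runs reproducible. AA axes are computed on amino-acid
  counts, CR axes on RSCU with undefined entries set to 0 and zero-margin
  codons dropped.
- **N_MFE** (RNA minimal free energy) is never computed internally; it is
  accepted only as an externally supplied per-gene column.
- Cellular role enters models as a one-hot block counted as one logical
  predictor, since no encoding convention exists for it as a single
  covariate.

## Operon prediction (`operons`)

Operons are maximal same-replicon, same-strand runs with intergenic gaps
(next.start − prev.end − 1) strictly below 15 bp; overlapping same-strand
genes count as gap ≤ 0 and merge; runs of length 1 are not operons. The
"<15" threshold is read strictly and is configurable. Genes are not
merged across a circular replicon origin.

## Imputation model (`imputer`)

One hidden layer of `tanh(v/2)` units and a linear output neuron. Inputs
and target are affinely mapped to [−1, 1] over their *training* ranges
(prediction-time inputs extend linearly beyond the box, no clipping; a
constant training column is an error). The loss is MSE on the scaled
target.

**Optimizer.** Full-batch gradient descent with momentum 0.9 and a
multiplicative adaptive learning rate (accept a step and grow the rate by
1.05 unless the loss rises by more than 4%, in which case the step is
rejected, the rate shrinks by 0.7 and momentum resets). Initialization is
uniform [−0.5, 0.5] from seeded substreams; max 2000 epochs with early
stop when the best loss fails to improve by 1e-7 for 25 epochs; 3
restarts keep the best final loss. Everything derives from one master
seed, so training is bit-reproducible.

**Hidden-size selection.** 10-fold CV over sizes 5..12; folds come from a
single seeded permutation, each fold's scalers are fit on its training
part only, the validation metric is scaled-target MSE, and ties go to the
smallest size. Fold models use a single initialization for speed; the
final refit uses the full restart schedule. Both the training R² (after
the final refit) and a CV-based R² are reported, clearly labelled, since
either convention is defensible.

**Training set.** Genes with a measured protein in the condition (after
the replicate-presence rule) and a complete predictor row. The default
predictor panel is per-condition log2 mRNA, log2 gene length, CAI, Nc,
GC, GRAVY, instability index, aliphatic index, AA_axis1 and CR_axis1 —
ten predictors mixing expression, codon-usage and protein properties;
the panel is configuration-driven.

## Operon validation (`operon_validation`)

Predictions (pure model outputs for *all* genes, measured included — the
convention the per-gene prediction tables use) are divided by molecular
weight ("molar abundance") before CV calculation; CV uses the sample SD
(n−1). Each operon's null resamples size-matched gene sets without
replacement from the full prediction pool, 2000 draws by default,
vectorized via random-key partial sorting. Percentiles use ≤ (ties count
against the operon — conservative). Per-operon substreams are indexed by
operon id, so adding an operon never perturbs the others' nulls and the
whole report is bit-reproducible.

## Missingness model (`missingness`)

Outcome 1 = protein undetected in the condition after replicate collapse;
one model per condition. Covariates use the display scaling (mRNA and
gene length log2; instability, aliphatic index, Nc ÷10; CAI, N_MFE,
GRAVY, AA/CR axes ×10), which leaves the fit invariant but makes odds
ratios readable. Fitting is Newton maximum likelihood with SEs from the
inverse observed information (statsmodels behind the module surface);
complete separation or a singular information matrix is an explicit
error, never a silent ridge. Stepwise selection uses likelihood-ratio
tests for both entry and removal at 0.05 (the classic score/Wald mixture
of legacy stepwise implementations is path-dependent and tool-specific;
LR is well defined and asymptotically equivalent), preceded by a
correlation pre-filter that drops the later of any pair with |r| > 0.95.
Candidates are complete-cased on the full panel so nested LR tests always
compare identical rows. The intercept is always included and never a
candidate. A one-hot cellular-role block enters selection as a single
jointly tested candidate with one level dropped as the reference (it
would otherwise be collinear with the intercept). Wald limits use
z = 1.959964.

## Synthetic data (`synthetic_data`)

The generator defines the study conditions; defaults emulate a
dataset-1-like campaign: 3500 genes, 3 conditions, 4 replicates, ~30% of
proteins detected. Key structure:

- **Genome**: transcription-unit sizes from a truncated geometric on
  1..13; within-operon gaps uniform 0..14 bp, between-operon gaps 50..500
  bp; gene lengths log-normal (median 300 codons, log-SD 0.35). Codons
  are drawn from a mixture of the uniform distribution over the 61 sense
  codons and a point mass on one fixed optimal codon per amino acid with
  mixing weight b ~ Beta(2, 2) — drawn per transcription unit, because
  co-expressed genes share codon adaptation. b = 1 forces Nc → 20 and
  CAI → 1 against a high-b reference; b = 0 gives Nc → 61.
- **Transcripts** (log2 fluorescence): mean 9.5; gene effect SD 1.6 with
  within-unit coherence ρ (default 0.8) applied to both the baseline and
  the per-condition response (co-regulation); +2·(b − 0.5) couples codon
  bias to expression; replicate noise SD 0.4; condition effect SD 0.8;
  2% of cells missing completely at random.
- **Proteome link**: latent log2 protein = 2.5 + 0.6·s(log2 mRNA) +
  1·(log2 gene length, centred) + 1·CAI − 0.01·instability + N(0, 0.5²),
  where s is a smooth ramp `anchor + span·tanh((t−anchor)/span)` anchored
  at the 10th percentile with span 6 log2 units — linear through the bulk
  of the range and flattening only at high mRNA, the plateau seen in
  partial-dependence plots. The length term reflects that longer proteins
  yield more observable peptides; molar normalization cancels it later.
  Observed counts are negative binomial (size 4) with mean 2^latent,
  floored at 1 hit.
- **Missingness**: each protein is masked with probability from the
  logistic mechanism with β* = (−0.8 on log2 mRNA, +0.5 on
  instability/10) and the intercept calibrated by bisection to a 70%
  missing fraction (so ~30% detected).

All draws come from substreams keyed by (component, entity id), so
regeneration from (config, seed) is bit-identical and adding genes does
not reshuffle existing ones.

**What the generator does not emulate**: peptide-level detectability
(digestion, flyability), microarray probe effects, cross-hybridization,
condition-specific proteolysis, or operon-internal promoters. Passing
tests therefore demonstrate that the machinery is correct and calibrated
under the stated statistical structure, not that the biological link in
any particular real dataset has this form.

## Problem sizes used in tests and the acceptance script

Shared fixtures use 200–2000 genes with median gene length 120 codons;
the 2000-gene runs give per-condition training sets of ~600 detected
proteins, close to the larger of the two emulated campaigns, and the
900-gene runs give ~270, close to the smaller. Hidden-size selection in
tests sometimes restricts the candidate list or epoch budget; the final
refit always searches deterministically within 5..12. Operon-validation
checks use 500–2000 permutations. These sizes were chosen so each suite
exercises the full method at realistic per-condition sample sizes.

## Known limitations

- The MLP optimizer is a fixed, reproducible contract; it is not meant to
  replicate any external toolbox's weights.
- Nc is undefined (NaN) for genes lacking an observable two-, four- or
  six-fold family; such genes are complete-cased out of the logistic
  panel.
- The stepwise procedure inherits the usual caveats of stepwise
  inference: reported SEs and p-values are conditional on the selected
  model.
- CA axes are comparable across runs only through the fixed sign rule;
  axes near ties in inertia can swap order between datasets.
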