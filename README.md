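# protimpute

Transcriptome-guided imputation of missing shotgun-proteomics data, with
operon-based validation and logistic modelling of protein detectability.

## The problem

Shotgun (LC-MS/MS) proteomics typically detects only 10–30% of a
bacterial proteome: low-abundance, unstable or otherwise awkward proteins
simply yield no peptide identifications. Treating those proteins as
"zero" biases every downstream comparison. When a cognate transcriptomic
dataset exists for the same conditions, the transcript–protein
relationship can be learned on the detected proteins and used to assign
abundance estimates to the undetected ones.

`protimpute` implements that workflow end to end for paired microarray
fluorescence (transcripts) and peptide-hit counts (proteins), as in the
*Desulfovibrio vulgaris* datasets it was designed around:

1. **Preprocessing** — quantile normalization of transcript intensities,
   log2 transformation, collapse of replicates with a minimum-presence
   rule (e.g. ≥3 of 4 replicates measured).
2. **Sequence features** — per-gene codon adaptation index (CAI) against
   a ribosomal-protein reference, Wright's effective number of codons
   (Nc), synonymous third-position composition (A3s/T3s/C3s/G3s, GC3s),
   GC content, correspondence-analysis axes of amino-acid and RSCU usage
   (AA_axis1–4, CR_axis1–4), and ProtParam-style protein indices (GRAVY,
   aromaticity, aliphatic index, instability index, molecular weight).
3. **Imputation** — a single-hidden-layer perceptron
   `y = w₂·f(W₁x′ + b₁) + b₂` with hidden activation
   `f(v) = (1 − e^{−v})/(1 + e^{−v}) = tanh(v/2)` and a linear output,
   inputs and target rescaled to [−1, 1]; the hidden size is selected
   from 5..12 by 10-fold cross-validation and the fit is reported as the
   coefficient of determination R².
4. **Operon validation** — genes co-transcribed in an operon (same-strand
   runs with intergenic gaps < 15 bp) should have coherent protein
   levels, so each operon's coefficient of variation (CV = SD/mean of
   molecular-weight-normalized predictions) is compared with 2000
   size-matched random gene sets: PCV is the mean permuted CV and the
   percentile score is the fraction of permuted CVs ≤ the observed one.
5. **Missingness model** — stepwise logistic regression
   `logit(pᵢ) = β₀ + β₁x₁ᵢ + … + β_k x_kᵢ` for the probability a protein
   is undetected, with likelihood-ratio entry/removal at the 0.05 level
   and odds ratios `e^{β_j}` with 95% Wald limits.
6. **Reporting** — cross-condition differential tables from the imputed
   data, with undetected proteins rendered `x`.

Because the original paired datasets are not publicly deposited, the
package ships a first-class synthetic-data generator
(`protimpute.synthetic_data`) that reproduces their statistical
structure — operon-structured genome, codon-bias gradients, replicate
noise, a saturating transcript→protein link with negative-binomial
peptide counts, and a logistic missingness mechanism with known
coefficients — so every stage is testable against ground truth.

## Worked example

`examples/` contains one short script per capability. Training the
imputer on a 900-gene synthetic dataset (about 270 detected proteins per
condition, as in a real campaign) prints:

```
$ python examples/04_impute_proteome.py
condition:            LL
training genes:       274
selected hidden size: 8
training R^2:         0.506
imputed proteins:     596
rank corr. with withheld truth: 0.836
```

The R² of ~0.5 is what the generator's noise allows (protein-level noise
plus peptide-count dispersion); the rank correlation of 0.84 between
imputed values and the withheld true abundances of *undetected* proteins
is the quantity that matters for downstream interpretation. Validating
the same predictions against operons (`examples/05_validate_operons.py`):

```
operons validated:            220
fraction CV < PCV:            89.09%
fraction percentile < 0.2:    53.64%
```

i.e. 89% of operons are more coherent than size-matched random gene
sets. The missingness model (`examples/06_missingness_model.py`) recovers
the generating mechanism exactly — stepwise selection keeps `mRNA_log2`
(odds ratio 0.441 per log2 unit, truth e^{−0.8} = 0.449) and
`InstabilityIndex` (1.681 per 10 units, truth e^{0.5} = 1.649) and
nothing else. The bundled *D. vulgaris* energy-metabolism table
(`examples/07_differential_report.py`) shows the motivating use case:
only 2 of 9 putative ATP synthase subunits were ever detected
experimentally, yet the imputed complex shows a coherent ~0.89× mean
downregulation on formate relative to lactate-exponential growth.

A thin CLI mirrors the library (`protimpute simulate`, `features`,
`operons`, `run-all`, `report`, …); `protimpute run-all --config run.yaml`
executes every stage and writes per-stage TSV/JSON artifacts plus the
resolved config and seed.

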