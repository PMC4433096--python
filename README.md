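# mockbias

Quantifying and correcting bias in 16S rRNA amplicon surveys with
mixture-design mock communities.

Read counts from 16S amplicon sequencing are a distorted picture of the
cells actually present: DNA extraction, PCR amplification, and
sequencing/classification each amplify some taxa and suppress others, on
top of the purely arithmetic inflation from 16S gene copy number.
`mockbias` implements the full mock-community protocol for measuring that
distortion and inverting it, aimed at microbiome labs validating a
processing pipeline for a small panel of target organisms (the shipped
panel is seven vaginally-relevant strains).

## What it computes

**Design.** A mixture experiment prescribes proportions x₁,…,x_p ≥ 0 with
Σxᵢ = 1 per mock community. Responses on the simplex are modeled with the
Scheffé special cubic polynomial

    E(y) = Σᵢ βᵢxᵢ + ΣΣ_{i<j} β_ij xᵢxⱼ + ΣΣΣ_{i<j<k} β_ijk xᵢxⱼx_k,

which has p + C(p,2) + C(p,3) coefficients (63 for p = 7, 298 for p = 12),
so at least that many runs are needed. `mockbias` builds a D-optimal
support from the classic vertex / binary-midpoint / ternary-centroid
candidate set by Fedorov point exchange, then adds interior lack-of-fit
runs and exact replicates: the default seven-taxon layout is 80 runs with
65 unique treatment combinations and 15 replicates.

**Bias.** Three parallel experiments mix prescribed proportions of cells,
genomic DNA, and PCR product over the same design. After adjusting counts
(cells: divide by 16S copy number; DNA: multiply by genome size, divide by
copy number) and normalizing, the bias of taxon i is x̂ᵢ − xᵢ (observed
minus prescribed; negative = suppressed). Differencing the experiments
attributes bias to stages — extraction (exp1 − exp2), PCR (exp2 − exp3),
sequencing/classification (exp3 − prescribed) — which telescope to the
total (exp1 − prescribed). Replicates give the technical-variation floor
(median absolute error), and a bootstrap Mahalanobis test flags stages
whose mean bias vector differs from zero.

**Models.** Per-taxon special cubic fits of observed on prescribed
proportions screen Bonferroni-adjusted blending terms: a significant
positive β_ij is a synergistic relationship (taxon j inflates the observed
proportion of i), negative is antagonistic.

**Correction.** Per-taxon random forests (500 trees, two split variables)
learn the scaling factor x̂ᵢ/xᵢ from the mocks as a function of the
observed proportion vector; new samples are copy-number adjusted, divided
by the predicted factor, and re-normalized to estimate true composition.

Because real sequencing runs are not required, a forward simulator with
exportable ground truth (per-taxon stage efficiencies, pairwise
interaction coefficients, lognormal technical jitter, multinomial read
sampling) generates the three experiments for validation end to end.

## Worked example

The numbered scripts under `analysis/` run the whole protocol on simulated
data and write tables to `results/`:

```
$ python analysis/01_generate_design.py
panel: 7 taxa -> minimum runs 63
assembled 80 runs (65 unique treatments, 15 replicates, 2 lack-of-fit) -> results/design.csv

$ python analysis/02_simulate_experiments.py
truth (seed 2): depth 16000 reads/sample, noise cv 0.03, 5 extraction and 14 PCR interaction terms
exp1 (cells): 80 samples, 1,280,000 reads -> results/exp1.tsv
...

$ python analysis/03_quantify_bias.py
median bias per taxon (total stage):
  A. vaginae       -19.0%
  G. vaginalis     -17.6%
  L. crispatus      -0.4%
  L. iners         +20.3%
  ...
replicate median absolute error (max over taxa):
  exp1: 0.59%
  exp2: 0.86%
  exp3: 0.82%

$ python analysis/04_fit_mixture_models.py
A. vaginae      R2=0.9999 significant blends: 18 (10 synergistic, 8 antagonistic)
...

$ python analysis/05_inverse_correction.py
clinical-like samples: uncorrected MAE 4.01% -> corrected MAE 0.91%
```

Reading the output: under this simulated truth the observed proportion of
*L. iners* overshoots its true share by a median of 20 percentage points
while *A. vaginae* is suppressed by 19; technical replicates disagree by
under 1%, so the distortion is bias, not noise. All seven special cubic
models fit with R² > 0.99, and applying the learned inverse models to 50
held-out low-diversity samples cuts the mean composition error from 4.0%
to 0.9%.

The same steps are available as a CLI (`mockbias design | simulate | bias |
fit | correct | run`) and as library functions (`mockbias.build_design`,
`simulate_experiment`, `stage_decomposition`, `fit_taxon_models`,
`fit_inverse`, ...).

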