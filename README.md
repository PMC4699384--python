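# prc2kit

Analysis toolkit for four linked questions about Polycomb (PRC2) biology in
tumors, built entirely on synthetic data generators so every stage is
testable offline:

1. **Prognosis** (`prc2kit.prognosis`) — proliferation-metagene adjustment of
   a marker transcript plus a from-scratch survival suite: Kaplan–Meier,
   k-sample log-rank with O/E hazard ratios, univariate Cox (Efron or
   Breslow ties, Newton–Raphson with step-halving and monotone-likelihood
   detection), Benjamini–Hochberg FDR, per-gene copy-number-loss Cox scans,
   and rank-based ROC AUC. The headline behavior: a marker whose hazard
   contribution mixes a positive proliferation component with a negative
   proliferation-independent component shows HR(high vs low) > 1 before
   adjustment and < 1 after OLS residualization on the metagene.
2. **Homeostasis** (`prc2kit.homeostasis`) — kinetics of a repressive
   histone-mark occupancy fraction under enzyme-dependent deposition,
   turnover, and cell-division dilution (`dm/dt = αE(1−m) − δm − g·ln2·m`),
   with closed-form steady state, RK4 and discrete-halving integrators,
   growth-rate sweeps under enzyme–proliferation coupling, and a
   least-squares parameter fitter. Proportional coupling keeps the mark
   constant across growth rates; fixed or under-scaled enzyme makes it
   strictly decreasing.
3. **Targets** (`prc2kit.targets`) — classification of repressed target
   genes from promoter mark density (bedGraph coverage around the TSS,
   scaled, against genomic background and a knockout condition) and
   replicated expression contrasts (rank-product statistic with permutation
   pfp and a geometric-mean fold-change gate; defaults pfp ≤ 0.15, FC ≥ 2),
   including responsive/indirect/nonresponsive partition, early/late timing,
   TSS density profiles, and rescue classification.
4. **Single cell** (`prc2kit.singlecell`) — dye/genotype-assay consistency
   filtering, binary detection matrices, per-genotype detection frequencies
   with exact binomial CIs, and a variance-ratio concordance statistic
   (S = 1 for all-or-none activation, ≈ 0 for independent genes) with a
   permutation p-value.

`prc2kit.synthetic_data` generates every input (cohort expression/CNV/
survival tables, growth-rate triplets, promoter signal + time courses,
single-cell matrices) with planted ground truth; `prc2kit.io` holds strict
TSV/bedGraph/JSON readers and writers.

## CLI

All stages are exposed under a single entry point; each run writes results
plus `provenance.json` (inputs, parameters, seed, version) to `--out`:

```bash
prc2kit simulate-cohort --seed 1 --out sim/
prc2kit prognosis --expression sim/expression.tsv --clinical sim/clinical.tsv \
    --cnv sim/cnv.tsv --out results/
prc2kit scan --cnv sim/cnv.tsv --clinical sim/clinical.tsv --out results/
prc2kit simulate-targets --seed 1 --out simt/
prc2kit targets --bedgraph-wt simt/signal_wt.bedgraph \
    --bedgraph-ko simt/signal_ko.bedgraph --annotation simt/annotation.tsv \
    --timecourse simt/timecourse.tsv --out results/
prc2kit simulate-cells --seed 1 --out simc/
prc2kit singlecell --expression simc/expression.tsv --cells simc/cells.tsv \
    --out results/
prc2kit homeostasis --config params.json --out results/
```

Exit codes: 0 success, 2 missing input, 3 validation failure. Parameter
overrides come from a JSON `--config` file.

## Conventions

- Expression values are log2; time-course columns are named
  `t<timepoint>_r<replicate>`.
- bedGraph intervals are 0-based half-open; annotation TSS is 1-based and
  converted on load.
- Copy-number states: −2 homozygous loss, −1 hemizygous loss, 0 neutral,
  +1 gain; median splits send ties to "low".
- Every generator takes its seed in the config and is reproducible
  byte-for-byte.
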