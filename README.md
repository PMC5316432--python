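# fuzzybase

Neuro-fuzzy per-base confidence estimation for DNA base calling.

A called base in a sequencing trace is described by six normalized
features: the peakness of the called peak and of the runner-up peak
(`NP_called`, `NP_2nd`), their heights (`NH_called`, `NH_2nd`), and the
spacing to the next and previous peaks (`dNS_next`, `dNS_prev`).  Three
two-input ANFIS subsystems (adaptive neuro-fuzzy inference systems) turn
these into a peakness score, a height score and a spacing score; a
three-input main system combines the scores into one confidence value in
[0, 1] per base.

Every system is a grid-partitioned zero-order Sugeno FIS with 5
membership functions per input and constant rule consequents — triangular
MFs for peakness, two-sided Gaussians for height, trapezoids for spacing,
and two-sided Gaussians for the main confidence system.  Training is
full-batch backpropagation (500 epochs by default, adaptive step length,
optional hybrid least-squares/gradient method) on sample files of 500
records split 350/150 into train/test.

The trace-derived sample files the design is based on are not available,
so `fuzzybase.synthetic` generates statistically similar 500-record files
with supervised targets from smooth monotone reference functions.  A
bundled six-base worked example (ATCTCG) with reference outputs of the
originally trained systems is used for qualitative comparison; exact
reference values are not reproducible because the original training data
is unpublished.

## CLI

```sh
# write synthetic training files (peakness/height/spacing/confidence CSVs)
fuzzybase generate --out-dir data --seed 0

# train all four systems and save a JSON model bundle
fuzzybase train --data-dir data --out model.json --seed 0 --epochs 500

# score a record file (base,NP_called,NP_2nd,NH_called,NH_2nd,dNS_next,dNS_prev)
fuzzybase predict --model model.json --records data/records.csv --out scored.csv

# RMSE of one system on a labeled sample file
fuzzybase eval --model model.json --data data/peakness.csv --system peakness

# train on defaults and print the six-base worked example next to the
# reference values
fuzzybase demo --seed 0
```

Exit codes: 0 success, 2 validation error, 3 numeric failure.  The same
functionality is available programmatically via `fuzzybase.fit_pipeline`,
`PipelineModel`, `make_training_files`, `train`, `evaluate` and `split`.

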