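# flexdecode

Population decoding of history-dependent olfactory spike-train ensembles.

The package implements an analysis pipeline for projection-neuron (PN)
ensemble recordings in which a target odorant is presented either solitarily
or 500 ms after a distractor odorant:

- **core** — spike rasters, stimulus protocols, 50 ms half-open binning,
  trial averaging, and condition concatenation with provenance (the
  85 × 80 per-odor response matrices and their 480- / 240-column
  concatenations).
- **simulate** — a seeded inhomogeneous-Poisson generator of PN ensembles
  with transient-then-steady ON responses, below-baseline inhibition,
  largely non-overlapping OFF ensembles, history cross-talk (shared
  responders suppressed, distractor-inhibited responders enhanced), and
  synthetic palp-opening-response (POR) traces — all with exported ground
  truth.
- **characterize** — responder barcodes (mean + 6.5 s.d. pre-stimulus
  criterion), response latencies with the 600 ms early/late cutoff, and
  consistent / unique-consistent set algebra.
- **geometry** — PCA / LDA population trajectories, per-trial ensemble
  correlations over the first response second with paired t-tests
  (contrast enhancement), the linear shift prediction, and per-neuron
  temporal-pattern correlations.
- **decoders** — a linear soft-margin SVM (box constraint 0.01), the
  flexible m-of-n (OR-of-ANDs) decoder in analog and digital variants,
  per-bin classification probabilities, and a leave-one-trial-out
  nearest-centroid confusion matrix.
- **behavior** — POR responsiveness classification, ON/OFF binary weight
  templates, and the ON–OFF model that turns ON/OFF classification
  probabilities into predicted palp opening/closing.
- **pipeline / cli** — a config-driven, fully reproducible end-to-end run.

## CLI

```sh
flexdecode run-all --seed 17 --out rundir            # defaults: 85 PNs, 10 trials
flexdecode run-all --config config.yaml --out rundir
```

Stage subcommands (`simulate`, `characterize`, `trajectories`, `contrast`,
`decode-svm`, `decode-flex`, `predict-por`) operate on the same run
directory and read only the documented CSV/JSON artifacts of earlier
stages. Example config:

```yaml
simulate:
  n_neurons: 85
  n_trials: 10
  odors: [hex, 2oct, iaa, bzald, cit, app]
  suppression_factor: 0.4
  enhancement_factor: 1.5
  seed: 17
target: hex
distractors: [2oct, iaa, bzald, cit, app]
bin_width_s: 0.05
k_sd: 6.5
flex_m: 4
```

A run directory contains, per stage: ground truth and rasters
(`simulate/`), barcodes and latencies (`characterize/`), PCA trajectories
and the contrast report (`geometry/`), decoder models and per-bin
classification probabilities (`decode/`), fitted ON–OFF parameters and
predicted-vs-observed PORs (`behavior/`), plus `summary.json` and a
parameter-echoing `run.log`. Identical config + seed reproduces identical
outputs.

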