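# hetfx

Heterogeneous treatment-effect analysis for multi-reader multi-case
(MRMC) diagnostic studies with AI assistance.

Given read-level tables — one predicted probability (0–100) per
(radiologist, patient case, pathology, treatment condition), plus
expert-consensus continuous case truths, AI predictions, and reader
survey characteristics — the package provides:

* **Metrics** (`hetfx.metrics`): absolute/signed error, empirical
  AUROC (Mann–Whitney with half-credit ties), sensitivity/specificity,
  and per-reader condition means with standard errors. Treatment-effect
  sign conventions: `unassisted − assisted` for error metrics and
  `assisted − unassisted` for AUROC, so positive always means
  improvement.
* **Empirical Bayes shrinkage** (`hetfx.empirical_bayes`): normal–normal
  method-of-moments prior (grand mean; variance of reader means minus
  the mean squared standard error) and closed-form posterior updates
  that de-noise per-reader heterogeneity estimates.
* **Two-way cluster-robust OLS** (`hetfx.regression_core`): sandwich
  covariance clustered on patient case × radiologist via
  inclusion–exclusion, the treatment-effect and subgroup-specific
  regression models, Wald joint-equality tests, unpaired t-tests,
  Benjamini–Hochberg FDR control, and the binned-AUROC F-test.
* **Split-sampling designs** (`hetfx.split_sampling`): leave-one-case-out
  regression constructions that keep the baseline predictor and the
  outcome on disjoint cases — eliminating reversion-to-the-mean bias —
  plus the deliberately biased "naive" diagnostic and the
  errors-in-variables attenuation correction (slope and SE divided by
  the plug-in reliability ratio λ).
* **Subgroup & bin analyses** (`hetfx.subgroup_analysis`): oracle and
  characteristic median splits, the cross-fitted
  combined-characteristics split, AI absolute-error (5 bins) and
  signed-error (10 bins) treatment-effect tables, and the strict >10%
  high-prevalence pathology filter.
* **Synthetic studies** (`hetfx.synthetic_data`): a generator that
  reproduces the study structure (non-repeated readers with disjoint
  30/30 assisted/unassisted case sets, repeated readers under all four
  conditions, a 324-case pool, 15 pathologies with heterogeneous
  prevalence) with known per-reader true effects, so every analysis
  stage has a parameter-recovery test without the restricted dataset.

## CLI

```bash
# generate a synthetic bundle (reads/truths/ai/profiles CSVs + sim_truth.json)
hetfx simulate --config sim.yaml --out data/ --seed 1

# per-reader summaries for one metric
hetfx summarize --in data/ --metric abs_error --out reader_summaries.csv

# full pipeline: summarize -> shrink -> subgroups -> split sampling -> bins
hetfx analyze --in data/ --out report/ --seed 1
# or simulate-and-analyze in one go
hetfx analyze --simulate sim.yaml --out report/ --seed 1
```

`analyze` writes CSV tables (`reader_summaries.csv`, `shrinkage.csv`,
`subgroups.csv`, `split_design.csv`, `bins.csv`, `binscatter.csv`), an
`attenuation.json`, and a machine-readable `summary.json` that embeds
the resolved configuration, seed and a manifest of row counts and
exclusions.

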