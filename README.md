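# mirserum

Differential-expression analysis for serum miRNA qPCR panels measured on a
handful of pooled replicates — the setting of biomarker screens where a
~750-assay panel is run for four clinical severity groups (normal, mild,
moderate, severe) with two serum pools each, and the question is which
circulating miRNAs separate patients from controls.

The package implements the full screening workflow as a tested library plus
a `mirserum` command line:

- **I/O and QC** — wide/long Ct tables with roles (target / reference / IPC /
  other control), panel and plate assignment, right-censoring at the
  40-cycle ceiling; inter-plate-calibrator QC (strict SD < 0.05 gate) and
  additive plate calibration.
- **Normalization** — strict "Ct < 40 in all measurements" expression
  filter, reference-gene stability ranking, and mean-of-reference delta-Ct
  scaling (default anchors miR-103a-3p, miR-423-5p, miR-191-5p).
- **Differential core** — empirical-Bayes moderated t: per-feature pooled
  variance s² shrunk toward a prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), with
  (d₀, s₀²) by method of moments on log s²; fold change FC = 2^(−Δ); and a
  permutation **sampling p** (default B = 10 000) that permutes values
  across features within each sample group and pools the null p-values.
  Candidates (sampling p < 0.05) are intersected across the two analysis
  branches (raw Ct vs IPC/delta-Ct) and across group comparisons.
- **Enrichment** — candidate miRNAs → validated gene targets →
  hypergeometric term enrichment with fold enrichment (k/n)/(K/N) and
  Benjamini–Hochberg FDR (DAVID-style EASE variant by flag).
- **Validation** — per-patient Student's t on delta-Ct and ROC/AUC by the
  Mann–Whitney rank estimator.
- **Synthetic data** — a generator for the full panel design (two panels,
  pooled groups, IPC wells, stable references, censoring at 40), so every
  stage is testable without instrument data.

See `docs/methods.md` for the model, its assumptions and the numerical
choices.

## Worked example

Simulate a screen with three known group effects, run the raw branch for
the normal-vs-mild comparison, and select candidates:

```python
from mirserum import (SimConfig, simulate_experiment, filter_expressed,
                      GroupComparison, fit_moderated_t, sampling_p,
                      build_diff_table, select_candidates)
from mirserum.normalization import NormalizedTable

spikes = [("hsa-miR-i0001", "mild", -4.7),   # ~2^4.7 = 26-fold up in cases
          ("hsa-miR-i0003", "mild", 3.3),    # ~10-fold down
          ("hsa-miR-i0005", "mild", -2.4)]
table, sheet, truth = simulate_experiment(SimConfig(seed=1, spikes=spikes))

filtered = filter_expressed(table, panel_policy="panel_I_only")
targets = [f for f in filtered.features if filtered.roles[f] == "target"]
data = NormalizedTable(values=filtered.values.loc[targets], provenance="raw")

comp = GroupComparison("normal_vs_mild", case="mild", control="normal")
fit = fit_moderated_t(data, sheet, comp)
sp = sampling_p(data, sheet, comp, B=10_000, seed=17)
diff = build_diff_table(fit, sp)
print(diff.head(6))
```

```
                  dCt     FC   p value  sampling p
MicroRNA Name
hsa-miR-i0001   -4.31  19.84 1.274e-64           0
hsa-miR-i0003   3.249 0.1052 1.752e-37           0
hsa-miR-i0005  -2.553  5.868  8.86e-24           0
hsa-miR-i0367  0.8338 0.5611  0.001025   2.688e-06
hsa-miR-i0016 -0.6596   1.58  0.009385     0.00336
hsa-miR-i0279  0.6586 0.6335  0.009494    0.003427
```

The three spiked assays top the ranking with the right signs: `dCt` is the
case-minus-control difference on the cycle scale (negative = fewer cycles =
more template = up-regulated), and `FC = 2^(−dCt)` recovers the planted
26-, 10- and 5.9-fold changes within sampling error of two pools per group.
`select_candidates(diff, alpha=0.05)` keeps the 29 features with sampling
p < 0.05 — the three spikes plus the ≈5% of 372 null features expected at
that threshold, which is exactly what the branch and group intersections
are for.

The same workflow runs end-to-end from a YAML config:

```sh
mirserum simulate --seed 1 --out-dir fixtures/ --spike hsa-miR-i0001:mild:-4.7
mirserum run --config pipeline.yaml
```

writing one TSV per comparison × branch (`MicroRNA Name, dCt, FC, p value,
sampling p`), intersection lists, enrichment tables and a JSON manifest
that records every parameter and derived seed.

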