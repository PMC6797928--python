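# methyldelay

Case/control DNA-methylome analysis for array-style beta-value data, built
around four questions that arise when comparing the methylome of a clinical
cohort (e.g. autism-diagnosed donors) against matched controls across age
groups:

1. **Which CpGs are differentially methylated?**  Per age group, a
   differentially methylated locus (DML) is a probe passing both an
   effect-size gate |Δβ| ≥ 0.10 (Δβ = mean β<sub>case</sub> − mean
   β<sub>control</sub>) and a significance gate *p* < 0.05 from a
   **permutation empirical-Bayes test**: the per-probe pooled variance
   s²<sub>g</sub> is shrunk toward a common prior,
   s²<sub>post,g</sub> = (d₀s₀² + d·s²<sub>g</sub>)/(d₀ + d), with (d₀, s₀²)
   fit by method of moments on the log sample variances; the moderated
   statistic t<sub>g</sub> = Δβ / √(s²<sub>post,g</sub>(1/n₁ + 1/n₂)) gets an
   empirical two-sided *p* by permuting the case/control labels (exact
   enumeration of all balanced assignments when they number ≤ 2,000).
2. **Where do the DML sit?**  χ² goodness-of-fit of their genomic-region
   categories against the array background, and fold enrichment inside
   bivalent chromatin domains — the intersection of H3K4me3 and H3K27me3
   peak tracks, computed by a bedtools-style per-pair interval engine
   (a CpG at 1-based position *p* occupies [p−1, p+1) and counts when it
   overlaps a domain by ≥ 1 bp).
3. **Are they developmentally dynamic?**  CpGs whose fetal-brain methylation
   changes across four prenatal stage bins (23–76, 77–89, 90–108, 109–184
   days post conception) are "dynamic"; CpGs both bivalent **and** dynamic
   form **epigenetically dynamic regions (EDRs)**, and DML enrichment in
   dynamic CpGs and EDRs is quantified as fold = (hit rate in DML)/(hit
   rate in background) with a 1-df χ².
4. **Is there an epigenetic delay?**  Group-mean methylation at the
   DML-in-EDR CpGs is correlated (Pearson) against each fetal stage's mean
   methylome; the delay score r<sub>case</sub> − r<sub>control</sub> at the
   two earliest prenatal stages is positive when the case methylome
   resembles an earlier developmental state than its matched controls.

A first-class synthetic-data generator emulates the whole study — manifest,
peak tracks, staged fetal methylomes, case/control cohort — with planted
ground truth (DML effects, bivalent set, dynamic set, delayed CpGs), so
every stage is testable end-to-end without downloading any cohort data.
Auxiliary procedures from the same study design are included: cell-type
concordance (Pearson correlation to glia/neuron reference profiles),
complete-linkage/Manhattan sample clustering, KS and Welch t comparisons,
percent-spliced-in (Ψ) event classification, and the ELISA percent-5mC
standard-curve fit.

## Worked example

```python
from methyldelay import SimulationConfig, simulate_dataset, filter_probes
from methyldelay import comparisons_from_sample_sheet, run_comparison

cfg = SimulationConfig(n_probes=4000, seed=7)
data = simulate_dataset(cfg)
betas, report = filter_probes(data.betas, data.manifest)
print(f"retained {report.n_retained}/{report.n_input} probes")
spec = comparisons_from_sample_sheet(data.samples)[0]
called = run_comparison(betas, spec, seed=7)
print(f"{spec.label}: {len(called.table)} DML")
print(called.table.head(3)[["delta_beta", "t_mod", "p_perm"]].round(4))
```

prints

```
retained 3926/4000 probes
young: 70 DML
            delta_beta    t_mod  p_perm
cg00000030      0.1399  12.7759  0.0022
cg00000209      0.1363  12.4518  0.0022
cg00000306     -0.1420 -12.9717  0.0022
```

74 probes were SNP-flagged and removed by QC; the young-group comparison
(6 cases vs 6 controls) calls 70 DML, each with a planted |Δβ| near 0.15 and
the smallest attainable exhaustive permutation *p* of 2/924 ≈ 0.0022 (924
balanced relabellings of 12 samples).

The full pipeline is one call (or `methyldelay run --config cfg.yaml`):

```python
from methyldelay import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(outdir="demo", seed=7, simulate={"n_probes": 4000}))
print("dml:", summary["dml"])
print("dynamic fold:", summary["dynamic"]["fold"])
print("edr:", {k: summary["edr"][k] for k in ("n_edr", "n_dml_in_edr", "fold")})
print("delay (pooled):", summary["delay"]["delay_scores_pooled"])
```

```
dml: {'young': 71, 'middle': 70, 'old': 70, 'union': 195}
dynamic fold: 3.0054
edr: {'n_edr': 45, 'n_dml_in_edr': 9, 'fold': 4.0072}
delay (pooled): {'all': {'s1': 0.7981, 's2': 0.3732}}
```

The DML union is ~3-fold enriched among developmentally dynamic CpGs and
~4-fold enriched in EDRs — recovering the rates at which the generator
planted them — and the pooled case-vs-control delay scores at the two
earliest prenatal stages are positive, recovering the planted delay.  The
output directory also holds per-group DML tables, enrichment TSVs, the
group × stage correlation matrix, and a `summary.json` that is bit-identical
across reruns with the same config and seed.

The statistical core is also exposed as scikit-learn estimators:
`DMLDetector` (a feature selector over probes: `fit(X, y)` on a
samples × probes matrix, `transform` keeps called DML) and
`CellTypeCorrelator` (nearest-reference classification under Pearson
correlation), so both compose with sklearn pipelines and model selection.

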