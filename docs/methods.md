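# Methods

## Differential methylation: moderated t with a permutation null

Beta values (methylated / total signal, β ∈ [0, 1]) are compared between a
case and a control arm within each age group.  For probe *g* with arm sizes
n₁, n₂ and pooled two-sample variance s²_g on d = n₁ + n₂ − 2 degrees of
freedom, the variance is moderated empirical-Bayes style:

    s²_post,g = (d₀·s₀² + d·s²_g) / (d₀ + d)
    t_g       = Δβ_g / sqrt(s²_post,g · (1/n₁ + 1/n₂))

The prior (d₀, s₀²) is fit by method of moments on z_g = log s²_g.  Under a
scaled-F model, E[z] = log s₀² + ψ(d/2) − log(d/2) − ψ(d₀/2) + log(d₀/2) and
Var[z] = ψ′(d/2) + ψ′(d₀/2), so d₀ solves ψ′(d₀/2) = Var̂[e] − ψ′(d/2)
(Newton inversion of the trigamma function) with e_g = z_g − ψ(d/2) +
log(d/2).  When the observed log-variance dispersion does not exceed the
sampling floor ψ′(d/2), the data carry no evidence of heterogeneity: d₀ is
taken as infinite and s²_post is set to the geometric mean of the raw
variances, which makes perfectly homogeneous variances a fixed point of the
shrinkage (identical s² in → identical s² out).  Zero-variance probes are
excluded from the moment fit; if no probe has positive variance the
statistic falls back to the unmoderated t with a warning.

Significance comes from permuting the case/control labels, re-running the
*entire* statistic — including re-estimation of (d₀, s₀²) — for each
relabelling:

- **Exhaustive mode** (automatic when C(n, n₁) ≤ 2,000, which covers the
  target design of ~6 samples per arm, C(12, 6) = 924): the two-sided p is
  the exact fraction of balanced assignments with |t*| ≥ |t_obs|, identity
  included, so p ∈ (0, 1] with minimum 2/C(n, n₁) (an assignment and its
  complement always tie in |t|).
- **Monte-Carlo mode** otherwise: B random assignments and the add-one
  estimator p = (1 + #{|t*| ≥ |t_obs|}) / (B + 1), default B = 999.

A probe is a DML when p < α and |Δβ| ≥ δ, defaults α = 0.05, δ = 0.10.  The
boundary is inclusive on the effect size.  **No multiple-testing correction
is applied** — the raw-p-plus-effect-size gate is the procedure being
replicated and is deliberately conservative only through the Δβ gate; users
screening large arrays for discovery should add FDR control themselves.
Tie comparison uses |t*| ≥ |t_obs| − 10⁻¹², so exact complements count even
after floating-point evaluation.

Under a null cohort (no planted effects, 6 vs 6, 2,000 probes), the
exhaustive p-values are uniform and the empirical type-I error at α = 0.05
sits at the attainable exact level 46/924 ≈ 0.0498; both properties are
asserted by the acceptance tests.

## Interval engine and enrichment statistics

Peak tracks are 0-based half-open (chrom, start, end) intervals.
`intersect_tracks` emits one fragment per overlapping (a, b) pair — the
common "intersect" semantics under which the two histone-mark tracks yield
a count of overlapping peaks — using a sorted scan with a cumulative
max-end bound, so mutually overlapping intervals inside one raw track are
handled.  `merge_peaks` collapses book-ended/overlapping runs.  A CpG probe
at 1-based cytosine position p occupies the dinucleotide interval
[p−1, p+1) and counts as inside a domain when it overlaps any merged
interval by at least one base.  The engine is validated against a per-base
brute-force oracle on random toy genomes and against bedtools on random
tracks.

Fold enrichment of a probe subset in an annotation is
(hits/|subset|) / (background hits/|background|), with a 1-df χ²
goodness-of-fit of the observed subset hit count against its
background-rate expectation; region-category distributions use the k−1-df
χ² against the post-filter manifest proportions.  Percentages are reported
to one decimal with round-half-even; a printed value that can only be
reached by truncation is documented as a discrepancy rather than
replicated.

## Probe filtering

A probe is removed when it has a missing value in any sample, carries a SNP
flag, or exceeds detection p 0.05 in **any** sample (the conservative
reading of "low detection P"; the quantifier is a design choice documented
here because alternative readings — mean p, fraction of samples — retain
more probes).  Surviving values are never altered.

## Fetal trajectories and the delay score

Staged fetal reference methylomes are reduced to per-CpG arithmetic means
over four day-post-conception bins (23–76, 77–89, 90–108, 109–184); every
sample must fall in exactly one bin and no bin may be empty.  "Dynamic"
CpGs are those whose stage-mean range is ≥ 0.1 β units (half the
generator's minimum planted trajectory span of 0.2, leaving equal margin
against noise in both directions).  EDRs are the intersection of the
bivalent and dynamic CpG sets.

The delay analysis correlates per-CpG **group means** (not per-sample
values) against each fetal stage's mean vector, over the case-associated
DML that fall inside EDRs — the analysis subset is the DML ∩ EDR CpGs, with
a fallback to the full EDR set when fewer than three are available.  The
delay score for a group at stage s is r_case(s) − r_control(s), evaluated
at the two earliest prenatal stages; a positive score flags a methylome
resembling an earlier developmental state.  Scores are computed both per
age group and with age groups pooled per diagnosis; the pooled score is the
headline statistic (it averages over age-group-specific planted effects and
is the stabler summary), the per-group matrix is written alongside.
Correlation p-values are two-sided t-approximations without multiplicity
correction.

## The synthetic-data generator

The generator emulates the emulated study's shapes and effect sizes; its
defaults are the package's reference conditions and are exercised verbatim
by the acceptance tests.

| parameter | default | rationale |
|---|---|---|
| n_probes | 10,000 | array scaled down ~45× ; keeps exhaustive permutation × 3 comparisons in seconds |
| age_groups × n_per_group | 3 × 6 per arm | the 34-sample three-age-group case/control design |
| dml_fraction | 0.05 | planted DML per cohort (union over groups) |
| dml_delta | 0.15 | straddles the 0.10 call gate without saturating β |
| noise_sd | 0.02 | per-sample β noise, truncated-Gaussian on the β scale |
| bivalent_probe_fraction | 0.10 | array fraction inside both-mark domains |
| dynamic_fraction | 0.08 | ≈ the 28,718/~450k dynamic-CpG fraction |
| edr_dml_fold / dynamic_dml_fold | 4.0 / 3.0 | planted enrichment of DML in EDRs / dynamic CpGs |
| delayed_fraction | 0.18 | fraction of EDR CpGs delayed; the largest value compatible with the 4-fold EDR quota (every delayed CpG is also a planted DML) |
| stage_bins, n_fetal_per_stage | the four d.p.c. bins, 25 | 100 fetal samples over 23–184 d.p.c. |

Construction: probe positions sit on a 16-bp grid (so peak margins can
never leak onto a neighbouring probe); bivalent CpGs receive core intervals
in both mark tracks with asymmetric margins while every other probe is
covered by at most one track — the two-track intersection therefore covers
*exactly* the planted bivalent set, and the region module recovers it
bit-for-bit.  Dynamic CpGs follow strictly monotone stage-mean trajectories
(total change uniform in [0.2, 0.5], random direction); control cohort
means equal the final-stage fetal means; case means add a signed dml_delta
at planted DML (sign flipped near the [0, 1] boundary, with the effective
delta recorded in the ground truth) and take an earlier stage's value at
delayed CpGs (earliest stage by default).  DML are apportioned across
EDR / dynamic-only / other strata by exact quotas so the realised
enrichment folds equal the planted ones up to rounding; regular DML are
partitioned into distinct per-age-group sets (as in the emulated study)
while delayed CpGs are DML in every group.  Noise is truncated-Gaussian on
the β scale — simpler than a logit-normal and adequate for recovery
testing; swap in a custom noise model by post-processing the emitted
matrices if heteroscedasticity near the β boundaries matters.

What the generator does **not** emulate: probe-level spatial correlation,
batch/chip effects, cell-composition drift between groups, bimodal β
distributions, and array detection-p failures (the detection-p filter is
exercised with hand-built fixtures instead).  Passing recovery tests
therefore demonstrates correctness of the statistical machinery under
clean, independent-probe conditions — not robustness to the correlated
noise structure of real arrays.

A "no-effect" configuration (dml_fraction = 0, delayed_fraction = 0) is the
null condition for calibration checks: with planted DML but no delay, the
case-profile perturbation depresses correlations at every stage equally —
a small uniform attenuation, not a delay signal — so centring checks are
run under the full null.

## Auxiliary procedures

- **Cell-type concordance**: Pearson r of each sample's β vector against
  reference cell-type profiles over shared marker CpGs; the label is the
  argmax-r type.  This is concordance, not deconvolution — no proportion
  estimates are produced.
- **Clustering**: complete linkage on Manhattan distances between sample β
  vectors; samples are sorted lexicographically before linkage so ties
  break deterministically.
- **Splice events**: inclusion class from the control Ψ (≥ 0.9 included,
  ≤ 0.1 excluded) and aberrance from ΔΨ = Ψ_control − Ψ_case (> 0.1 down,
  < −0.1 up).  The orientation (control − case, so "down" = reduced
  inclusion in cases) is a declared convention, flippable by flag.
- **ELISA percent-5mC**: "logarithmic second-order regression" is read as
  percent = a + b·ln(A) + c·ln(A)², i.e. quadratic in ln(absorbance),
  least squares over ≥ 3 standards; with exactly three distinct standards
  the fit interpolates them exactly.  The alternative reading (log of a
  quadratic) is monotone-equivalent only locally and is not implemented.

## Pipeline determinism

One run seed fans out to per-stage child seeds by CRC-hashing the stage
name, so adding or removing a stage never perturbs another stage's
randomness; no stage consumes wall-clock entropy and reruns with the same
config and seed are bit-identical, including `summary.json` and the log
(log lines deliberately carry no timestamps for this reason).

## Known limitations

- The Monte-Carlo permutation p-value has resolution 1/(B+1); with B = 999
  the smallest attainable p is 0.001 and α should not be set below it.
- Covariate adjustment (age, post-mortem interval, cell composition) is out
  of scope; the comparisons assume matched arms.
- The EDR enrichment denominator is the union of per-group DML sets; other
  denominators (per-group, sum of counts) can be computed by calling
  `edr_enrichment` with the corresponding id sets.
- Region-level (bump-style) detection, array normalisation and IDAT
  handling are outside the pipeline, which starts at normalised β values.
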