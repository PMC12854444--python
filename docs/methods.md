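# Methods

## The droplet model and its inverse

A ddPCR well partitions template into `n` droplets (default 20,000 of
0.85 nl, a QX-class instrument convention; both configurable). The forward
simulator assigns each molecule — after per-molecule dropout at `fn_rate` —
uniformly to one droplet (multinomial loading, equivalent to Poisson
loading conditional on totals), and draws false positives binomially at
`fp_rate` over the *unoccupied* droplets only, so a positive droplet is
never double-counted. Positives therefore can never exceed accepted
droplets, and with no noise a well with ≥ 1 molecule always has ≥ 1
positive droplet.

Quantification inverts this: λ = −ln(1 − k/n) mean copies per droplet,
concentration λ/V copies/µl. The 95% CI is a Wilson interval on k/n pushed
through that monotone transform; Wilson rather than Wald because it stays
informative at k = 0 and never degenerates. A fully positive well
(k = n) is reported with `saturated=True` and an infinite point estimate —
never silently dropped. Replicates are pooled by summing counts (the
maximum-likelihood pooling under the Poisson model), not by averaging
concentrations.

## Volume chain

`VolumeChain` maps copies/µl of reaction back to copies/ml plasma through
the sample-processing workflow: 4 ml plasma → 200 µl eluate (60 µl buffer
+ 140 µl water) → 30 µl removed for QC → 170 µl concentrated to 20 µl
(treated as lossless, so the output volume cancels) → bisulfite conversion
eluted in 15 µl → 6 µl template in a 24 µl reaction. The resulting default
multiplier is 24/6 × 15 × 200/170 ÷ 4 = 17.6470588… (copies/ml per
copy/µl), frozen as a regression constant in the tests. This chain is our
declared reading of the extraction/bisulfite workflow; instrument software
may normalize differently, so absolute copies/ml should be compared only
within one chain convention.

## Discovery cascade

Filtering precedes averaging: probes with any missing beta value are
removed, then group means are plain arithmetic means. The DMC rule is
strict (`>` 0.75 and `<` 0.25; boundary values excluded), matching the
printed inequalities, and probes without a CpG-island assignment are
discarded even when they pass.

RFE is re-implemented rather than borrowed: each round scores the
surviving features with a pluggable ranker (default: impurity importances
of an extra-trees ensemble; a deterministic |Δβ| mean-difference ranker is
provided), drops the lowest half (at least one feature), and records the
retained set's mean accuracy ± SE under repeated stratified k-fold CV of a
small random forest (defaults 10 folds × 5 repeats, 25 trees). The chosen
subset is the smallest size within one standard error of the best mean
accuracy — a declared default, since no subset-size criterion is printed
for this procedure.

Candidate islands are groups of **all** threshold-passing DMCs sharing an
island id with > 1 unique probe; RFE contributes the per-probe rank
reported alongside. Island selection deliberately does not restrict to the
one-SE subset: with perfectly separating probes that subset collapses to a
single feature and no multi-DMC island could ever be formed. "Manual
inspection" of beta distributions is replaced by two auditable per-island
quantities: a uniform-direction flag and a separation score
(min over members of |mean β_PRAD − mean β_REST|).

## Limit of blank and positivity

The LOB estimator sorts a marker's blank counts ascending and takes the
value at rank ⌈confidence·n⌉ (1-based) — at n = 40 and 95%, the 38th order
statistic. The phrase "highest blank signal at 95% confidence" is also
compatible with the CLSI interpolated position 0.5 + 0.95·n; that variant
is available behind `method="clsi"`, but the rank rule is the default
because interpolating between integer droplet counts is ill-defined. The
estimator is monotone in confidence and permutation-invariant; validation
confirms a LOB when at most 1 − confidence of an independent blank cohort
exceeds it (boundary inclusive).

Positivity is strictly greater than the LOB, in droplet counts (not
concentrations), per assay. A sample is ctDNA-positive when ≥ 1 of the
five markers is positive; all-five, conserved-any (ACTRT2/EVX1/HOXD13) and
specific-any (DOCK2/HAPLN3) counts are derived from the same calls.

Cohort sensitivity uses the truncated, integer-rounded Wald interval
p̂ ± 1.96√(p̂(1−p̂)/n) as the primary method — for 19/20 it gives
(85%, 100%), the convention used in reporting for this assay class. The
exact Clopper–Pearson interval is exposed as `ci_method="clopper-pearson"`
and intentionally does **not** reproduce that bound (it gives ≈ 75% below);
tests pin both so the methods cannot be silently swapped.

The Mann–Whitney test enumerates all group assignments exactly (two-sided:
assignments whose U deviates from n₁n₂/2 at least as much as observed)
when the smaller group has ≤ 8 observations, and otherwise uses the normal
approximation with tie-corrected variance and midranks throughout.

## Synthetic generators: what they emulate and what they do not

* **Beta matrices.** Values are Beta-distributed with (mean, concentration)
  parameterization, respecting the [0,1] support of array beta values.
  Defaults mirror the discovery setting: 553 PRAD vs 828 REST samples and
  9 planted islands; the probe count defaults to 20,000 rather than array
  scale, since background probes beyond a few thousand add nothing to
  planted-truth recovery. Planted islands alternate hyper/hypo direction
  with means (0.9, 0.1)/(0.1, 0.9) and concentration 50. Missingness is
  probe-driven (each *background* probe carries masked cells with
  probability `missing_rate`), which mirrors how detection failures
  cluster by probe on real arrays and keeps the planted ground truth
  discoverable after complete-probe filtering — cell-i.i.d. missingness at
  realistic rates would remove essentially every probe with ≥ 100 samples
  and make ground-truth recovery undefined. The generator does not emulate
  probe cross-reactivity, batch effects, or tissue heterogeneity, so
  passing discovery tests demonstrate the cascade's correctness, not its
  robustness to array artifacts.
* **Blank cohorts.** Markers carry zero template; signal arises only from
  per-assay false-positive rates. Defaults put mean blank counts at
  {0.8, 0.2, 0.3, 0.02, 0.2} droplets/well for ACTRT2/EVX1/HOXD13/DOCK2/
  HAPLN3 — echoing the relative blank levels of the five assays, with
  ACTRT2 noisiest and DOCK2 essentially silent — and were chosen away from
  Poisson-quantile steps where a rank-based LOB at n = 40 is unstable.
  ALB wells default to ~1,100 copies, the blank-plasma ccfDNA median
  (841 copies/ml) mapped through the default volume chain. An optional
  spike reproduces the occasional high-signal blank outlier
  qualitatively; outliers are *included* in LOB ranking unless a QC rule
  removes them.
* **Dilution series.** Expected marker copies start/factor^k per point
  (defaults 7 points, 3-fold, triplicates, 1,500-copy reference
  background); realized copies are Poisson around the expectation, so
  detection at the 8-copy point is stochastic, as in practice.
* **mCRPC cohorts.** Per sample, total template copies (lognormal, median
  ~1,500/well — the mCRPC ccfDNA median through the 2 ml chain) and a
  ctDNA fraction (lognormal, median 10%) are drawn; every marker carries
  fraction × total expected copies, zeroed per marker with 5% dropout to
  emulate heterogeneous marker shedding; ALB carries the total. True
  fractions are recorded for recovery tests. Published LOB values
  (5/1/2/0/1 droplets) are *not* reproducible from these generators — they
  depend on the raw blank cohorts — so tests target the machinery's
  properties, not those integers.

Determinism: every cohort spawns per-well substreams from its seed
(`SeedSequence`), so outputs are byte-identical across reruns and
independent of generation order.

## Problem sizes and numerical choices

Test and acceptance runs use scaled problem sizes chosen as sensible
defaults for simulation studies: 1,000-probe matrices with 50+50 samples
for discovery recovery (20 seeds), 40-blank cohorts with 200 fresh cohorts
for false-positive control, 10⁴ wells per λ for inverse-consistency, and
100 seeded dilution-series runs. Monte-Carlo tolerances are ~99% normal
bands around the design level. Ties in feature importances break by
position (stable argsort); R² is defined as 0 for a zero-variance
response; saturated ratios propagate a flag rather than infinities.

## Known limitations

* Fluorescence amplitudes, droplet rain and cluster calling are out of
  scope; the pipeline consumes per-channel positive/accepted counts.
* The clinical limit of detection (as opposed to the limit of blank) is
  not estimated.
* Absolute copies/ml depend on the declared volume-chain reading (above).
* QC exclusion policy — samples failing a severity=fail rule are excluded
  from cohort statistics, with the exclusion logged — is a package
  decision; no explicit policy is printed for the assay.
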