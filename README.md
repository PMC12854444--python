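# methplex

Analysis pipeline for a methylation-specific **multiplex droplet digital PCR
(ddPCR)** assay that detects circulating tumor DNA (ctDNA) in plasma from
prostate cancer patients. The assay targets five methylation biomarkers in
one reaction — three *prostate-conserved* regions (**ACTRT2**, **EVX1**,
**HOXD13**, methylation patterns shared by normal and cancerous prostate
tissue) and two *PCa-specific* hypermethylated regions (**DOCK2**,
**HAPLN3**) — plus the **ALB** reference gene.

The package is aimed at assay developers and computational biologists who
need the full quantitative chain as reusable, tested code:

1. **Biomarker discovery** — from a 450K-style beta-value matrix (probes ×
   samples, labeled PRAD vs REST): drop probes with missing values, compute
   group mean betas, keep differentially methylated CpGs (DMCs) with
   mean β<sub>PRAD</sub> > 0.75 ∧ mean β<sub>REST</sub> < 0.25 (or the
   reverse), restrict to CpG islands, rank by recursive feature elimination
   under repeated stratified cross-validation, and keep islands containing
   more than one unique DMC.
2. **Quantification** — droplet counts to concentration via the Poisson
   partition model, λ = −ln(1 − k/n) for k positive of n accepted droplets,
   copies/µl = λ/V with droplet volume V; replicate pooling by summed
   counts; marker/ALB ratios (×100 = ctDNA fraction); a volume chain mapping
   concentrations back to copies per ml plasma; dilution-series linearity
   and lowest detected quantity.
3. **QC** — strict acceptance gates (accepted droplets > 15,000; bisulfite
   conversion recovery ratio > 0.2), spike-in and fragmentation reporting,
   and plate-control validation.
4. **Limit of blank & positivity** — per-assay LOB as the
   ceil(0.95·n)-rank order statistic of blank droplet counts, validation on
   an independent blank cohort, positivity when droplets strictly exceed
   the LOB, and cohort sensitivity with a truncated Wald interval
   p̂ ± 1.96·√(p̂(1−p̂)/n) (Clopper–Pearson available as an alternative).
5. **Synthetic data** — generators for every input, with ground truth:
   beta matrices with planted DMC islands, blank cohorts, dilution series
   and mCRPC-like patient cohorts.

## Worked example

`examples/estimate_lob_and_call.py` runs the liquid-biopsy chain end to end
on synthetic data:

```
limit of blank (positive droplets): {'ACTRT2': 2, 'EVX1': 1, 'HOXD13': 1, 'DOCK2': 0, 'HAPLN3': 1}
validation cohort confirms: {'ACTRT2': True, 'EVX1': True, 'HOXD13': True, 'DOCK2': True, 'HAPLN3': True}
mCRPC01: positive=True (4/5 markers), fractions={'ACTRT2': '8.7%', 'EVX1': '7.7%', 'HOXD13': '8.5%', 'DOCK2': '0.0%', 'HAPLN3': '7.7%'}
...
sensitivity 100% (95% CI 100-100%), all-five 15/20, conserved-any 20/20, specific-any 20/20
```

The LOB line is the highest blank signal expected per assay at 95%
confidence; a patient marker scoring strictly more droplets than that is
positive, and the per-marker percentages are marker/ALB concentration
ratios — the estimated ctDNA fraction. The other examples cover discovery
(`discover_islands.py` recovers the three planted CpG islands with their
RFE ranks) and technical sensitivity (`quantify_dilution.py`: per-assay
R² ≈ 1 down a 7-point 3-fold series, lowest fully detected quantity
8 copies).

The same stages are scriptable from the shell:

```bash
methplex simulate --seed 3 --out-dir run/
methplex lob --blanks run/blank_test_wells.csv --validation run/blank_validation_wells.csv --out run/lob.json
methplex call --wells run/patient_wells.csv --lob run/lob.json --out run/calls.tsv
methplex report --calls run/calls.tsv --out run/summary.json
# or everything at once, with a hashed artifact manifest:
methplex run --seed 3 --out-dir run/ --config examples/run_config.yaml
```

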