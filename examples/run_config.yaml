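# Example run configuration for `methplex run --config run_config.yaml`.
# Every key is optional; shown values are the defaults unless noted.
seed: 0
out_dir: methplex_run
total_droplets: 20000          # droplets generated per well
droplet_volume_nl: 0.85        # QX-class droplet volume
lob_confidence: 0.95
lob_method: rank               # or "clsi" (interpolated percentile position)
ci_method: wald                # or "clopper-pearson"
n_blanks: 40                   # blank samples per LOB cohort arm
n_patients: 20                 # simulated mCRPC-like cohort size
marker_dropout: 0.05           # per-marker chance a sample sheds no signal
blank_fp_rates:                # per-droplet false-positive rate per assay
  ACTRT2: 4.0e-5
  EVX1: 1.0e-5
  HOXD13: 1.5e-5
  DOCK2: 1.0e-6
  HAPLN3: 1.0e-5
volume_chain:                  # override any step of the plasma->well chain
  plasma_ml: 4.0
rfe: {}                        # RfeConfig overrides, e.g. {n_folds: 5}
qc_overrides: {}
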