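lattice_length: 5000
n_rep: 100
seed: 1
sample_dt: 5.0
snapshot_times:
- 1800.0
- 2400.0
length_model:
  m: 0.3
  alpha: 2.33352
  beta: 1.15953
rate_sets:
  150mM:
    k_bind: 4.71286e-06
    k_off20: 5.26978e-06
    k_ext: 0.0173129
    k_retr: 0.0163565
  15mM:
    k_bind: 9.49817e-06
    k_off20: 0.000122594
    k_ext: 0.000320295
    k_retr: 0.00022579
protocols:
  pretreat_only:
    reference_time: 1800.0
    phases:
    - duration: 1800.0
      fold: 1.0
      rate_label: 150mM
  fold25_150mM:
    reference_time: 1800.0
    phases:
    - duration: 1800.0
      fold: 1.0
      rate_label: 150mM
    - duration: 600.0
      fold: 25.0
      rate_label: 150mM
  fold10_150mM:
    reference_time: 1800.0
    phases:
    - duration: 1800.0
      fold: 1.0
      rate_label: 150mM
    - duration: 600.0
      fold: 10.0
      rate_label: 150mM
  fold25_15mM:
    reference_time: 1800.0
    phases:
    - duration: 1800.0
      fold: 1.0
      rate_label: 150mM
    - duration: 600.0
      fold: 25.0
      rate_label: 15mM
  fold10_15mM:
    reference_time: 1800.0
    phases:
    - duration: 1800.0
      fold: 1.0
      rate_label: 150mM
    - duration: 600.0
      fold: 10.0
      rate_label: 15mM
observables:
  gap_threshold: 18
  include_terminal: true
  gap_cutoff: 30.0
optics:
  px_size: 100.0
  frame_dt: 5.0
  psf_sigma: 1.5
  signal_per_rpa: 50.0
  background: 10.0
  noise_sd: 2.0
  shot_noise: false
provenance: rate_sets/length_model fitted to data/observations_printed.csv by scripts/calibrate_defaults.py
  (seed=12345, n_rep=8, weighted SSE=1.186, 2026-09-28)
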