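# Demo run: two simulated context sessions (40 neurons) sharing 3 of 6
# ensembles, so the planted matching score is 0.5.
seed: 11
out_dir: scratch/demo_run
simulation:
  mode: pair
  n_neurons: 40
  n_ensembles: 6
  neurons_per_ensemble: 4
  shared_fraction: 0.5
  event_rate: 0.2
factorization:
  n_restarts: 10
  max_iter: 300
  rel_tol: 1.0e-5
  rank_range: [3, 9]
matching:
  threshold_c: 0.6
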