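# Demo configuration for `mtrepair run`: a small end-to-end pipeline on
# synthetic data (bending cycles + rigidity fits + softening test, erfc tip
# fits, damage-trace incorporation rate, lattice-gap detection).
seed: 11
out_dir: demo_run
n_filaments: 2
cycles: 5
replicates: 2
kappa0: 50.0
kappa_decline: 0.9
n_nodes: 41
flow_vy: 100.0
noise_sigma_px: 1.0
fit_origin: true
alpha: 0.05
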