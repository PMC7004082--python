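# Study conditions for the synthetic analysis: four Svalbard-like colonies,
# 12 birds each, 3 incubation trips per bird (SimConfig defaults), 10-min
# fixes. Randomization and bootstrap sizes are scaled for a desk run.
workdir: results/pipeline
seed: 1
simulate: true
sim: {}
buffer_m: 300.0
min_trip_hr: 1.0
hmm_n_states: 3
hmm_n_restarts: 2
hmm_maxiter: 300
fidelity_n_iter: 300
n_boot: 500
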