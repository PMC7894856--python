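# Small end-to-end demo: 1,500 synthetic patients, 8 planted subgroups,
# 5 disjoint risk-stratified sets (4 training + 1 validation).
seed: 7
n_total: 1500
n_subgroups: 8
n_sets: 5
tsne_iterations: 500
exaggeration_duration: 125
momentum_switch: 125
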