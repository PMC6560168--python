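# Compare conventional and t-SNE-guided gating across the 8 general lineages
# of a synthetic discrete-marker cohort.
#   cytomatch run --config examples/general_lineages.yaml --out report/
experiment: general_lineages
template_scale: mini
n_donors: 10
cells_per_donor: 2000     # 20,000 cells total
mean_shift_sd: 0.1
seed: 1
cofactor: 5.0
perplexity: 30.0
n_iter: 1000
theta: 0.5
backend: approximate
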