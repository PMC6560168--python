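# Two-marker mixtures at decreasing discreteness: how marker continuity limits
# population separation in the embedding.
experiment: continuity_study
seed: 11
continuity_n_cells: 5000
perplexity: 30.0
n_iter: 1000
theta: 0.5
backend: approximate
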