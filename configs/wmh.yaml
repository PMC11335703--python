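# Secondary analysis: NVU measures averaged in white matter hyperintensities.
source: synthetic
roi: wmh
cognition_mode: tests13
adjustment: none
n_permutations: 1000
seed: 0
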