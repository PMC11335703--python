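# Robustness: three cognitive-domain compound z-scores instead of 13 tests.
source: synthetic
roi: nawm
cognition_mode: domains3
adjustment: none
n_permutations: 1000
seed: 0
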