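# Primary analysis: NVU function in normal-appearing white matter vs the
# 13-test cognitive battery, unadjusted.
source: synthetic
roi: nawm
cognition_mode: tests13
adjustment: none
n_permutations: 1000
seed: 0
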