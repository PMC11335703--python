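# Robustness: adjustment additionally for relative brain and WMH volume.
source: synthetic
roi: nawm
cognition_mode: tests13
adjustment: age_sex_edu_brain_wmh
n_permutations: 1000
seed: 0
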