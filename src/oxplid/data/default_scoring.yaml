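# Default scoring configuration.
# m/n are the Stein-style weight exponents (intensity^m * mz^n); f_amplify
# scales the decibel specificity ratio so that a 3:1 specific/unspecific
# intensity ratio reaches a score of 100.  Thresholds are package defaults
# and instrument-tunable; they are not literature values.
m: 0.6
n: 3.0
f_amplify: 10.4795
w_frag: {}
ms1_ppm: 10.0
ms2_ppm: 20.0
isotope_depth: 2
min_similarity: 20.0
min_rank: 20.0
min_fingerprint: 10.0
min_specificity: 0.0
min_isotope: 60.0
min_overall: 40.0
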