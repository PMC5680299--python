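# Default CID intensity profile (negative mode), relative intensities on a
# 0..999 scale, keyed by ion type.  These ranks encode the usual negative-mode
# glycerophospholipid pattern (sn-2 carboxylate >= sn-1 carboxylate >
# head-group ions > neutral-loss and modification-specific signals).
# Relative intensities are instrument-dependent: tune them freely — the ion
# inventory (which m/z values are predicted) never changes with this file.
sn2_carboxylate: 999
sn1_carboxylate: 850
head_fragment: 400
head_neutral_loss: 350
precursor_surrogate: 120
sn_neutral_loss_ketene: 250
sn_neutral_loss_acid: 200
water_loss: 150
peroxide_loss: 150
co2_loss: 150
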