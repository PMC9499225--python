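subfamily,genus,species,role,brightness_mean,brightness_n,relative_eye_size
Dolichoderinae,Dorymyrmex,dark congeners (max of 5),dark_reference,,,0.0249
Dolichoderinae,Iridomyrmex,dark congeners (max of 5),dark_reference,,,0.0278
Myrmicinae,Temnothorax,dark congeners (max of 5),dark_reference,,,0.0224
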