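color,nocturnal,variable,diurnal
Pale,9,1,0
Dark,0,13,3
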