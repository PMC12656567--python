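reference,bare_soil,grasses,mixed_forbs
bare_soil,26,24,0
grasses,10,27,17
mixed_forbs,0,13,37
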