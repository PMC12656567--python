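reference,bare_soil,grasses,mixed_forbs
bare_soil,36,10,4
grasses,9,41,0
mixed_forbs,0,1,49
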