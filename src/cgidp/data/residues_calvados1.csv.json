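{
 "name": "CALVADOS1",
 "description": "Residue stickiness/size/charge/mass table for the CALVADOS1 model variant",
 "sha256": "b36d816c2347e8ba2434f95ea962484ed6b9ad7a164c3d7488235659eed028a0"
}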