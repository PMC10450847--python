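{
 "name": "CALVADOS2",
 "description": "Residue stickiness/size/charge/mass table for the CALVADOS2 model variant",
 "sha256": "89be923184373cb1178115484b4884ee5d194a1ff51f593f6aeb7181176de999"
}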