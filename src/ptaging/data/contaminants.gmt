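blood_contaminants	blood-derived contaminant proteins	Hbb-b1	Hbb-b2	Hbb-y	Hbb-bh1	Hbz	Hbb-bh0	Alb
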