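#OTU ID	sampleA	sampleB
asv0001	10	0
asv0002	5	7
asv0003	0	3
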