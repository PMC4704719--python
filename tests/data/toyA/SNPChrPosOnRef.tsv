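1000	1	999
2000	2	4999
5000	3	41
6000	Multi	
7000	NotOn	
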