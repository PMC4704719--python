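4000	2013-01-01	137	137	
3000	2013-01-01	137	137	
5000	2013-01-01	137	137	Re-activation needed
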