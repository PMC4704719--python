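1002	1001	142	0	2013-01-01	2014-01-01	1000
1001	1000	142	0	2013-01-01	2014-01-01	1000
2001	2000	142	0	2013-01-01	2014-01-01	2000
3001	3000	142	0	2013-01-01	2014-01-01	3000
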