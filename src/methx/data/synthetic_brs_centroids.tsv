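gene	BRAF	RAS
SIG01	8.2	3.1
SIG02	2.5	7.9
SIG03	6.7	6.5
SIG04	1.9	5.2
SIG05	9.1	2.4
SIG06	4.3	8.8
SIG07	7.6	1.7
SIG08	3.4	6.9
SIG09	5.8	4.0
SIG10	2.2	9.3
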