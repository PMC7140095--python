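SIG01
SIG02
SIG03
SIG04
SIG05
SIG06
SIG07
SIG08
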