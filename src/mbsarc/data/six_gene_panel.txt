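IMPG2
NPR3
KHDRBS2
RBM24
WIF1
EMX2
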