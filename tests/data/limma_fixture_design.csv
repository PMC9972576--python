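sample_id,intercept,group,cov
s00,1.0,0.0,0.3047
s01,1.0,0.0,-1.04
s02,1.0,0.0,0.7505
s03,1.0,0.0,0.9406
s04,1.0,0.0,-1.951
s05,1.0,0.0,-1.3022
s06,1.0,1.0,0.1278
s07,1.0,1.0,-0.3162
s08,1.0,1.0,-0.0168
s09,1.0,1.0,-0.853
s10,1.0,1.0,0.8794
s11,1.0,1.0,0.7778
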