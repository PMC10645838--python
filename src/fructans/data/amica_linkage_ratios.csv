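sample,t_fruf_ratio,b21_ratio,b26_ratio,di_ratio,glcp_ratio
N1,1.8,2.2,0.3,0.6,1.0
N2,2.3,2.8,0.3,0.8,1.0
N3,2.0,2.1,0.2,0.6,1.0
N4,2.0,2.2,0.3,0.5,1.0
N5,2.0,2.3,0.2,0.5,1.0
N6,2.0,1.8,0.4,0.6,1.0
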