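method_label,P,B,G,A,W,V,v,t,E,q,D,R,r
qPCR,0,0,0.5,0,1,4,0.5,0.3,0,1.8,0.2,3,0
goby_metabarcode,0,0,0.5,0,1,4,0.5,0.3,0,3.5,0.2,3,0
fish_metabarcode,0,6,0.5,0,1,4,0.5,0.3,0,3.5,0.2,8,0
goby_seine,15,0,3,0,4,4,0.5,0.3,3,0,0.2,3,0
fish_seine,15,3,3,0,4,4,0.5,0.3,3,0,0.4,6,0
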