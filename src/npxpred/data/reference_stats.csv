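feature,mean,sd
baseline_das,5.4,1.3
KRT19,3.344,0.596
HAO1,6.231,1.33
CXCL1,4.9,1.295
RARRES2,5.856,0.532
FCRL6,7.164,0.575
REN,6.37,1.479
IL13,4.42,0.776
SPON1,5.224,0.656
MMP1,7.592,0.929
ARNT,4.702,1.188
TNFSF13B,8.228,1.026
PRKCQ,4.083,1.487
TNFRSF10B,2.21,0.821
OSCAR,4.897,0.856
CCL8,3.369,1.431
DPP10,3.224,0.629
GDNF,7.2,0.746
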