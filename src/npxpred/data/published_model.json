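{
  "description": "Published anti-TNF response signature: 17 plasma proteins plus gender and baseline DAS28-ESR, with logistic score mapping p = 1/(1+exp(-(S-t))).",
  "intercept": 3.8,
  "threshold": 0.7136,
  "gender_coding": {"M": 1, "F": 0},
  "features": [
    {"name": "baseline_das", "kind": "clinical", "panel": null, "fi": 0.21, "beta": 2.133},
    {"name": "gender", "kind": "clinical", "panel": null, "fi": 0.17, "beta": 0.116},
    {"name": "KRT19", "kind": "protein", "panel": "IMMUNE", "fi": 0.13, "beta": -2.126},
    {"name": "HAO1", "kind": "protein", "panel": "CVD II", "fi": 0.13, "beta": -2.068},
    {"name": "CXCL1", "kind": "protein", "panel": "CVD II + INFLAM", "fi": 0.1, "beta": 0.421},
    {"name": "RARRES2", "kind": "protein", "panel": "CVD III", "fi": 0.1, "beta": 2.488},
    {"name": "FCRL6", "kind": "protein", "panel": "IMMUNE", "fi": 0.1, "beta": -2.595},
    {"name": "REN", "kind": "protein", "panel": "CVD II", "fi": 0.1, "beta": -0.96},
    {"name": "IL13", "kind": "protein", "panel": "INFLAM", "fi": 0.09, "beta": -0.651},
    {"name": "SPON1", "kind": "protein", "panel": "CVD III", "fi": 0.08, "beta": 2.557},
    {"name": "MMP1", "kind": "protein", "panel": "INFLAM", "fi": 0.08, "beta": -0.83},
    {"name": "ARNT", "kind": "protein", "panel": "IMMUNE", "fi": 0.07, "beta": -0.758},
    {"name": "TNFSF13B", "kind": "protein", "panel": "CVD III", "fi": 0.07, "beta": 1.281},
    {"name": "PRKCQ", "kind": "protein", "panel": "IMMUNE", "fi": 0.07, "beta": 0.744},
    {"name": "TNFRSF10B", "kind": "protein", "panel": "CVD II", "fi": 0.07, "beta": -0.421},
    {"name": "OSCAR", "kind": "protein", "panel": "CVD II", "fi": 0.05, "beta": 2.661},
    {"name": "CCL8", "kind": "protein", "panel": "INFLAM", "fi": 0.05, "beta": -0.243},
    {"name": "DPP10", "kind": "protein", "panel": "IMMUNE", "fi": 0.05, "beta": 2.99},
    {"name": "GDNF", "kind": "protein", "panel": "INFLAM", "fi": 0.05, "beta": -2.574}
  ]
}
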