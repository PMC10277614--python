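{
  "groups": {
    "overall_lymphoproliferations": {"k": 16, "n": 145},
    "luad_regions": {"k": 8, "n": 45},
    "lusc_regions": {"k": 6, "n": 60},
    "fresh_injections": {"k": 6, "n": 68},
    "cryopreserved_injections": {"k": 10, "n": 77}
  },
  "comparisons": [
    ["luad_regions", "lusc_regions"],
    ["fresh_injections", "cryopreserved_injections"]
  ]
}
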