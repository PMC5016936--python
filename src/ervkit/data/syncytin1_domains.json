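{
  "receptor_binding": {
    "start": 100,
    "end": 110,
    "pattern": "SDGGGX2DX2R"
  },
  "su_cwic": {
    "start": 186,
    "end": 189,
    "motif": "CWIC"
  },
  "furin_site": {
    "start": 314,
    "end": 317,
    "motif": "RKNR"
  },
  "fusion_peptide_332": {
    "position": 332,
    "expected": "A"
  },
  "tm_cx6cc": {
    "start": 388,
    "end": 396,
    "pattern": "CX6CC"
  },
  "immunosuppressive": {
    "start": 400,
    "end": 416
  },
  "heptad_433": {
    "position": 433,
    "expected": "R"
  },
  "r_peptide_cleavage": {
    "after": 500,
    "motif": "LQMV",
    "state_in_reference": "deleted"
  }
}
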