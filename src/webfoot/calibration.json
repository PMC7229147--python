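{
  "region": {
    "width": 40,
    "height": 340
  },
  "image": [
    512,
    512
  ],
  "render": {
    "sigma": 1.5
  },
  "series": {
    "moorhen_like": {
      "joint": 189,
      "phalanx": 80
    },
    "grebe_like": {
      "joint": 163,
      "phalanx": 110
    },
    "coot_like": {
      "joint": 107,
      "phalanx": 110
    }
  },
  "targets": {
    "moorhen_like": 5.0,
    "grebe_like": 2.0,
    "coot_like": 0.95
  },
  "pilot": {
    "seeds": [
      1000,
      1001,
      1002,
      1003,
      1004
    ],
    "probe_n": [
      60,
      80,
      100,
      120,
      140,
      160,
      180,
      200,
      220,
      240,
      260,
      280,
      300
    ],
    "mean_S": [
      371588.0,
      668823.9,
      1001746.7,
      1383518.6,
      1915491.8,
      2275139.8,
      3056943.9,
      3663160.4,
      4577826.5,
      5144930.4,
      5959200.3,
      6828029.0,
      7219665.1
    ],
    "achieved_ratio": {
      "moorhen_like": 4.979,
      "grebe_like": 2.006,
      "coot_like": 0.952
    }
  }
}
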