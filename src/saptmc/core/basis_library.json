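{
  "sto-3g": {
    "H": [
      {"l": 0, "exps": [3.42525091, 0.62391373, 0.16885540],
       "coefs": [0.15432897, 0.53532814, 0.44463454]}
    ],
    "He": [
      {"l": 0, "exps": [6.36242139, 1.15892300, 0.31364979],
       "coefs": [0.15432897, 0.53532814, 0.44463454]}
    ]
  },
  "6-31g": {
    "H": [
      {"l": 0, "exps": [18.7311370, 2.8253937, 0.6401217],
       "coefs": [0.03349460, 0.23472695, 0.81375733]},
      {"l": 0, "exps": [0.1612778], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [38.4216340, 5.7780300, 1.2417740],
       "coefs": [0.02376600, 0.15467900, 0.46963000]},
      {"l": 0, "exps": [0.2979640], "coefs": [1.0]}
    ]
  },
  "6-31g**": {
    "H": [
      {"l": 0, "exps": [18.7311370, 2.8253937, 0.6401217],
       "coefs": [0.03349460, 0.23472695, 0.81375733]},
      {"l": 0, "exps": [0.1612778], "coefs": [1.0]},
      {"l": 1, "exps": [1.1], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [38.4216340, 5.7780300, 1.2417740],
       "coefs": [0.02376600, 0.15467900, 0.46963000]},
      {"l": 0, "exps": [0.2979640], "coefs": [1.0]},
      {"l": 1, "exps": [1.1], "coefs": [1.0]}
    ]
  },
  "cc-pvdz": {
    "H": [
      {"l": 0, "exps": [13.0100, 1.9620, 0.4446, 0.1220],
       "coefs": [0.0196850, 0.1379770, 0.4781480, 0.5012400]},
      {"l": 0, "exps": [0.1220], "coefs": [1.0]},
      {"l": 1, "exps": [0.7270], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [38.360, 5.770, 1.240],
       "coefs": [0.0238090, 0.1548910, 0.4699870]},
      {"l": 0, "exps": [0.2976], "coefs": [1.0]},
      {"l": 1, "exps": [1.2750], "coefs": [1.0]}
    ]
  },
  "aug-cc-pvdz": {
    "H": [
      {"l": 0, "exps": [13.0100, 1.9620, 0.4446, 0.1220],
       "coefs": [0.0196850, 0.1379770, 0.4781480, 0.5012400]},
      {"l": 0, "exps": [0.1220], "coefs": [1.0]},
      {"l": 0, "exps": [0.0297400], "coefs": [1.0]},
      {"l": 1, "exps": [0.7270], "coefs": [1.0]},
      {"l": 1, "exps": [0.1410000], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [38.360, 5.770, 1.240],
       "coefs": [0.0238090, 0.1548910, 0.4699870]},
      {"l": 0, "exps": [0.2976], "coefs": [1.0]},
      {"l": 0, "exps": [0.0725500], "coefs": [1.0]},
      {"l": 1, "exps": [1.2750], "coefs": [1.0]},
      {"l": 1, "exps": [0.2473000], "coefs": [1.0]}
    ]
  },
  "cc-pvtz": {
    "H": [
      {"l": 0, "exps": [33.8700, 5.0950, 1.1590, 0.3258, 0.1027],
       "coefs": [0.0060680, 0.0453080, 0.2028220, 0.5039030, 0.3834210]},
      {"l": 0, "exps": [0.3258], "coefs": [1.0]},
      {"l": 0, "exps": [0.1027], "coefs": [1.0]},
      {"l": 1, "exps": [1.4070], "coefs": [1.0]},
      {"l": 1, "exps": [0.3880], "coefs": [1.0]},
      {"l": 2, "exps": [1.0570], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [234.0600, 35.1600, 7.9890, 2.2120],
       "coefs": [0.0025870, 0.0195330, 0.0909980, 0.2720500]},
      {"l": 0, "exps": [0.6669], "coefs": [1.0]},
      {"l": 0, "exps": [0.2089], "coefs": [1.0]},
      {"l": 1, "exps": [3.0440], "coefs": [1.0]},
      {"l": 1, "exps": [0.7580], "coefs": [1.0]},
      {"l": 2, "exps": [1.9650], "coefs": [1.0]}
    ]
  },
  "aug-cc-pvtz": {
    "H": [
      {"l": 0, "exps": [33.8700, 5.0950, 1.1590, 0.3258, 0.1027],
       "coefs": [0.0060680, 0.0453080, 0.2028220, 0.5039030, 0.3834210]},
      {"l": 0, "exps": [0.3258], "coefs": [1.0]},
      {"l": 0, "exps": [0.1027], "coefs": [1.0]},
      {"l": 0, "exps": [0.0252600], "coefs": [1.0]},
      {"l": 1, "exps": [1.4070], "coefs": [1.0]},
      {"l": 1, "exps": [0.3880], "coefs": [1.0]},
      {"l": 1, "exps": [0.1020000], "coefs": [1.0]},
      {"l": 2, "exps": [1.0570], "coefs": [1.0]},
      {"l": 2, "exps": [0.2470000], "coefs": [1.0]}
    ],
    "He": [
      {"l": 0, "exps": [234.0600, 35.1600, 7.9890, 2.2120],
       "coefs": [0.0025870, 0.0195330, 0.0909980, 0.2720500]},
      {"l": 0, "exps": [0.6669], "coefs": [1.0]},
      {"l": 0, "exps": [0.2089], "coefs": [1.0]},
      {"l": 0, "exps": [0.0513800], "coefs": [1.0]},
      {"l": 1, "exps": [3.0440], "coefs": [1.0]},
      {"l": 1, "exps": [0.7580], "coefs": [1.0]},
      {"l": 1, "exps": [0.1993000], "coefs": [1.0]},
      {"l": 2, "exps": [1.9650], "coefs": [1.0]},
      {"l": 2, "exps": [0.4592000], "coefs": [1.0]}
    ]
  }
}
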