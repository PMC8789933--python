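{
 "version": 1,
 "pca": {
  "mu_ff": [
   45.3,
   33.1,
   18.8,
   80.6,
   44.1,
   32.2,
   18.4,
   79.8
  ],
  "sigma_ff": [
   11.8,
   5.8,
   3.6,
   21.7,
   23.1,
   9.1,
   6.5,
   18.9
  ],
  "eigenvectors": [
   [
    0.4309,
    0.3716,
    0.3411,
    0.2385,
    0.3313,
    0.4475,
    0.3517,
    0.2632
   ],
   [
    -0.2169,
    -0.0757,
    -0.0983,
    0.6501,
    0.0487,
    -0.239,
    -0.2191,
    0.1026
   ],
   [
    0.0818,
    0.5303,
    0.5431,
    -0.0157,
    -0.2471,
    -0.2924,
    -0.5142,
    -0.0768
   ],
   [
    -0.2179,
    0.0431,
    0.0444,
    -0.2122,
    0.8958,
    -0.1628,
    -0.265,
    -0.0662
   ],
   [
    0.8062,
    -0.0306,
    -0.4364,
    0.0212,
    0.0977,
    -0.3044,
    -0.2357,
    -0.0207
   ],
   [
    -0.2394,
    0.6778,
    -0.6126,
    0.0986,
    -0.0299,
    0.2633,
    -0.1047,
    -0.1308
   ],
   [
    -0.0499,
    0.2873,
    -0.1001,
    -0.55,
    -0.0699,
    -0.3928,
    0.375,
    0.5506
   ],
   [
    0.0616,
    -0.1735,
    -0.0375,
    -0.4031,
    -0.0944,
    0.5607,
    -0.5353,
    0.4386
   ]
  ],
  "eigenvalues": [
   3.6423,
   1.7643,
   1.5316,
   0.4671,
   0.3226,
   0.1748,
   0.0606,
   0.0368
  ]
 },
 "gmm": {
  "components": [
   {
    "label": "MR",
    "pi": 0.1947,
    "mu": [
     0.7056,
     2.7126,
     1.495
    ],
    "sigma": [
     [
      0.0425,
      -0.0007,
      0.0013
     ],
     [
      -0.0007,
      0.2343,
      -0.0126
     ],
     [
      0.0013,
      -0.0126,
      0.2122
     ]
    ]
   },
   {
    "label": "MS",
    "pi": 0.0827,
    "mu": [
     3.2981,
     -2.6064,
     -3.7382
    ],
    "sigma": [
     [
      0.331,
      -0.0094,
      -0.0122
     ],
     [
      -0.0094,
      0.3906,
      -0.021
     ],
     [
      -0.0122,
      -0.021,
      0.5386
     ]
    ]
   },
   {
    "label": "ASD",
    "pi": 0.113,
    "mu": [
     2.3453,
     -0.3484,
     0.5773
    ],
    "sigma": [
     [
      0.5373,
      -0.0172,
      -0.0039
     ],
     [
      -0.0172,
      0.0608,
      -0.0053
     ],
     [
      -0.0039,
      -0.0053,
      0.1883
     ]
    ]
   },
   {
    "label": "NM",
    "pi": 0.1683,
    "mu": [
     2.7874,
     1.862,
     -0.9829
    ],
    "sigma": [
     [
      0.1403,
      0.0107,
      0.0063
     ],
     [
      0.0107,
      0.2549,
      0.0016
     ],
     [
      0.0063,
      0.0016,
      0.1301
     ]
    ]
   },
   {
    "label": "AS",
    "pi": 0.0783,
    "mu": [
     0.7511,
     0.3199,
     -0.5341
    ],
    "sigma": [
     [
      0.0972,
      0.0077,
      -0.0161
     ],
     [
      0.0077,
      0.0344,
      -0.005
     ],
     [
      -0.0161,
      -0.005,
      0.2634
     ]
    ]
   },
   {
    "label": "AR",
    "pi": 0.2676,
    "mu": [
     -1.2294,
     0.1198,
     0.3222
    ],
    "sigma": [
     [
      0.3301,
      -0.0011,
      0.0025
     ],
     [
      -0.0011,
      0.023,
      0.0005
     ],
     [
      0.0025,
      0.0005,
      0.3255
     ]
    ]
   },
   {
    "label": "VSD",
    "pi": 0.0954,
    "mu": [
     -0.1631,
     -1.1167,
     0.9454
    ],
    "sigma": [
     [
      0.1338,
      0.0048,
      -0.0155
     ],
     [
      0.0048,
      0.1449,
      -0.0095
     ],
     [
      -0.0155,
      -0.0095,
      0.1573
     ]
    ]
   }
  ],
  "beta": [
   0.87,
   0.65,
   0.67,
   0.65,
   0.67,
   0.79,
   0.87
  ],
  "mdc": [
   5.6489,
   3.2831,
   3.4297,
   3.2831,
   3.4297,
   4.5258,
   5.6489
  ]
 }
}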