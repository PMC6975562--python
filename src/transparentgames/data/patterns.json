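{
  "PD": [
    {
      "name": "WSLS",
      "descriptor": "(100c;1***;****), c >= 2/3",
      "tokens": ["1", "0", "0", {"lo": 0.6666666666666666, "hi": 1.0, "lo_open": false, "hi_open": false},
                 "1", "*", "*", "*", "*", "*", "*", "*"]
    },
    {
      "name": "GWSLS",
      "descriptor": "(1abc;1***;****), c >= 2/3, a,b < 2/3, a > 0.1 or b > 0.1",
      "tokens": ["1",
                 {"lo": 0.0, "hi": 0.6666666666666666, "lo_open": false, "hi_open": true},
                 {"lo": 0.0, "hi": 0.6666666666666666, "lo_open": false, "hi_open": true},
                 {"lo": 0.6666666666666666, "hi": 1.0, "lo_open": false, "hi_open": false},
                 "1", "*", "*", "*", "*", "*", "*", "*"],
      "any_gt": [[1, 0.1], [2, 0.1]]
    },
    {
      "name": "GTFT",
      "descriptor": "(1a1c;1***;****), 0.1 < a,c < 0.9",
      "tokens": ["1",
                 {"lo": 0.1, "hi": 0.9, "lo_open": true, "hi_open": true},
                 "1",
                 {"lo": 0.1, "hi": 0.9, "lo_open": true, "hi_open": true},
                 "1", "*", "*", "*", "*", "*", "*", "*"]
    },
    {
      "name": "TFT",
      "descriptor": "(1010;1***;****)",
      "tokens": ["1", "0", "1", "0", "1", "*", "*", "*", "*", "*", "*", "*"]
    },
    {
      "name": "FbF",
      "descriptor": "(101c;1***;****), 0.1 < c < 0.9",
      "tokens": ["1", "0", "1",
                 {"lo": 0.1, "hi": 0.9, "lo_open": true, "hi_open": true},
                 "1", "*", "*", "*", "*", "*", "*", "*"]
    },
    {
      "name": "AllD",
      "descriptor": "(0000;**00;**00)",
      "tokens": ["0", "0", "0", "0", "*", "*", "0", "0", "*", "*", "0", "0"]
    },
    {
      "name": "L-F",
      "descriptor": "(*00c;****;*11d), c < 1/3, d < 2/3",
      "tokens": ["*", "0", "0",
                 {"lo": 0.0, "hi": 0.3333333333333333, "lo_open": false, "hi_open": true},
                 "*", "*", "*", "*",
                 "*", "1", "1",
                 {"lo": 0.0, "hi": 0.6666666666666666, "lo_open": false, "hi_open": true}]
    }
  ],
  "ACG": [
    {
      "name": "Turn-taker",
      "descriptor": "(*01*;*0**;**1*)",
      "tokens": ["*", "0", "1", "*", "*", "0", "*", "*", "*", "*", "1", "*"]
    },
    {
      "name": "Challenger",
      "descriptor": "(11b*;****;*1**), b <= 0.1",
      "tokens": ["1", "1", "0", "*", "*", "*", "*", "*", "*", "1", "*", "*"]
    },
    {
      "name": "Aggressive Challenger",
      "descriptor": "(11b*;****;*1**), 0.1 < b <= 1/3",
      "tokens": ["1", "1",
                 {"lo": 0.1, "hi": 0.3333333333333333, "lo_open": true, "hi_open": false},
                 "*", "*", "*", "*", "*", "*", "1", "*", "*"]
    },
    {
      "name": "Challenging Leader-Follower",
      "descriptor": "(11b*;0c0*;*1**), 1/3 < b <= 0.9, c <= 1/3",
      "tokens": ["1", "1",
                 {"lo": 0.3333333333333333, "hi": 0.9, "lo_open": true, "hi_open": false},
                 "*", "0",
                 {"lo": 0.0, "hi": 0.3333333333333333, "lo_open": false, "hi_open": false},
                 "0", "*", "*", "1", "*", "*"]
    },
    {
      "name": "Leader-Follower",
      "descriptor": "(*11*;*00*;****)",
      "tokens": ["*", "1", "1", "*", "*", "0", "0", "*", "*", "*", "*", "*"]
    }
  ]
}
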