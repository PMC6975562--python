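{
  "_notes": [
    "Strategy pairs used in the published pairwise-invasion maps, transcribed",
    "from caption glyph runs into 12-entry vectors (probability of action A1,",
    "order s1..s12).  Fractional glyphs like '910' mean 9/10 and '13' means 1/3;",
    "0 and 1 stand for the epsilon-substituted 0.001 and 0.999.",
    "For the anti-coordination maps the captions list only s1..s8 and state",
    "that s9..s12 = 1 for every strategy.",
    "Entries marked ambiguous=true have glyph runs whose segmentation is not",
    "unique; the reading used here is recorded and should not be treated as",
    "authoritative."
  ],
  "ipd": {
    "WSLS_fig5": {"s": [1, 0, 0, 0.9, 1, 0, 0, 1, 0, 0, 0, 0],
                  "glyphs": "(100910;1001;0000)", "ambiguous": false},
    "GTFT_fig5": {"s": [1, 0.3333333333333333, 1, 0.3333333333333333,
                         1, 0.3333333333333333, 1, 0.3333333333333333,
                         0, 0, 0, 0],
                  "glyphs": "(113113;113113;0000)", "ambiguous": false},
    "AllC_prudent_fig5": {"s": [1, 1, 1, 1, 1, 1, 1, 1, 0, 0, 0, 0],
                          "glyphs": "(1111;1111;0000)", "ambiguous": false},
    "LF_fig5": {"s": [0.3333333333333333, 0, 0, 0,
                       0.6666666666666666, 0, 0, 0,
                       1, 1, 1, 0.3333333333333333],
                "glyphs": "(13000;23000;11113)", "ambiguous": true},
    "AllD_fig5": {"s": [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
                  "glyphs": "(0000;0000;0000)", "ambiguous": false},
    "treacherous_WSLS_fig5": {"s": [1, 0, 0, 0.9, 0, 0, 0, 0, 0, 0, 0, 0],
                              "glyphs": "(100910;0000;0000)", "ambiguous": false}
  },
  "iacg": {
    "TurnTaker_fig8": {"s": [0.625, 0, 1, 0.625, 0, 0, 0, 0, 1, 1, 1, 1],
                       "glyphs": "(q01q;0000) with q=5/8, s9..s12=1",
                       "ambiguous": false},
    "AggressiveChallenger_fig8": {"s": [1, 1, 0.2, 1,
                                         0.5, 0.5, 0.2, 0.5,
                                         1, 1, 1, 1],
                                  "glyphs": "(11151;12121512)",
                                  "ambiguous": true},
    "Challenger_fig8": {"s": [0.9, 1, 0, 1, 0.5, 0.5, 0, 0.5, 1, 1, 1, 1],
                        "glyphs": "(910101;1212012)", "ambiguous": true},
    "LF_fig8": {"s": [1, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 1],
                "glyphs": "(1111;0000), s9..s12=1", "ambiguous": false}
  }
}
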