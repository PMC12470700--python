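d,contrast_cream,contrast_bosso,entropy_cream,entropy_bosso
0.2,2.02946,2.03651,0.42969,0.42896
0.4,2.04138,2.04412,0.42969,0.43134
0.6,2.04575,2.04710,0.42969,0.43675
0.8,2.04800,2.04862,0.42896,0.43820
1.0,2.04943,2.04949,0.42896,0.43949
1.2,2.05047,2.05000,0.42990,0.44050
1.4,2.05129,2.05027,0.43618,0.44029
1.6,2.05195,2.05484,0.43689,0.44125
1.8,2.05253,2.06230,0.43604,0.44038
2.0,2.05876,2.06868,0.43809,0.44036
2.2,2.06737,2.07416,0.43981,0.44067
2.4,2.07656,2.07888,0.43902,0.44106
2.6,2.08475,2.08298,0.43964,0.44177
2.8,2.09197,2.08656,0.44158,0.44291
3.0,2.09828,2.08970,0.44161,0.44267
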