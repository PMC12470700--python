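d,contrast_cream,contrast_bosso,entropy_cream,entropy_bosso
0.2,2.2069,2.2829,0.17973,0.17973
0.4,2.2870,2.4217,0.17973,0.17974
0.6,2.3713,2.5371,0.17973,0.17980
0.8,2.4441,2.6241,0.17973,0.17992
1.0,2.5078,2.6872,0.17974,0.17976
1.2,2.5622,2.7323,0.17976,0.17974
1.4,2.6089,2.7649,0.17977,0.17977
1.6,2.6494,2.7889,0.17974,0.17982
1.8,2.6846,2.8068,0.17976,0.17974
2.0,2.7151,2.8206,0.17979,0.17980
2.2,2.7413,2.8313,0.17976,0.17974
2.4,2.7637,2.8398,0.17976,0.17976
2.6,2.7827,2.8467,0.17976,0.17977
2.8,2.7988,2.8524,0.17979,0.17979
3.0,2.8124,2.8571,0.17974,0.17980
3.2,2.8239,2.8611,0.17977,0.17982
3.4,2.8337,2.8645,0.17977,0.17979
3.6,2.8420,2.8673,0.17977,0.17976
3.8,2.8492,2.8698,0.17974,0.17977
4.0,2.8553,2.8720,0.17977,0.17977
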