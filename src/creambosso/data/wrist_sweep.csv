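d,contrast_cream,contrast_bosso,entropy_cream,entropy_bosso
0.2,3.4047,3.4604,0.22315,0.22315
0.4,3.4836,3.5701,0.22315,0.22322
0.6,3.5516,3.6115,0.22315,0.22387
0.8,3.6123,3.7001,0.22322,0.22414
1.0,3.6667,3.7387,0.22339,0.22492
1.2,3.7156,3.7667,0.22376,0.22498
1.4,3.7580,3.7874,0.22458,0.22559
1.6,3.7936,3.8030,0.22500,0.22624
1.8,3.8228,3.8150,0.22548,0.22620
2.0,3.8464,3.8244,0.22604,0.22734
2.2,3.8651,3.8318,0.22558,0.22791
2.4,3.8802,3.8377,0.22608,0.22869
2.6,3.8922,3.8451,0.22651,0.22868
2.8,3.9017,3.8533,0.22624,0.22972
3.0,3.9093,3.8604,0.22695,0.23077
3.2,3.9154,3.8665,0.22781,0.23140
3.4,3.9202,3.8718,0.22886,0.23105
3.6,3.9240,3.8764,0.22937,0.23120
3.8,3.9270,3.8804,0.22909,0.23136
4.0,3.9295,3.8840,0.23161,0.23191
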