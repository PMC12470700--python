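image_id,d,cream,bosso
004001A,0.2,5,1
004001A,0.7,5,1
004001A,1.7,1,5
004001A,3.2,,
005002A,0.2,5,1
005002A,3.2,5,1
005002A,5.7,5,1
008001A,0.2,1,5
008001A,0.7,3,3
008001A,2.7,1,5
008001A,3.2,3,3
008001A,5.2,5,1
008004A,4.2,5,3
008004A,5.7,3,3
008007A,0.2,5,1
008007A,3.2,3,3
006006A,1.2,5,1
006006A,3.2,5,1
006006A,5.7,3,3
009005A,0.2,5,1
009005A,3.2,5,1
009005A,5.7,5,1
006002A,0.7,5,1
006002A,3.2,3,3
009001A,0.2,5,1
009001A,0.7,5,1
009001A,1.7,5,1
009001A,3.7,3,3
009001A,5.2,5,1
007001A,0.2,5,1
007001A,2.7,5,1
007001A,5.7,5,1
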