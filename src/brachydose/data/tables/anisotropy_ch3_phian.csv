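0.25,0.5,0.75,1.0,1.5,2.0,2.5,3.0,4.0,5.0,6.0,7.0,8.0,10.0
,,,,0.999,0.999,0.997,0.997,0.997,0.993,0.988,0.994,0.993,0.994
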