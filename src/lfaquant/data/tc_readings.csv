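set_id,quantity_fg,reading_index,tc_ratio
1,100000,1,0.764
1,100000,2,0.782
1,100000,3,0.772
1,100000,4,0.758
1,100000,5,0.762
1,10000,1,0.672
1,10000,2,0.618
1,10000,3,0.502
1,10000,4,0.536
1,10000,5,0.596
1,1000,1,0.434
1,1000,2,0.404
1,1000,3,0.394
1,1000,4,0.452
1,1000,5,0.38
1,100,1,0.21
1,100,2,0.234
1,100,3,0.2
1,100,4,0.18
1,100,5,0.194
1,10,1,0
1,10,2,0
1,10,3,0
1,10,4,0
1,10,5,0
2,100000,1,0.806
2,100000,2,0.807
2,100000,3,0.82
2,100000,4,0.85
2,100000,5,0.836
2,10000,1,0.634
2,10000,2,0.622
2,10000,3,0.674
2,10000,4,0.67
2,10000,5,0.668
2,1000,1,0.456
2,1000,2,0.456
2,1000,3,0.438
2,1000,4,0.472
2,1000,5,0.426
2,100,1,0.246
2,100,2,0.242
2,100,3,0.212
2,100,4,0.226
2,100,5,0.176
2,10,1,0
2,10,2,0
2,10,3,0
2,10,4,0
2,10,5,0
3,100000,1,0.796
3,100000,2,0.828
3,100000,3,0.882
3,100000,4,0.64
3,100000,5,0.798
3,10000,1,0.634
3,10000,2,0.61
3,10000,3,0.608
3,10000,4,0.722
3,10000,5,0.64
3,1000,1,0.426
3,1000,2,0.5
3,1000,3,0.496
3,1000,4,0.416
3,1000,5,0.476
3,100,1,0.238
3,100,2,0.204
3,100,3,0.208
3,100,4,0.194
3,100,5,0.22
3,10,1,0
3,10,2,0
3,10,3,0
3,10,4,0
3,10,5,0
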