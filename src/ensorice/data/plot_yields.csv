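plot,season,ys,yo
1,WS,6.18,6.52
2,WS,5.12,5.00
3,WS,5.61,5.03
4,WS,6.18,5.59
5,WS,6.38,6.40
6,WS,6.01,6.07
7,WS,7.42,7.82
8,WS,6.71,6.65
1,SA,4.30,4.21
2,SA,3.81,3.21
3,SA,5.78,5.42
6,SA,5.87,5.78
1,AW,5.29,5.04
2,AW,5.62,5.69
3,AW,5.45,5.48
4,AW,6.44,5.39
5,AW,6.37,5.87
6,AW,5.08,4.78
7,AW,7.31,7.21
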