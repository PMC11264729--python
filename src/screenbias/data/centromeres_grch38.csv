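chromosome,centromere_bp
1,123400000
2,93900000
3,90900000
4,50000000
5,48800000
6,59800000
7,60100000
8,45200000
9,43000000
10,39800000
11,53400000
12,35500000
13,17700000
14,17200000
15,19000000
16,36800000
17,25100000
18,18500000
19,26200000
20,28100000
21,12000000
22,15000000
X,61000000
Y,10400000
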