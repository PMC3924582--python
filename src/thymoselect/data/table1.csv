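mouse,n1,n2,n3,n4,n8
1,82580000,9300000,18360000,13850000,4510000
2,142190000,19940000,26200000,18730000,7460000
3,89000000,5980000,15980000,11880000,4100000
4,29320000,2090000,5610000,4400000,1210000
5,29320000,2090000,5610000,4400000,1210000
6,51260000,5930000,9010000,6850000,2160000
7,64480000,6810000,11640000,9030000,2610000
8,218940000,15420000,40200000,29460000,10740000
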