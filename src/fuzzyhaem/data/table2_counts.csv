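disease,g1_a1,g1_a2,g1_a3,g1_a4,g1_a5,g2_a1,g2_a2,g2_a3,g2_a4,g2_a5,g3,total
D0,2,4,5,4,12,2,2,3,3,10,4,51
D1,0,1,1,2,5,0,1,2,1,4,3,20
D2,0,0,0,2,10,0,0,0,4,5,2,23
D3,0,0,2,2,6,0,0,1,1,4,2,18
D4,0,0,0,0,1,0,0,0,0,1,0,2
D5,0,1,1,3,13,0,0,1,2,6,2,29
D6,0,0,0,0,1,0,0,0,0,1,0,2
D7,1,2,2,4,6,1,1,1,2,10,1,31
D8,0,0,1,1,2,0,0,1,1,3,7,16
D9,0,0,0,0,2,0,0,0,0,0,0,2
D10,0,1,2,2,3,0,1,1,1,2,1,14
D11,0,0,1,0,1,0,0,1,1,1,0,5
D12,0,0,0,1,1,0,0,1,1,1,0,5
D13,0,0,1,0,1,0,0,0,1,1,0,4
D14,1,1,2,3,5,0,1,2,2,3,2,22
D15,0,0,1,1,2,0,0,0,1,1,1,7
D16,1,2,2,6,6,2,1,3,3,7,4,37
D17,0,0,0,4,4,0,0,0,3,4,8,23
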