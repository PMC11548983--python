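id,gender,age_group,mcv,rdw,hb,pcv,professional_1,professional_2,further,later,system_output
r01,G2,A5,89.6,13.6,12.0,39.5,D0,D0,D0,D0,D0:0.83
r02,G1,A5,83.3,14.4,12.1,40.5,D0,D0,D0,D0,D0:0.60|D17:0.33
r03,G2,A5,78.6,17.7,9.1,35.2,D17,D3-5,D3,D3,D17:0.69|D3:0.68|D4:0.68|D5:0.68|D8:0.32|D12:0.32|D13:0.32|D14:0.32
r04,G2,A5,90.0,13.8,12.9,39.7,D0,D0,D0,D0,D0:0.84
r05,G1,A5,84.3,13.8,12.6,40.8,D0,D0,D17,D17,D0:0.80|D17:0.20
r06,G2,A5,83.4,14.9,13.2,41.1,D0,D0,D0,D0,D0:0.50
r07,G1,A5,84.4,14.0,14.5,42.9,D0,D0,D0,D0,D0:0.84
r08,G1,A5,115.8,17.6,8.4,26.4,D17,D8-9,D9,D9,D8:0.84|D9:0.84|D17:0.50
r09,G1,A5,100.7,14.4,15.2,44.5,D0,D0,D0,D0,D0:0.60
r10,G2,A5,85.8,13.5,11.6,33.3,D0,D17,D0,D0,D1:0.41|D10:0.41|D11:0.41|D17:0.38
r11,G2,A5,70.0,18.3,9.5,31.8,D3,D17,D5,D5,D3:0.84|D4:0.84|D5:0.84|D17:0.84
r12,G2,A5,87.7,15.5,10.8,34.1,D8,D12,D14,D14,D8:0.84|D12:0.84|D13:0.84|D14:0.84|D17:0.50
r13,G2,A5,70.3,18.6,8.9,31.7,D3,D4-5,D5,D5,D3:0.84|D4:0.84|D5:0.84|D17:0.84
r14,G1,A5,86.3,11.9,9.6,25.9,D1,D11,D10,D10,D1:0.84|D10:0.84|D11:0.84|D17:0.50
r15,G2,A5,69.7,17.4,9.8,31.3,D3,D4-5,D5,D5,D3:0.84|D4:0.84|D5:0.84|D17:0.84
r16,G1,A5,73.4,14.5,11.6,36.1,D17,D3,D17,D17,D1:0.48|D2:0.48|D3:0.48|D4:0.48|D5:0.48|D17:0.48
r17,G1,A5,88.0,13.0,7.4,20.5,D1,D17,D11,D11,D1:0.84|D10:0.84|D11:0.84|D17:0.50
r18,G2,A5,78.4,14.9,11.4,33.0,D3,D17,D5,D5,D3:0.59|D4:0.59|D5:0.59|D17:0.59|D8:0.26|D12:0.26|D13:0.26|D14:0.26
r19,G2,A5,59.9,18.2,11.6,37.5,D0,D17,D17,D17,D17:0.39|D3:0.30|D4:0.30|D5:0.30
r20,G1,A5,102.5,14.0,8.9,28.8,D7,D17,D6,D6,D6:0.84|D7:0.84|D17:0.50
r21,G2,A5,75.3,14.0,10.6,32.9,D1,D17,D2,D2,D1:0.84|D2:0.84|D17:0.84
r22,G1,A5,93.0,13.0,18.0,52.0,D0,D17,D17,D17,D17:0.50
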