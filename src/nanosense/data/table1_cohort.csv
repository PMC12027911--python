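sample_id,group,indication,specimen,miR-15b,miR-21,miR-375,miR-141
A1,cancer,lung,serum,ν,ν,ν,ν
A2,cancer,ovarian,serum,ν,ν,ν,ν
A3,cancer,ovarian,serum,ν,ν,ν,ν
A4,cancer,ovarian,serum,ν,ν,ν,ν
A5,cancer,ovarian,serum,ν,ν,ν,ν
No1,cancer,colorectal,serum,ν,ν,ν,ν;ν
No2,cancer,lung,serum,Ν;ν,X,ν;ν,ν;ν
No3,cancer,colorectal,serum,ν,ND,ν,ν;ν;ν
No4,cancer,lung,serum,ν;ν,ν,ν;ν,ν;ν;ν
No6,cancer,lung,serum,ν,ν;ν,X,ν;ν;ν
No7,cancer,colorectal,serum,ν,ν;ν,ν,ν;ν;ν
D1,cancer,prostate,serum,ν,ν,ν,X
D2,cancer,pancreatic,serum,ν,ν,X,ν
D3,cancer,breast,serum,X,ν,ND,ν
D4,cancer,breast,serum,ν,ν,ν,ν
D5,cancer,prostate,serum,X,ν,ν,ND
D6,cancer,prostate,serum,ν,X,ν,ν;ν
D7,cancer,prostate,serum,ν,ν,ν,ν
D8,cancer,pancreatic,serum,ν,ν,ν,ν
D9,cancer,prostate,serum,ν,ν,ν,ν
D10,cancer,breast,serum,ν,ν,X,ν
D11,cancer,pancreatic,serum,ν,ν,X,ν
SQ H6914,healthy,healthy,serum,ν;ν;ν,ν;ν;ν,ν;ν,ν;ν
H6914 2025,healthy,healthy,serum,ν,ν;ν,ν,ND
Healthy1,healthy,healthy,urine,ND,ν;ν,ND,ν;ν
Healthy2,healthy,healthy,urine,ν;ν,ν;ν,X,ν
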