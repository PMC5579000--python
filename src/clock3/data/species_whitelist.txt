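# 208-species inventory of the extended human clock model
MnPo
McPo
MnPt
McPt
MnPth
McPth
MnCo
McCo
MnCt
McCt
MnB
McB
MnCl
McCl
MnRev
McRev
GPo
GPoA
GPoAR1
GPoAR2
GPt
GPtA
GPtAR1
GPtAR2
GPth
GPthA
GPthAR1
GPthAR2
GCo
GCoA
GCoAR1
GCoAR2
GCt
GCtA
GCtAR1
GCtAR2
GRev
GRevA
GRevAR1
GRevAR2
GB
GBRev
Bc
Bn
BGc
BGn
PBc
PBn
Clc
Cln
ClKc
ClKn
PClc
PCln
Revc
Revn
RevGc
RevGn
PRevc
PRevn
x00001
x00011
x00100
x00110
x00200
x00210
x01000
x01001
x01010
x01011
x01200
x01201
x01210
x01211
x02000
x02001
x02010
x02011
x02200
x02201
x02210
x02211
x10000
x10010
x10011
x10100
x10110
x10111
x11000
x11010
x11011
x11100
x11110
x11111
x12000
x12010
x12011
x12100
x12110
x12111
x20000
x20010
x20011
x20100
x20110
x20111
x21000
x21010
x21011
x21100
x21110
x21111
x22000
x22010
x22011
x22100
x22110
x22111
x30000
x30010
x30011
x30100
x30110
x30111
x31000
x31010
x31011
x31100
x31110
x31111
x32000
x32010
x32011
x32100
x32110
x32111
x40000
x40010
x40011
x40100
x40110
x40111
x41000
x41010
x41011
x41100
x41110
x41111
x42000
x42010
x42011
x42100
x42110
x42111
x70000
x70010
x70011
x70100
x70110
x70111
x71000
x71010
x71011
x71100
x71110
x71111
x72000
x72010
x72011
x72100
x72110
x72111
x80000
x80010
x80011
x80100
x80110
x80111
x81000
x81010
x81011
x81100
x81110
x81111
x82000
x82010
x82011
x82100
x82110
x82111
x90000
x90010
x90011
x90100
x90110
x90111
x91000
x91010
x91011
x91100
x91110
x91111
x92000
x92010
x92011
x92100
x92110
x92111
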