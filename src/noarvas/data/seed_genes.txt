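AR
BOLL
BRCA2
DAZL
DMC1
DNAH6
FAM47C
FANCM
MAGEB4
MCM8
MEI1
MEIOB
NPAS2
NR5A1
PIWIL1
RNF212
SOHLH1
SPINK2
STAG3
STX2
SYCE1
SYCP3
TAF4B
TDRD7
TDRD9
TEX11
TEX14
TEX15
WT1
XRCC2
ZMYND15
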