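gene	inheritance_model
AR	XL
BOLL	AR
BRCA2	AD
DAZL	AR
DMC1	AR
DNAH6	AR
FAM47C	XL
FANCM	AR
MAGEB4	XL
MCM8	AR
MEI1	AR
MEIOB	AR
NPAS2	AD
NR5A1	AD
PIWIL1	AD
RNF212	AR
SOHLH1	AD
SPINK2	AR
STAG3	AR
STX2	AR
SYCE1	AR
SYCP3	AD
TAF4B	AR
TDRD7	AR
TDRD9	AR
TEX11	XL
TEX14	AR
TEX15	AR
WT1	AD
XRCC2	AR
ZMYND15	AR
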