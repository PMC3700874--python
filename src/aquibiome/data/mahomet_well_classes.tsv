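well	published_class
Chm94B	HS
Chm96A	HS
Frd94A	HS
Iro95A	HS
Iro96A	HS
Iro98B	HS
Iro98D	HS
Ver94A	HS
Ver94B	HS
Chm94A	LS
Chm95A	LS
Chm95B	LS
Chm95C	LS
Frd94B	LS
Iro98C	LS
Ver94C	LS
Ver94D	LS
AnderN	NS
AnderS	NS
CardiS	NS
Chm95D	NS
Chm98A	NS
PklndE	NS
PklndW	NS
RailRd	NS
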