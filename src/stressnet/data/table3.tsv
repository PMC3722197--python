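gene	description	expression_pattern
dac-1	Ortholog of SKI/SNO/DAC family of proteins	nervous system, hypodermal seam cells
nhr-35	Nuclear hormone receptor	Intestine
C32D5.1	Putative DNA binding domain	Unknown
nhr-45	Nuclear hormone receptor	Unknown
dnj-11	Ortholog of the mammalian ZRF1/MIDA1/MPP11/DNAJC2 family	pharynx, intestine, muscle, nervous system, reproductive system
mxl-2	Max-Like protein X - bHLH-Zip family protein	hypodermis, intestine
R06C1.6	Uncharacterized protein	Unknown
nhr-61	Nuclear hormone receptor	Unknown
zip-4	Putative C/EBP protein, divergent ortologue to human CEBPA-Mutated in acute myeloid leukemia	Weak general expression and higher expression in pharynx and somatic gonad
ztf-22	Zinc finger putative Transcription Factor family	Nervous system, head muscles, intestine
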