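# lncRNAs with prior literature support (colorectal or other cancers),
# matched case-sensitively against gene symbols; everything else among the
# confirmed hits counts as novel.
CCAT1
UCA1
MEG3
LINC00974
TRPM2-AS
RP11-115D19.1
TINCR
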