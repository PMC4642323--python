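# Small subset of named plant cis-element patterns (PLACE-style IUPAC
# consensus motifs) shipped as a test/demo fixture; the full database is an
# external resource supplied by the user as a motif TSV.
DOFCOREZM	AAAG
CACTFTPPCA1	YACT
CAATBOX1	CAAT
GATABOX	GATA
GT1CONSENSUS	GRWAAW
GT1GMSCAM4	GAAAAA
IBOX	GATAAG
MYBCORE	CNGTTR
MYBATRD22	CTAACCA
MYCCONSENSUSAT	CANNTG
WRKY71OS	TGAC
WBOXNTERF3	TGACY
TATABOX3	TATTAAT
TATABOX5	TTATTT
ARR1AT	NGATT
EECCRCAH1	GANTTNC
AGCBOXNPGLB	AGCCGCC
DRE2COREZMRAB17	ACCGAC
CBFHV	RYCGAC
POLLEN1LELAT52	AGAAA
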