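# Restriction enzyme catalogue (REBASE-style public recognition data).
# recognition: IUPAC, written 5'->3' on the recognition strand.
# cut_top: cut position on the recognition strand, bases from the 5' start
#   of the recognition site (may exceed its length for downstream cutters,
#   e.g. GTCTC(1/5) -> cut_top 6).
# cut_bottom: cut position on the complementary strand, measured along the
#   recognition strand from the same 5' start.
name	recognition	cut_top	cut_bottom
AccI	GTMKAC	2	4
AflII	CTTAAG	1	5
AflIII	ACRYGT	1	5
AluI	AGCT	2	2
ApaI	GGGCCC	5	1
ApoI	RAATTY	1	5
AscI	GGCGCGCC	2	6
AvaI	CYCGRG	1	5
BamHI	GGATCC	1	5
BanI	GGYRCC	1	5
BcoDI	GTCTC	6	10
BglII	AGATCT	1	5
BsaHI	GRCGYC	2	4
BsaI	GGTCTC	7	11
DdeI	CTNAG	1	4
DpnII	GATC	0	4
DraI	TTTAAA	3	3
EarI	CTCTTC	7	10
EcoRI	GAATTC	1	5
EcoRV	GATATC	3	3
FokI	GGATG	14	18
HaeIII	GGCC	2	2
HgaI	GACGC	10	15
HhaI	GCGC	3	1
HincII	GTYRAC	3	3
HindIII	AAGCTT	1	5
HinfI	GANTC	1	4
HpaI	GTTAAC	3	3
KpnI	GGTACC	5	1
MlyI	GAGTC	10	10
MspI	CCGG	1	3
NcoI	CCATGG	1	5
NdeI	CATATG	2	4
NheI	GCTAGC	1	5
NotI	GCGGCCGC	2	6
PstI	CTGCAG	5	1
PvuII	CAGCTG	3	3
RsaI	GTAC	2	2
SacI	GAGCTC	5	1
SalI	GTCGAC	1	5
ScaI	AGTACT	3	3
SmaI	CCCGGG	3	3
SpeI	ACTAGT	1	5
SphI	GCATGC	5	1
SspI	AATATT	3	3
StuI	AGGCCT	3	3
StyI	CCWWGG	1	5
TaqI	TCGA	1	3
XbaI	TCTAGA	1	5
XhoI	CTCGAG	1	5
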