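# Published per-line SNP counts from read-mapping against the reference
# genome (homozygous: read rate >= 90%; heterozygous: 40-60%; other:
# unclassifiable).
line	total_snps	homozygous	heterozygous	other
DAH	245860	209526	10643	25691
NB5410	248778	214428	9292	25058
OTO9491	246534	216062	8993	21479
NB-DAH NIL	216455	186869	8673	20913
OTO-DAH NIL	249912	219027	9631	21254
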