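# Published whole-genome resequencing statistics of the five watermelon
# lines, one row per read file (two files per line, paired-end).
# trimmed_over_raw_pct = trimmed length / raw length x 100.
line	n_reads	trimmed_bases	trimmed_over_raw_pct
DAH	42158401	3611517582	71.04
DAH	42158401	3640042936	71.60
NB5410	23469008	1984647849	67.91
NB5410	23469008	1961105072	67.10
OTO9491	22586239	1878291403	59.59
OTO9491	22586239	1727416695	54.80
NB-DAH NIL	20030848	1699640123	67.76
NB-DAH NIL	20030848	1701402747	67.83
OTO-DAH NIL	48997839	4294744894	66.49
OTO-DAH NIL	48997839	4141524303	64.11
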