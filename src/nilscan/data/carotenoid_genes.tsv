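# Carotenoid biosynthesis pathway genes of watermelon (Citrullus lanatus),
# with spans and strands from the public Charleston Gray reference genome
# annotation; listed pathway-upstream to -downstream. 1-based inclusive
# coordinates.
name	enzyme	gene_id	chromosome	start	end	strand
CHYB	beta-carotene hydroxylase	ClCG01G002410	Chr01	2378461	2381614	+
PSY	phytoene synthase	ClCG01G008470	Chr01	10039958	10042905	+
PSY	phytoene synthase	ClCG02G023970	Chr02	38304958	38307096	-
PSY	phytoene synthase	ClCG07G010760	Chr07	26633212	26636449	+
FPS	farnesyl diphosphate synthase	ClCG01G011400	Chr01	18713844	18718625	+
FPS	farnesyl diphosphate synthase	ClCG09G021520	Chr09	38485275	38489544	+
GGPR	geranylgeranyl diphosphate reductase	ClCG02G024280	Chr02	38557070	38558437	+
GGPS	geranylgeranyl diphosphate synthase	ClCG02G003810	Chr02	3851659	3854438	-
ZEP	zeaxanthin epoxidase	ClCG02G012500	Chr02	25999338	26006398	+
ZEP	zeaxanthin epoxidase	ClCG02G024290	Chr02	38562422	38564200	-
LCYB	lycopene beta-cyclase	ClCG04G004090	Chr04	15694446	15696571	+
LCYB	lycopene beta-cyclase	ClCG10G010860	Chr10	24184154	24186135	+
ZDS	zeta-carotene desaturase	ClCG06G009140	Chr06	14827548	14838999	-
PDS	phytoene desaturase	ClCG07G015130	Chr07	31562036	31578907	+
IPI	isopentenyl diphosphate isomerase	ClCG09G003440	Chr09	2959189	3006838	+
CRTISO	carotenoid isomerase	ClCG10G017990	Chr10	32958299	32963939	-
CRTISO	carotenoid isomerase	ClCG10G007140	Chr10	10280425	10285209	-
LCYE	lycopene epsilon-cyclase	ClCG11G001670	Chr11	1815768	1821324	+
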