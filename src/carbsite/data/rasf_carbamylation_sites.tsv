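accession	protein_name	annotated_sequence	site
P02763	alpha-1-acid glycoprotein 1	TYMLAFDVNDEKNWGLSVYADK	K138
P01009	alpha-1-antitrypsin	FNKPFVFLMIEQNTK	K392
P01023	alpha-2-macroglobulin	KDNSVHWERPQK	K1177
P02768	Albumin	AACLLPKLDELRDEGK	K205
P02768	Albumin	LDELRDEGKASSAK	K214
P02768	Albumin	CASLQKFGER	K229
P02768	Albumin	AFKAWAVAR	K236
P02768	Albumin	FPKAEFAEVSK	K249
P02768	Albumin	AEFAEVSKLVTDLTK	K257
P02768	Albumin	ADLAKYICENQDSISSK	K286
P02768	Albumin	LKECCEKPLLEK	K305
P02768	Albumin	NYAEAKDVFLGMFLYEYAR	K347
P02768	Albumin	LAKTYETTLEK	K375
P02768	Albumin	VFDEFKPLVEEPQNLIK	K402
P02768	Albumin	QNCELFEQLGEYKFQNALLVR	K426
P02768	Albumin	VTKCCTESLVNR	K499
P02768	Albumin	EFNAETFTFHADICTLSEKER	K543
P02768	Albumin	KQTALVELVK	K549
P02768	Albumin	EQLKAVMDDFAAFVEK	K569
P02768	Albumin	ADDKETCFAEEGK	K588
P02647	Apolipoprotein A-I	QEMSKDLEEVK	K112
P04114	Apolipoprotein B-100	LLKENLCLNLHK	K4349
P02656	Apolipoprotein C-III	GWVTDGFSSLKDYWSTVK	K071
P05090	Apolipoprotein D	KMTVTDQVNCPK	K176
Q96JP9	Cadherin-related family member 1	TMGSPVQSTLISELKQK	K845
P00450	Ceruloplasmin	MYYSAVDPTKDIFTGLIGPMK	K547
P01024	Complement C3	YFKPGMPFDLMVFVTNPDGSPAYR	K365
P15924	Desmoplakin	KIKNDLNLK	K815
P02675	Fibrinogen beta chain	KGGETSEMYLIQPDSSVKPYR	K247
P02679	Fibrinogen gamma chain	AIQLTYNPDESSKPNMIDAATLK	K101
P02751	Fibronectin	TEIDKPSQMQVTDVQDNSISVK	K1544
P00738	Haptoglobin	KQWINKAVGDK	K077
P00739	Haptoglobin-related protein	AVGDKLPECEAVCGKPK	K083
Q14520	Hyaluronan-binding protein 2	GSRQLLDAKVK	K468
P01857	Immunoglobulin heavy constant gamma 1	FNWYVDGVEVHNAKTKPR	K171
P01857	Immunoglobulin heavy constant gamma 1	VVSVLTVLHQDWLNGKEYK	K200
P01857	Immunoglobulin heavy constant gamma 1	VSNKALPAPIEK	K209
A0A0C4DH39	Immunoglobulin heavy variable 1-58	KPGTSVKVSCK	K038
A0A0B4J1Y9	Immunoglobulin heavy variable 3-72	NSLYLQMNSLKTEDTAVYYCAR	K108
P04430	Immunoglobulin kappa variable 1-16	ASQGISNYLAWFQQKPGK	K061
B9A064	Immunoglobulin lambda-like polypeptide 5	AGVETTKPSKQSNNK	K165
Q27J81	Inverted formin-2	ALDELFEAIEQKQR	K889
P13646	Keratin, type I cytoskeletal 13	LASYLEKVR	K121
Q08722	Leukocyte surface antigen CD47	AVEEPLNAFKESK	K314
Q9ULZ9	Matrix metalloproteinase-17	TYFFKDQLYWR	K447
P08590	Myosin light chain 3	TPKCEMKITYGQCGDVLR	K070
P05155	Plasma protease C1 inhibitor	LYHAFSAMKK	K161
P02787	Serotransferrin	HSTIFENLANKADRDQYELLCLDNTR	K236
P02787	Serotransferrin	KPVDEYKDCHLAQVPSHTVVAR	K258
P02787	Serotransferrin	SDNCEDTPEAGYFAIAVVKK	K452
Q8WZ42	Titin	KYEIVADGR	K13390
P02766	Transthyretin	KAADETWEPFASGK	K055
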