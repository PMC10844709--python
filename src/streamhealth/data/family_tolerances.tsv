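# Family-level pollution tolerance values in [0, 10] after Hilsenhoff (1988),
# version 1. 0 = intolerant (clean water), 10 = highly tolerant. Used only as an
# opt-in fallback when taxon-level tolerances are missing from the trait table.
family	tolerance
Baetidae	4
Baetiscidae	3
Caenidae	7
Ephemerellidae	1
Ephemeridae	4
Heptageniidae	4
Leptophlebiidae	2
Oligoneuriidae	2
Polymitarcyidae	2
Potamanthidae	4
Siphlonuridae	7
Tricorythidae	4
Capniidae	1
Chloroperlidae	1
Leuctridae	0
Nemouridae	2
Perlidae	1
Perlodidae	2
Pteronarcyidae	0
Taeniopterygidae	2
Brachycentridae	1
Glossosomatidae	0
Helicopsychidae	3
Hydropsychidae	4
Hydroptilidae	4
Lepidostomatidae	1
Leptoceridae	4
Limnephilidae	4
Molannidae	6
Odontoceridae	0
Philopotamidae	3
Phryganeidae	4
Polycentropodidae	6
Psychomyiidae	2
Rhyacophilidae	0
Sericostomatidae	3
Aeshnidae	3
Calopterygidae	5
Coenagrionidae	9
Cordulegastridae	3
Corduliidae	5
Gomphidae	1
Lestidae	9
Libellulidae	9
Macromiidae	2
Corydalidae	0
Sialidae	4
Athericidae	2
Blephariceridae	0
Ceratopogonidae	6
Chironomidae	7
Culicidae	8
Empididae	6
Ephydridae	6
Psychodidae	10
Simuliidae	6
Muscidae	6
Syrphidae	10
Tabanidae	6
Tipulidae	3
Dryopidae	5
Elmidae	4
Psephenidae	4
Hydrophilidae	5
Dytiscidae	5
Gyrinidae	4
Haliplidae	5
Gammaridae	6
Hyalellidae	8
Asellidae	8
Oligochaeta	8
Glossiphoniidae	8
Erpobdellidae	9
Physidae	8
Lymnaeidae	6
Planorbidae	7
Sphaeriidae	8
Hydrobiidae	8
Corbiculidae	6
Cambaridae	6
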