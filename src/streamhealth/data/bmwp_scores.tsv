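# BMWP family scores, original UK system (Armitage et al. 1981), version 1.
# Scores are pollution-sensitivity weights in [1, 10]; presence-based, one score
# per family. Override with --scores / read_scores() for regional score sets.
family	bmwp_score
Siphlonuridae	10
Heptageniidae	10
Leptophlebiidae	10
Ephemerellidae	10
Potamanthidae	10
Ephemeridae	10
Taeniopterygidae	10
Leuctridae	10
Capniidae	10
Perlodidae	10
Perlidae	10
Chloroperlidae	10
Aphelocheiridae	10
Phryganeidae	10
Molannidae	10
Beraeidae	10
Odontoceridae	10
Leptoceridae	10
Goeridae	10
Lepidostomatidae	10
Brachycentridae	10
Sericostomatidae	10
Astacidae	8
Lestidae	8
Calopterygidae	8
Gomphidae	8
Cordulegastridae	8
Aeshnidae	8
Corduliidae	8
Libellulidae	8
Psychomyiidae	8
Philopotamidae	8
Caenidae	7
Nemouridae	7
Rhyacophilidae	7
Polycentropodidae	7
Limnephilidae	7
Neritidae	6
Viviparidae	6
Ancylidae	6
Hydroptilidae	6
Unionidae	6
Corophiidae	6
Gammaridae	6
Platycnemididae	6
Coenagrionidae	6
Mesoveliidae	5
Hydrometridae	5
Gerridae	5
Nepidae	5
Naucoridae	5
Notonectidae	5
Pleidae	5
Corixidae	5
Haliplidae	5
Hygrobiidae	5
Dytiscidae	5
Gyrinidae	5
Hydrophilidae	5
Clambidae	5
Scirtidae	5
Dryopidae	5
Elmidae	5
Chrysomelidae	5
Curculionidae	5
Hydropsychidae	5
Tipulidae	5
Simuliidae	5
Planariidae	5
Dendrocoelidae	5
Baetidae	4
Sialidae	4
Piscicolidae	4
Valvatidae	3
Hydrobiidae	3
Lymnaeidae	3
Physidae	3
Planorbidae	3
Sphaeriidae	3
Glossiphoniidae	3
Hirudinidae	3
Erpobdellidae	3
Asellidae	3
Chironomidae	2
Oligochaeta	1
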