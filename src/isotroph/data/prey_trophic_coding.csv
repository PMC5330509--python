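category,rank
plant_material,1
seeds,1
flowers,1
fruit,1
leaves,1
Isoptera,2
Pentatomidae,2
Acrididae,2
Tettigoniidae,2.5
Gryllidae,2.5
Lepidoptera_larvae,2
Lepidoptera_adults,2
Hemiptera_other,2
Cicadidae,2
Fulgoroidea,2
Aphidoidea,2
Coccoidea,2
Psyllidae,2
Thysanoptera,2
Phasmatodea,2
Coleoptera_adults,2.5
Coleoptera_larvae,2.5
Curculionidae,2
Scarabaeidae,2
Tenebrionidae,2.5
Carabidae,3.5
Buprestidae,2
Elateridae,2.5
Chrysomelidae,2
Formicidae,3
Formicidae_alates,3
Hymenoptera_other,2.5
Vespidae,3.5
Apoidea,2
Diptera_adults,2.5
Diptera_larvae,2.5
Blattodea,3
Mantodea,4
Neuroptera_larvae,3.5
Neuroptera_adults,3
Odonata,4
Embioptera,2
Dermaptera,3
Zygentoma,3
Collembola,2
Araneae,3.5
Scorpiones,4
Pseudoscorpiones,3.5
Opiliones,3.5
Acari,3
Chilopoda,3.5
Diplopoda,2
Isopoda,2
Amphipoda,2
Gastropoda,2
Oligochaeta,2
insect_eggs,2.5
insect_larvae_unidentified,2.5
arthropod_fragments,2.5
Squamata_other,5
Scincidae,5
Gekkonidae,5
Vertebrates,5
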