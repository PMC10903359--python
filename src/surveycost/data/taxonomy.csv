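# Reference taxonomy and plausible-species list for the Calleguas Creek /
# Mugu Lagoon estuarine fish community. `plausible` marks membership of the
# locally credible species list compiled from prior surveys and range data;
# taxa with plausible=False (e.g. Fundulus lima) are carried only so that
# implausible metabarcoding hits can be reassigned to their closest plausible
# relative. habitat: estuarine / freshwater / marine; marine taxa are treated
# as exogenous-DNA sources (transported, e.g., in bird feces).
taxon,class,order,family,genus,species,plausible,habitat,previously_reported_refs,sequenced
Ameiurus nebulosus,Actinopteri,Siluriformes,Ictaluridae,Ameiurus,Ameiurus nebulosus,True,freshwater,3,True
Atherinops affinis,Actinopteri,Atheriniformes,Atherinopsidae,Atherinops,Atherinops affinis,True,estuarine,"1,4,5",True
Carassius auratus,Actinopteri,Cypriniformes,Cyprinidae,Carassius,Carassius auratus,True,freshwater,3,True
Citharichthys stigmaeus,Actinopteri,Pleuronectiformes,Paralichthyidae,Citharichthys,Citharichthys stigmaeus,True,estuarine,,True
Clevelandia ios,Actinopteri,Gobiiformes,Gobiidae,Clevelandia,Clevelandia ios,True,estuarine,"1,4,5",True
Cottus asper,Actinopteri,Perciformes,Cottidae,Cottus,Cottus asper,True,freshwater,2,True
Cymatogaster aggregata,Actinopteri,Perciformes,Embiotocidae,Cymatogaster,Cymatogaster aggregata,True,estuarine,8,True
Cyprinus carpio,Actinopteri,Cypriniformes,Cyprinidae,Cyprinus,Cyprinus carpio,True,freshwater,1,True
Eucyclogobius newberryi,Actinopteri,Gobiiformes,Gobiidae,Eucyclogobius,Eucyclogobius newberryi,True,estuarine,1,True
Fundulus lima,Actinopteri,Cyprinodontiformes,Fundulidae,Fundulus,Fundulus lima,False,freshwater,,True
Fundulus parvipinnis,Actinopteri,Cyprinodontiformes,Fundulidae,Fundulus,Fundulus parvipinnis,True,estuarine,1,False
Gambusia affinis,Actinopteri,Cyprinodontiformes,Poeciliidae,Gambusia,Gambusia affinis,True,freshwater,"1,3,5",True
Gila orcuttii,Actinopteri,Cypriniformes,Leuciscidae,Gila,Gila orcuttii,True,freshwater,3,True
Gillichthys mirabilis,Actinopteri,Gobiiformes,Gobiidae,Gillichthys,Gillichthys mirabilis,True,estuarine,"1,5",True
Hypsopsetta guttulata,Actinopteri,Pleuronectiformes,Pleuronectidae,Hypsopsetta,Hypsopsetta guttulata,True,estuarine,,True
Ilypnus gilberti,Actinopteri,Gobiiformes,Gobiidae,Ilypnus,Ilypnus gilberti,True,estuarine,1,False
Lepomis cyanellus,Actinopteri,Perciformes,Centrarchidae,Lepomis,Lepomis cyanellus,True,freshwater,5,True
Leptocottus armatus,Actinopteri,Perciformes,Cottidae,Leptocottus,Leptocottus armatus,True,estuarine,"1,5",True
Micropterus salmoides,Actinopteri,Perciformes,Centrarchidae,Micropterus,Micropterus salmoides,True,freshwater,3,True
Mugil cephalus,Actinopteri,Mugiliformes,Mugilidae,Mugil,Mugil cephalus,True,estuarine,,True
Paralichthys californicus,Actinopteri,Pleuronectiformes,Paralichthyidae,Paralichthys,Paralichthys californicus,True,estuarine,"1,4",True
Quietula y-cauda,Actinopteri,Gobiiformes,Gobiidae,Quietula,Quietula y-cauda,True,estuarine,,False
Syngnathus leptorhynchus,Actinopteri,Syngnathiformes,Syngnathidae,Syngnathus,Syngnathus leptorhynchus,True,estuarine,,True
Engraulis mordax,Actinopteri,Clupeiformes,Engraulidae,Engraulis,Engraulis mordax,True,marine,,True
Leuresthes tenuis,Actinopteri,Atheriniformes,Atherinopsidae,Leuresthes,Leuresthes tenuis,True,marine,,True
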