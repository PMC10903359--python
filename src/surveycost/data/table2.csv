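# Fishes detected at Calleguas Creek by eDNA metabarcoding and seining, with
# previously published accounts. Cell semantics: edna_reads "?" = unknown
# (possibly subsumed in an ambiguous higher-rank ASV; excluded from counts),
# blank = not surveyed/not applicable, 0 = surveyed but not detected.
# seine_count "Visual" = seen during seining but not captured (excluded from
# seine counts). The Fundulus parvipinnis read figure is stored as 110119
# (printed with ambiguous digit grouping). Rows at rank coarser than species
# are ambiguous multi-species ASV assignments.
taxon,previous_references,edna_reads,seine_count,rank,exogenous
Ameiurus nebulosus,3,0,,species,False
Atherinops affinis,"1,4,5",36158,159,species,False
Carassius auratus,3,?,,species,False
Citharichthys stigmaeus,,10,,species,False
Clevelandia ios,"1,4,5",402,42,species,False
Cottus asper,2,?,,species,False
Cymatogaster aggregata,8,752,,species,False
Cyprinus carpio,1,?,,species,False
Eucyclogobius newberryi,1,0,,species,False
Fundulus parvipinnis,1,110119,468,species,False
Gambusia affinis,"1,3,5",304,,species,False
Gila orcuttii,3,0,,species,False
Gillichthys mirabilis,"1,5",384,1,species,False
Hypsopsetta guttulata,,1491,,species,False
Ilypnus gilberti,1,?,,species,False
Lepomis cyanellus,5,0,,species,False
Leptocottus armatus,"1,5",544,3,species,False
Micropterus salmoides,3,29,,species,False
Mugil cephalus,,19013,Visual,species,False
Paralichthys californicus,"1,4",28,6,species,False
Quietula y-cauda,,?,1,species,False
Syngnathus leptorhynchus,,0,2,species,False
Gobiidae (Quietula y-cauda or Ilypnus gilberti),,176,,family,False
Cypriniformes (Carassius auratus or Cyprinus carpio),,312,,order,False
Engraulis mordax,,14,,species,True
Leuresthes tenuis,,192,,species,True
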