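phylum	family	genus	ms_mapped_reads	control_mapped_reads	ms_specimens_increased	pathogen	ecology
Proteobacteria	Nitrosomonadaceae	Nitrosospira	5262	0	2	no	Soil bacterium
Actinobacteria	Coriobacteriaceae	Atopobium	3562	90	2	no	Vaginal anaerobic bacterium
Fusobacteria	Fusobacteriaceae	Fusobacterium	3230	56	2	yes	Oral anaerobic bacterium
Basidiomycota	Ustilaginaceae	Ustilago	1668	6	4	no	Corn smut fungus
Proteobacteria	Pasteurellaceae	Aggregatibacter	1166	214	1	yes	Oral anaerobic bacterium
Gemmatimonadetes	Gemmatimonadaceae	Gemmatimonas	848	30	2	no	Soil bacterium
Bacteroidetes	Bacteroidaceae	Bacteroides	834	2	5	yes	Gut anaerobe
Proteobacteria	Nitrosomonadaceae	Nitrosomonas	700	10	2	no	Soil and water bacterium
Fusobacteria	Leptotrichiaceae	Leptotrichia	650	38	2	yes	Oral anaerobic bacterium
Viruses	Podoviridae	Luz24likevirus	590	0	2	no	Bacteriophage (virus)
Verrucomicrobia	Akkermansiaceae	Akkermansia	508	0	1	no	Gut anaerobic bacterium
Firmicutes	Streptococcaceae	Lactococcus	488	6	4	no	Anaerobic fermenting bacterium
Nitrospirae	Nitrospiraceae	Nitrospira	406	4	2	no	Waterborne bacterium
Bacteroidetes	Flavobacteriaceae	Capnocytophaga	358	12	4	yes	Oral anaerobic bacterium
Actinobacteria	Rubrobacteraceae	Rubrobacter	346	2	5	no	Thermophilic bacterium
Actinobacteria	Bifidobacteriaceae	Bifidobacterium	318	52	1	no	Vaginal and gut anaerobic bacterium
Firmicutes	Leuconostocaceae	Leuconostoc	314	30	1	yes	Anaerobic bacterium
Proteobacteria	Moraxellaceae	Psychrobacter	308	50	1	yes	Aerobic bacterium
Firmicutes	Lactobacillaceae	Pediococcus	270	0	1	no	Anaerobic fermenting bacterium
Proteobacteria	Aeromonadaceae	Aeromonas	246	26	2	yes	Waterborne anaerobic bacterium
Proteobacteria	Moraxellaceae	Moraxella	244	18	2	yes	Oral aerobic bacterium
Actinobacteria	Acidothermaceae	Acidothermus	214	36	3	no	Thermophilic bacterium
Proteobacteria	Hyphomicrobiaceae	Hyphomicrobium	196	10	2	no	Soil and water anaerobic bacterium
Proteobacteria	Ectothiorhodospiraceae	Thioalkalivibrio	162	2	4	no	Extremophile bacterium
Firmicutes	Aerococcaceae	Aerococcus	128	2	4	yes	Facultatitive Anaerobic bacterium
Plantomycetes	Planctomycetaceae	Rhodopirellula	120	22	1	no	Marine bacterium
Proteobacteria	Aeromonadaceae	Tolumonas	112	4	3	no	Anaerobic soil bacterium
Firmicutes	Staphylococcaceae	Macrococcus	102	10	2	no	Skin bacterium
Proteobacteria	Rhodospirillaceae	Azospirillum	100	22	1	no	Plant bacterium
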