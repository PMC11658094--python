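# synthetic deletion-region table (stand-in for the real supplementary
# deletion inventory): category census 4/2/3 and 259.7 kb total match the
# published aggregate; coordinates and gene labels are invented.
region_id	category	start	end	genes
prophage_1	prophage	120000	172400	prophage_1_g0;prophage_1_g1
prophage_2	prophage	522400	569700	prophage_2_g0;prophage_2_g1
prophage_3	prophage	919700	975500	prophage_3_g0;prophage_3_g1
prophage_4	prophage	1325500	1369400	prophage_4_g0;prophage_4_g1
genomic_island_1	genomic_island	1719400	1748000	genomic_island_1_g0;genomic_island_1_g1
genomic_island_2	genomic_island	2098000	2126200	genomic_island_2_g0;genomic_island_2_g1
nuclease_1	nuclease_gene	2476200	2477400	nuclease_1_g0
nuclease_2	nuclease_gene	2827400	2828500	nuclease_2_g0
nuclease_3	nuclease_gene	3178500	3179700	nuclease_3_g0
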