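# Nine blood-expressed 22q13 candidate genes (hg19 printed coordinates).
# hi_score is a DECIPHER-style %HI percentile. Only ADSL and EP300 fall in the
# 0-10% haploinsufficiency band; the percentages stored for them are synthetic
# stand-ins (flag-accurate only), and the other seven are left missing.
# coordinates: 1-based start/end as printed; length = end - start; set operations are half-open [start, end)
symbol	chrom	start	end	hi_score	expressed_in_blood	phenotype_terms
ADSL	chr22	40742504	40762575	8.0	1	
EP300	chr22	41488614	41576081	3.0	1	
TNFRSF13C	chr22	42321036	42322821		1	
NAGA	chr22	42454338	42466846		1	
A4GALT	chr22	43088127	43116876		1	
TRMU	chr22	46731298	46753237		1	
TUBGCP6	chr22	50656118	50683400		1	
SBF1	chr22	50883431	50913464		1	
ARSA	chr22	51061182	51066601		1	
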