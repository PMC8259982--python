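# Five-patient 22q13 terminal-deletion validation panel (hg19 printed coordinates).
# coordinates: 1-based start/end as printed; length = end - start; set operations are half-open [start, end)
patient_id	chrom	start	end	terminal	size_class
PMS 1	chr22	42740931	51244566	1	Large
PMS 2	chr22	42816484	51244566	1	Large
PMS 3	chr22	43800990	51244566	1	Mid
PMS 4	chr22	47731071	51193680	1	Small
PMS 5	chr22	51123491	51224252	1	Small
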