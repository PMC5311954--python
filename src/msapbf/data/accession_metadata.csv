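accession_id,genotype,bf_category,bf_score,clonal_age_decades
Carmel-ArbMarine,Carmel,Medium to High,5,2
Carmel-PFS,Carmel,Medium,4,7
Carmel-Wolfskill,Carmel,High,6,3
Mission-PFS,Mission,No,1,12
Mission-Wolfskill,Mission,High,6,2
Nonpareil-ArbMarine,Nonpareil,Low to Medium,3,9
Nonpareil-Arboretum,Nonpareil,High,6,5
Nonpareil-Esparto1,Nonpareil,Low,2,11
Nonpareil-Esparto2,Nonpareil,High,6,6
Nonpareil-PFS1,Nonpareil,Low to Medium,3,14
Nonpareil-PFS2,Nonpareil,Low to Medium,3,12
Nonpareil-PFS3,Nonpareil,Low to Medium,3,12
Stukey-5-1,Stukey-5,Low,2,2
Stukey-5-2,Stukey-5,High,6,1
Stukey-6-1,Stukey-6,High,6,1
Stukey-6-2,Stukey-6,Low,2,2
Turkmen-Repo1,Turkmen,High,6,1
Turkmen-Repo2,Turkmen,Low,2,2
Winters-Browne,Winters,No,1,4
Winters-PFS,Winters,No,1,5
Winters-R11-1,Winters,High,6,3
Winters-R11-2,Winters,High,6,2
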