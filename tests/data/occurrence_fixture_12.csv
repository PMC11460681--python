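species,lon,lat,date,coord_uncertainty_m,basis_of_record,coord_decimals
Synthetica exemplaris,0.55,0.45,2010-06-01,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,0.45,0.52,2012-07-15,,HUMAN_OBSERVATION,3
Synthetica exemplaris,2.5,2.5,1999-05-05,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,2.5,2.5,2010-06-01,500,FOSSIL_SPECIMEN,2
Synthetica exemplaris,2.5,2.5,2010-06-01,500,UNKNOWN,2
Synthetica exemplaris,2.5,2.5,2010-06-01,1500,HUMAN_OBSERVATION,2
Synthetica exemplaris,2.5,2.5,2010-06-01,,HUMAN_OBSERVATION,1
Synthetica exemplaris,1.5,1.5,2010-06-01,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,3.5,0.5,2010-06-01,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,0.5,3.5,2010-06-01,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,2.5,bad,2010-06-01,500,HUMAN_OBSERVATION,2
Synthetica exemplaris,2.5,2.5,2011-03-03,900,PRESERVED_SPECIMEN,2
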