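marker_id,chromosome,pos_start,pos_end,allele1,allele2
snpVU0007,1,36773526,36773649,T,C
snpVU0011,2,22941996,22942128,T,C
snpVU0018,4,16415787,16415919,A,G
snpVU0019,4,24230438,24230570,T,G
snpVU0001,5,399824,399956,C,G
snpVU0002,5,43326556,43327417,A,G
snpVU0009,6,30511313,30511445,A,C
snpVU0010,6,34246871,34247003,T,G
snpVU0003,7,4914544,4914676,T,C
snpVU0004,7,39680298,39680430,T,C
snpVU0008,8,34271840,34271972,A,G
snpVU0012,9,29111205,29111337,A,C
snpVU0013,9,37010557,37010817,A,T
snpVU0016,10,37900312,37900440,A,G
snpVU0017,10,967432,967564,C,G
snpVU0014,11,34083600,34083732,A,G
snpVU0015,11,12936036,12936168,T,C
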