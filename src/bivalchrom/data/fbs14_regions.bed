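chr10	102979800	102995000	FBS14_01	120
chr10	124898400	124914800	FBS14_02	120
chr11	20175400	20187600	FBS14_03	120
chr11	31817200	31852200	FBS14_04	120
chr1	180197000	180213000	FBS14_05	120
chr17	46616400	46706600	FBS14_06	120
chr17	48039800	48052200	FBS14_07	120
chr2	162268600	162285200	FBS14_08	120
chr2	175189800	175211200	FBS14_09	120
chr2	223152400	223173600	FBS14_10	120
chr4	113429200	113446000	FBS14_11	120
chr4	13523600	13551400	FBS14_12	120
chr6	100050200	100063200	FBS14_13	120
chr13	100617800	100650800	FBS14_14	121
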