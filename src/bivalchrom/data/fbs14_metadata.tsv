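region_id	chrom	start	end	support	genes
FBS14_01	chr10	102979800	102995000	120	LBX1,LBX1-AS1
FBS14_02	chr10	124898400	124914800	120	HMX2,BUB3
FBS14_03	chr11	20175400	20187600	120	DBX1
FBS14_04	chr11	31817200	31852200	120	PAX6,RCN1
FBS14_05	chr1	180197000	180213000	120	LHX4
FBS14_06	chr17	46616400	46706600	120	HOXB2,HOXB-AS1,HOXB-AS2,HOXB4,MIR10A,HOXB5,HOXB8,HOXB9,HOXB6,HOXB7,HOXB-AS4,HOXB3,HOXB-AS3
FBS14_07	chr17	48039800	48052200	120	RNU6-1313P,DLX4
FBS14_08	chr2	162268600	162285200	120	TBR1,AC009487.4,AC009487.5,SLC4A10
FBS14_09	chr2	175189800	175211200	120	SP9,AC018470.1,AC018470.4
FBS14_10	chr2	223152400	223173600	120	CCDC140,PAX3
FBS14_11	chr4	113429200	113446000	120	NEUROG2,RP11-402J6.1
FBS14_12	chr4	13523600	13551400	120	NKX3-2,AC006445.8
FBS14_13	chr6	100050200	100063200	120	PRDM13
FBS14_14	chr13	100617800	100650800	121	ZIC5,ZIC2,LINC00554
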