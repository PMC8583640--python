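group,parameter,unit,median,mean
all,body_weight,kg,25,27
all,food_ingestion,g/day,548,545
all,soil_ingestion,mg/day,41,51
all,water_intake,mL/day,1104,1083
3-6,body_weight,kg,17,19
3-6,food_ingestion,g/day,513,494
3-6,soil_ingestion,mg/day,40,36
3-6,water_intake,mL/day,953,937
7-12,body_weight,kg,32,30
7-12,food_ingestion,g/day,612,595
7-12,soil_ingestion,mg/day,66,62
7-12,water_intake,mL/day,1238,1254
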