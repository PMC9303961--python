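code,group,candidates
8000,other_unspecified,
8001,other_unspecified,
8010,,SMC|SQC|ADC|LAC|other_NSCLC
8012,LAC,
8013,LAC,
8014,LAC,
8031,other_NSCLC,
8032,other_NSCLC,
8033,other_NSCLC,
8041,SMC,
8042,SMC,
8043,SMC,
8044,SMC,
8045,SMC,
8046,,SQC|ADC|LAC|other_NSCLC
8070,SQC,
8071,SQC,
8072,SQC,
8073,SQC,
8074,SQC,
8140,ADC,
8250,ADC,
8251,ADC,
8252,ADC,
8253,ADC,
8255,ADC,
8260,ADC,
8310,ADC,
8480,ADC,
8481,ADC,
8490,ADC,
8560,other_NSCLC,
8800,other_unspecified,
8980,other_unspecified,
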