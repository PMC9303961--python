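sex,period_start,period_end,variable,category,count
male,1993,1999,histology,SMC,1206
male,2000,2004,histology,SMC,988
male,2005,2009,histology,SMC,1060
male,2010,2015,histology,SMC,1339
male,1993,1999,histology,SQC,3001
male,2000,2004,histology,SQC,2273
male,2005,2009,histology,SQC,2536
male,2010,2015,histology,SQC,3140
male,1993,1999,histology,ADC,3403
male,2000,2004,histology,ADC,3103
male,2005,2009,histology,ADC,3732
male,2010,2015,histology,ADC,5106
male,1993,1999,histology,LAC,304
male,2000,2004,histology,LAC,203
male,2005,2009,histology,LAC,194
male,2010,2015,histology,LAC,213
male,1993,1999,histology,other_NSCLC,107
male,2000,2004,histology,other_NSCLC,71
male,2005,2009,histology,other_NSCLC,156
male,2010,2015,histology,other_NSCLC,269
male,1993,1999,histology,other_unspecified,1753
male,2000,2004,histology,other_unspecified,1551
male,2005,2009,histology,other_unspecified,1737
male,2010,2015,histology,other_unspecified,2030
male,1993,1999,histology,8010,1006
male,2000,2004,histology,8010,883
male,2005,2009,histology,8010,949
male,2010,2015,histology,8010,1255
male,1993,1999,histology,8046,27
male,2000,2004,histology,8046,143
male,2005,2009,histology,8046,195
male,2010,2015,histology,8046,180
female,1993,1999,histology,SMC,214
female,2000,2004,histology,SMC,165
female,2005,2009,histology,SMC,201
female,2010,2015,histology,SMC,242
female,1993,1999,histology,SQC,318
female,2000,2004,histology,SQC,250
female,2005,2009,histology,SQC,271
female,2010,2015,histology,SQC,384
female,1993,1999,histology,ADC,2243
female,2000,2004,histology,ADC,2161
female,2005,2009,histology,ADC,2645
female,2010,2015,histology,ADC,3914
female,1993,1999,histology,LAC,72
female,2000,2004,histology,LAC,51
female,2005,2009,histology,LAC,30
female,2010,2015,histology,LAC,29
female,1993,1999,histology,other_NSCLC,35
female,2000,2004,histology,other_NSCLC,32
female,2005,2009,histology,other_NSCLC,38
female,2010,2015,histology,other_NSCLC,83
female,1993,1999,histology,other_unspecified,735
female,2000,2004,histology,other_unspecified,658
female,2005,2009,histology,other_unspecified,735
female,2010,2015,histology,other_unspecified,967
female,1993,1999,histology,8010,514
female,2000,2004,histology,8010,466
female,2005,2009,histology,8010,519
female,2010,2015,histology,8010,626
female,1993,1999,histology,8046,10
female,2000,2004,histology,8046,51
female,2005,2009,histology,8046,59
female,2010,2015,histology,8046,39
male,1993,1999,stage,localized,1766
male,2000,2004,stage,localized,1596
male,2005,2009,stage,localized,2227
male,2010,2015,stage,localized,3678
male,1993,1999,stage,regional,2904
male,2000,2004,stage,regional,2290
male,2005,2009,stage,regional,2840
male,2010,2015,stage,regional,3209
male,1993,1999,stage,distant,2864
male,2000,2004,stage,distant,2359
male,2005,2009,stage,distant,3251
male,2010,2015,stage,distant,4840
male,1993,1999,stage,unknown,1773
male,2000,2004,stage,unknown,1642
male,2005,2009,stage,unknown,1330
male,2010,2015,stage,unknown,1150
male,1993,1999,stage,missing,1500
male,2000,2004,stage,missing,1328
male,2005,2009,stage,missing,911
male,2010,2015,stage,missing,655
female,1993,1999,stage,localized,929
female,2000,2004,stage,localized,979
female,2005,2009,stage,localized,1413
female,2010,2015,stage,localized,2442
female,1993,1999,stage,regional,852
female,2000,2004,stage,regional,730
female,2005,2009,stage,regional,853
female,2010,2015,stage,regional,932
female,1993,1999,stage,distant,1017
female,2000,2004,stage,distant,945
female,2005,2009,stage,distant,1149
female,2010,2015,stage,distant,1955
female,1993,1999,stage,unknown,707
female,2000,2004,stage,unknown,613
female,2005,2009,stage,unknown,568
female,2010,2015,stage,unknown,546
female,1993,1999,stage,missing,636
female,2000,2004,stage,missing,567
female,2005,2009,stage,missing,515
female,2010,2015,stage,missing,409
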