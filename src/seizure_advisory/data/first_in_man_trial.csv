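patient,age,gender,zone,prior_resection,prior_vns,aeds,sf_pt,sf_eeg,data_collection_completed,data_collection_fail_reason,validation_completed,validation_fail_reason,advisory_completed,advisory_fail_reason,ccs,ces_ccs,red_sens_ccs_pct,red_sens_ces_pct,blue_npv_pct,time_high_pct,time_low_pct,lr_ccs,lr_ces,blue_enabled,note
1,26,M,PT,0,0,"CLO, LEV, LAM, VAL",4,14.17,1,,1,,1,,7,13,86,77,100,27,7,14.3,8.0,1,
2,44,M,OT,0,0,"LAC, LAM, OXC, VAL",3,1.52,1,,1,,1,,3,3,100,100,100,31,56,ALL,ALL,1,
3,22,F,PT,1,0,"CAR, LAM, PHE",7,126.65,1,,1,,1,,58,106,56,45,,29,N/E,3.1,2.1,0,NOCT
4,61,M,PT,0,0,"CAR, LAC, LAM, TOP, PHE",5,3.61,1,,1,,0,IFXN,,,,,,,,,,unknown,IFXN (infection; drainage with lead damage; removal)
5,20,F,FT,1,0,"CLO, LAM, OXC, TOP",4,1.32,0,REM,0,,0,,,,,,,,,,,,Migrated (removal)
6,62,M,T,0,0,none,2,6.32,1,,0,FAIL,0,,,,,,,,,,,,
7,52,M,FT,0,0,"CAR, CLO, LEV",,,1,,0,FAIL,0,,,,,,,,,,,,PLAN
8,48,M,FT,1,1,"CAR, LEV",4,42.32,1,,1,,1,,36,86,63,62,,28,N/E,4.4,4.2,0,
9,51,F,OP,0,0,CAR,10,30.37,1,,1,,1,,49,52,18,17,98,11,48,0.8,0.8,1,
10,50,F,FT,1,0,"LEV, OXC, ZON",4,52.28,1,,1,,1,,109,164,54,51,,17,N/E,5.8,5.1,0,
11,53,F,FT,0,0,"LAC, PHE, PER",8,102.50,1,,1,,1,,11,39,56,39,100,15,26,5.1,2.6,1,
12,43,M,T,0,0,"LAM, LAC, PHE, RET",5,0.37,1,,0,FAIL,0,,,,,,,,,,,,PSYCH
13,50,M,T,1,0,"CAR, CLO, LEV, LAC",7,25.74,1,,1,,1,,26,113,57,50,,28,N/E,3.4,5.1,0,Seroma (drainage)
14,49,F,PT,0,0,"CLO, OXC",3,0.00,1,,1,,1,,3,3,100,100,100,3,88,ALL,ALL,1,
15,36,M,T,1,0,"CAR, LAC, PER, TOP",5,6.28,1,,1,,1,,21,24,71,71,,41,N/E,3.6,3.5,0,
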