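label	reactants	products	rate_constant
r1_f	L + R	L_R	4e-07
r1_r	L_R	L + R	0.001
r1_c	L_R	DISC	1e-05
r2_f	flip + DISC	flip_DISC	1e-06
r2_r	flip_DISC	flip + DISC	0.001
r3_f	pC8 + DISC	DISC_pC8	1e-06
r3_r	DISC_pC8	pC8 + DISC	0.001
r3_c	DISC_pC8	C8 + DISC	1.0
r4_f	C8 + BAR	BAR_C8	1e-06
r4_r	BAR_C8	C8 + BAR	0.001
r5_f	pC3 + C8	C8_pC3	8e-08
r5_r	C8_pC3	pC3 + C8	0.001
r5_c	C8_pC3	C3 + C8	1.0
r6_f	pC6 + C3	C3_pC6	1e-07
r6_r	C3_pC6	pC6 + C3	0.001
r6_c	C3_pC6	C6 + C3	1.0
r7_f	pC8 + C6	C6_pC8	3e-08
r7_r	C6_pC8	pC8 + C6	0.001
r7_c	C6_pC8	C8 + C6	1.0
r8_f	XIAP + C3	XIAP_C3	2e-06
r8_r	XIAP_C3	XIAP + C3	0.001
r8_c	XIAP_C3	XIAP + C3_U	0.1
r9_f	PARP + C3	C3_PARP	1e-06
r9_r	C3_PARP	PARP + C3	0.01
r9_c	C3_PARP	cPARP + C3	1.0
r10_f	Bid + C8	C8_Bid	4.5e-08
r10_r	C8_Bid	Bid + C8	0.001
r10_c	C8_Bid	tBid + C8	1.0
r11_f	tBid + Bcl2c	Bcl2c_tBid	9e-07
r11_r	Bcl2c_tBid	tBid + Bcl2c	0.001
r12_f	Bax + tBid	tBid_Bax	1e-07
r12_r	tBid_Bax	Bax + tBid	0.001
r12_c	tBid_Bax	BaxA + tBid	1.0
r13_f	BaxA	BaxM	0.01
r13_r	BaxM	BaxA	0.01
r14_f	BaxM + Bcl2	Bcl2_BaxM	1.4285714285714284e-05
r14_r	Bcl2_BaxM	BaxM + Bcl2	0.001
r15_f	BaxM + BaxM	Bax2	1.4285714285714284e-05
r15_r	Bax2	BaxM + BaxM	0.001
r16_f	Bax2 + Bcl2	Bcl2_Bax2	1.4285714285714284e-05
r16_r	Bcl2_Bax2	Bax2 + Bcl2	0.001
r17_f	Bax2 + Bax2	Bax4	1.4285714285714284e-05
r17_r	Bax4	Bax2 + Bax2	0.001
r18_f	Bax4 + Bcl2	Bcl2_Bax4	1.4285714285714284e-05
r18_r	Bcl2_Bax4	Bax4 + Bcl2	0.001
r19_f	Bax4 + Mito	Bax4_Mito	1.4285714285714284e-05
r19_r	Bax4_Mito	Bax4 + Mito	0.001
r19_c	Bax4_Mito	AMito	1.0
r20_f	AMito + mCytoC	AMito_mCytoC	2.8571428571428567e-05
r20_r	AMito_mCytoC	AMito + mCytoC	0.001
r20_c	AMito_mCytoC	AMito + ACytoC	10.0
r21_f	AMito + mSmac	AMito_mSmac	2.8571428571428567e-05
r21_r	AMito_mSmac	AMito + mSmac	0.001
r21_c	AMito_mSmac	AMito + ASmac	10.0
r22_f	ACytoC	cCytoC	0.01
r22_r	cCytoC	ACytoC	0.01
r23_f	Apaf + cCytoC	Apaf_cCytoC	5e-07
r23_r	Apaf_cCytoC	Apaf + cCytoC	0.001
r23_c	Apaf_cCytoC	ApafA + cCytoC	1.0
r24_f	ApafA + pC9	Apop	5e-08
r24_r	Apop	ApafA + pC9	0.001
r25_f	Apop + pC3	Apop_pC3	5e-09
r25_r	Apop_pC3	Apop + pC3	0.001
r25_c	Apop_pC3	Apop + C3	1.0
r26_f	ASmac	cSmac	0.01
r26_r	cSmac	ASmac	0.01
r27_f	Apop + XIAP	XIAP_Apop	2e-06
r27_r	XIAP_Apop	Apop + XIAP	0.001
r28_f	cSmac + XIAP	XIAP_cSmac	7e-06
r28_r	XIAP_cSmac	cSmac + XIAP	0.001
r29_c		pC3	0.065
r30_c	pC3		3e-05
rCa1_c	Ca + CalpX	Ca + Calp1	5.72
rCa2_c	Ca + Calp1	Ca + Calp2	5.72
rCa3_c	Ca + Calp2	Ca + Calp3	5.72
rCa4_c	Ca + Calp3	Ca + Calp4	5.72
rCa5_c	Ca + Calp4	Ca + Calp5	5.72
rCa6_c	Ca + Calp5	Ca + Calp6	5.72
rCa7_c	Ca + Calp6	Ca + CalpA	57140000.0
rCd1_c	Calp1	CalpX	20.0
rCd2_c	Calp2	Calp1	20.0
rCd3_c	Calp3	Calp2	20.0
rCd4_c	Calp4	Calp3	20.0
rCd5_c	Calp5	Calp4	20.0
rCd6_c	Calp6	Calp5	20.0
rCd7_c	CalpA	Calp6	20.0
rCaB1_c	CalpA + Bcl2c	CalpA + Bcl2c_I	5.7e-08
rCaB2_c	CalpA + Bcl2c_tBid	CalpA + Bcl2c_I + tBid	5.7e-08
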