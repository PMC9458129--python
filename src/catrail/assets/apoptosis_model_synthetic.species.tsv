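name	compartment	initial_amount
L	extracellular	3000.0
R	membrane	200.0
L_R	membrane	0.0
DISC	membrane	0.0
flip	cytosolic	100.0
flip_DISC	membrane	0.0
pC8	cytosolic	20000.0
DISC_pC8	membrane	0.0
C8	cytosolic	0.0
BAR	cytosolic	1000.0
BAR_C8	cytosolic	0.0
pC3	cytosolic	10000.0
C8_pC3	cytosolic	0.0
C3	cytosolic	0.0
pC6	cytosolic	10000.0
C3_pC6	cytosolic	0.0
C6	cytosolic	0.0
C6_pC8	cytosolic	0.0
XIAP	cytosolic	101000.0
XIAP_C3	cytosolic	0.0
C3_U	cytosolic	0.0
PARP	cytosolic	1000000.0
C3_PARP	cytosolic	0.0
cPARP	cytosolic	0.0
Bid	cytosolic	40000.0
C8_Bid	cytosolic	0.0
tBid	cytosolic	0.0
Bcl2c	cytosolic	1980000.0
Bcl2c_tBid	cytosolic	0.0
Bax	cytosolic	100000.0
tBid_Bax	cytosolic	0.0
BaxA	cytosolic	0.0
BaxM	mitochondrial	0.0
Bcl2	mitochondrial	20000.0
Bcl2_BaxM	mitochondrial	0.0
Bax2	mitochondrial	0.0
Bcl2_Bax2	mitochondrial	0.0
Bax4	mitochondrial	0.0
Bcl2_Bax4	mitochondrial	0.0
Mito	mitochondrial	500000.0
Bax4_Mito	mitochondrial	0.0
AMito	mitochondrial	0.0
mCytoC	mitochondrial	500000.0
AMito_mCytoC	mitochondrial	0.0
ACytoC	mitochondrial	0.0
cCytoC	cytosolic	0.0
mSmac	mitochondrial	100000.0
AMito_mSmac	mitochondrial	0.0
ASmac	mitochondrial	0.0
cSmac	cytosolic	0.0
Apaf	cytosolic	50000.0
Apaf_cCytoC	cytosolic	0.0
ApafA	cytosolic	0.0
pC9	cytosolic	100000.0
Apop	cytosolic	0.0
Apop_pC3	cytosolic	0.0
XIAP_Apop	cytosolic	0.0
XIAP_cSmac	cytosolic	0.0
Ca	cytosolic	0.0
CalpX	cytosolic	1000.0
Calp1	cytosolic	0.0
Calp2	cytosolic	0.0
Calp3	cytosolic	0.0
Calp4	cytosolic	0.0
Calp5	cytosolic	0.0
Calp6	cytosolic	0.0
CalpA	cytosolic	0.0
Bcl2c_I	cytosolic	0.0
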