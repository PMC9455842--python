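label	x	y	z
Fp1	-0.308829	0.950477	-0.034899
Fp2	0.308829	0.950477	-0.034899
F7	-0.808524	0.587427	-0.034899
F3	-0.545007	0.673028	0.500000
Fz	0.000000	0.719340	0.694658
F4	0.545007	0.673028	0.500000
F8	0.808524	0.587427	-0.034899
FC5	-0.887888	0.340828	0.309017
FC1	-0.374710	0.374710	0.848048
FC2	0.374710	0.374710	0.848048
FC6	0.887888	0.340828	0.309017
T7	-0.999391	-0.000000	-0.034899
C3	-0.719340	-0.000000	0.694658
Cz	0.000000	0.000000	1.000000
C4	0.719340	0.000000	0.694658
T8	0.999391	0.000000	-0.034899
TP9	-0.861950	-0.280065	-0.422618
CP5	-0.887888	-0.340828	0.309017
CP1	-0.374710	-0.374710	0.848048
CP2	0.374710	-0.374710	0.848048
CP6	0.887888	-0.340828	0.309017
TP10	0.861950	-0.280065	-0.422618
P7	-0.808524	-0.587427	-0.034899
P3	-0.545007	-0.673028	0.500000
Pz	0.000000	-0.719340	0.694658
P4	0.545007	-0.673028	0.500000
P8	0.808524	-0.587427	-0.034899
PO9	-0.532714	-0.733218	-0.422618
O1	-0.308829	-0.950477	-0.034899
Oz	0.000000	-0.999391	-0.034899
O2	0.308829	-0.950477	-0.034899
PO10	0.532714	-0.733218	-0.422618
AF7	-0.587427	0.808524	-0.034899
AF3	-0.406247	0.871199	0.275637
AF4	0.406247	0.871199	0.275637
AF8	0.587427	0.808524	-0.034899
F5	-0.728993	0.633704	0.258819
F1	-0.286965	0.710264	0.642788
F2	0.286965	0.710264	0.642788
F6	0.728993	0.633704	0.258819
FT9	-0.861950	0.280065	-0.422618
FT7	-0.950477	0.308829	-0.034899
FC3	-0.669792	0.434968	0.601815
FC4	0.669792	0.434968	0.601815
FT8	0.950477	0.308829	-0.034899
FT10	0.861950	0.280065	-0.422618
C5	-0.933580	-0.000000	0.358368
C1	-0.390731	-0.000000	0.920505
C2	0.390731	0.000000	0.920505
C6	0.933580	0.000000	0.358368
TP7	-0.950477	-0.308829	-0.034899
CP3	-0.660881	-0.429181	0.615661
CPz	0.000000	-0.390731	0.920505
CP4	0.660881	-0.429181	0.615661
TP8	0.950477	-0.308829	-0.034899
P5	-0.728993	-0.633704	0.258819
P1	-0.286965	-0.710264	0.642788
P2	0.286965	-0.710264	0.642788
P6	0.728993	-0.633704	0.258819
PO7	-0.587427	-0.808524	-0.034899
PO3	-0.406247	-0.871199	0.275637
POz	0.000000	-0.933580	0.358368
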