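# Per-analyte blockade population parameters, one row per mixture component.
# units: "relative" = dimensionless dI/I0, "nA" = absolute blockade depth dI.
# charge_sign: net charge sign of the analyte at pH 7.8; the driving trans
# bias must have the opposite sign.
label	device	weight	mean	sd	units	charge_sign
G	Device #3	1.0	0.129	0.021	nA	-1
GG	Device #3	1.0	0.127	0.016	nA	-1
GGG	Device #3	1.0	0.127	0.021	nA	-1
G	Device #4	1.0	0.229	0.016	relative	-1
A	Device #4	1.0	0.295	0.021	relative	-1
K	Device #5	1.0	0.127	0.028	relative	1
R	Device #5	1.0	0.154	0.023	relative	1
Y	Device #5	1.0	0.106	0.012	relative	-1
p-Y	Device #5	1.0	0.128	0.019	relative	-1
D	Device #6	1.0	0.273	0.035	relative	-1
E	Device #6	1.0	0.252	0.042	relative	-1
H	Device #6	0.5	0.298	0.026	relative	-1
H	Device #6	0.5	0.389	0.068	relative	-1
A	Device #7	1.0	0.058	0.009	relative	-1
V	Device #7	1.0	0.065	0.009	relative	-1
L	Device #8	1.0	0.230	0.076	relative	-1
I	Device #8	1.0	0.284	0.065	relative	-1
M	Device #8	1.0	0.329	0.069	relative	-1
S	Device #9	1.0	0.228	0.033	relative	-1
T	Device #9	1.0	0.327	0.048	relative	-1
N	Device #10	1.0	0.241	0.031	relative	-1
Q	Device #10	1.0	0.268	0.024	relative	-1
N	Device #10 (N/L)	1.0	0.218	0.042	relative	-1
L	Device #10 (N/L)	1.0	0.360	0.078	relative	-1
F	Device #11	1.0	0.212	0.052	relative	-1
Y	Device #11	1.0	0.241	0.054	relative	-1
W	Device #11	1.0	0.284	0.047	relative	-1
G	Device #12	0.5	0.257	0.019	relative	-1
G	Device #12	0.5	0.356	0.077	relative	-1
C	Device #12	1.0	0.326	0.053	relative	-1
P	Device #12	1.0	0.349	0.060	relative	-1
D	Device #13	1.0	0.072	0.006	relative	-1
N	Device #13	1.0	0.083	0.006	relative	-1
E	Device #14	1.0	0.300	0.037	relative	-1
Q	Device #14	1.0	0.314	0.031	relative	-1
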