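label	source	occurrence
A	unit	2
B	unit	6
C	unit	41
C2	unit	57
C3	unit	3
C4	unit	8
D	unit	64
E	unit	2
F	unit	2
H	unit	2
I	unit	1
J	unit	17
K	unit	2
M	unit	4
O	unit	11
P	unit	19
P2	unit	9
P3	unit	8
Q	unit	2
Q2	unit	3
R	unit	4
OC2	cse	1
OC3	cse	1
P1	cse	4
P1D	cse	3
P2D	cse	1
P2F	cse	2
P4O	cse	2
P5A	cse	2
P5DOF	cse	12
PP1	cse	6
PP3A	cse	1
WF1	cse	1
WF1D	cse	1
WFG1	cse	2
WFG2	cse	1
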