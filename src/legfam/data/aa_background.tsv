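# Amino-acid background frequencies (Robinson & Robinson 1991), as used for
# log-odds columns of the profile scorer. Values renormalised to sum to 1.
A	0.07805
R	0.05129
N	0.04487
D	0.05364
C	0.01925
Q	0.04264
E	0.06295
G	0.07377
H	0.02199
I	0.05142
L	0.09019
K	0.05744
M	0.02243
F	0.03856
P	0.05203
S	0.07120
T	0.05841
W	0.01330
Y	0.03216
V	0.06441
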