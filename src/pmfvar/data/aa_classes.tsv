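aa	chemical_class	dipole_class	volume	size_class
A	aliphatic	low	88.6	small
R	basic	high	173.4	large
N	neutral	moderate	114.1	small
D	acidic	high	111.1	small
C	unique	moderate	108.5	small
Q	neutral	moderate	143.8	medium
E	acidic	high	138.4	medium
G	unique	low	60.1	small
H	basic	high	153.2	medium
I	aliphatic	low	166.7	medium
L	aliphatic	low	166.7	medium
K	basic	high	168.6	medium
M	aliphatic	low	162.9	medium
F	aromatic	low	189.9	large
P	unique	low	112.7	small
S	neutral	moderate	89.0	small
T	neutral	moderate	116.1	small
W	aromatic	low	227.8	large
Y	aromatic	moderate	193.6	large
V	aliphatic	low	140.0	medium
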