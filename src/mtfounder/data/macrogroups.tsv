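#prefix	class
M1	North African
U6	North African
M	South Asian
U	West Eurasian
H	West Eurasian
HV	West Eurasian
J	West Eurasian
K	West Eurasian
T	West Eurasian
V	West Eurasian
W	West Eurasian
X	West Eurasian
I	West Eurasian
N	West Eurasian
R	West Eurasian
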