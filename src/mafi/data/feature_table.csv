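ipa,syl,son,cons,cont,delrel,lat,nas,strid,voi,sg,cg,ant,cor,distr,lab,hi,lo,back,round,tense,long
p,-,-,+,-,-,-,-,-,-,-,-,+,-,-,+,-,-,-,-,0,-
b,-,-,+,-,-,-,-,-,+,-,-,+,-,-,+,-,-,-,-,0,-
t,-,-,+,-,-,-,-,-,-,-,-,+,+,-,-,-,-,-,-,0,-
d,-,-,+,-,-,-,-,-,+,-,-,+,+,-,-,-,-,-,-,0,-
k,-,-,+,-,-,-,-,-,-,-,-,-,-,-,-,+,-,+,-,0,-
g,-,-,+,-,-,-,-,-,+,-,-,-,-,-,-,+,-,+,-,0,-
ɡ,-,-,+,-,-,-,-,-,+,-,-,-,-,-,-,+,-,+,-,0,-
m,-,+,+,-,-,-,+,-,+,-,-,+,-,-,+,-,-,-,-,0,-
n,-,+,+,-,-,-,+,-,+,-,-,+,+,-,-,-,-,-,-,0,-
ŋ,-,+,+,-,-,-,+,-,+,-,-,-,-,-,-,+,-,+,-,0,-
f,-,-,+,+,-,-,-,+,-,-,-,+,-,-,+,-,-,-,-,0,-
v,-,-,+,+,-,-,-,+,+,-,-,+,-,-,+,-,-,-,-,0,-
θ,-,-,+,+,-,-,-,-,-,-,-,+,+,+,-,-,-,-,-,0,-
ð,-,-,+,+,-,-,-,-,+,-,-,+,+,+,-,-,-,-,-,0,-
s,-,-,+,+,-,-,-,+,-,-,-,+,+,-,-,-,-,-,-,0,-
z,-,-,+,+,-,-,-,+,+,-,-,+,+,-,-,-,-,-,-,0,-
ʃ,-,-,+,+,-,-,-,+,-,-,-,-,+,+,-,-,-,-,-,0,-
ʒ,-,-,+,+,-,-,-,+,+,-,-,-,+,+,-,-,-,-,-,0,-
h,-,-,-,+,-,-,-,-,-,+,-,0,0,0,-,-,-,-,-,0,-
ʔ,-,-,-,-,-,-,-,-,-,-,+,0,0,0,-,-,-,-,-,0,-
tʃ,-,-,+,-,+,-,-,+,-,-,-,-,+,+,-,-,-,-,-,0,-
dʒ,-,-,+,-,+,-,-,+,+,-,-,-,+,+,-,-,-,-,-,0,-
l,-,+,+,+,-,+,-,-,+,-,-,+,+,-,-,-,-,-,-,0,-
r,-,+,+,+,-,-,-,-,+,-,-,+,+,-,-,-,-,-,-,0,-
ɹ,-,+,+,+,-,-,-,-,+,-,-,-,+,+,-,-,-,-,-,0,-
j,-,+,-,+,-,-,-,-,+,-,-,-,-,-,-,+,-,-,-,+,-
w,-,+,-,+,-,-,-,-,+,-,-,-,-,-,+,+,-,+,+,+,-
i,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,+,-,-,-,+,-
ɪ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,+,-,-,-,-,-
e,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,-,-,+,-
ɛ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,-,-,-,-
æ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,+,-,-,-,-
a,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,+,-,-,+,-
ə,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,0,-,-,-
ɜ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,0,-,+,-
ʌ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,+,-,-,-
ɑ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,+,+,-,+,-
ɒ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,-,+,+,+,-,-
ɔ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,-,-,+,+,-,-
o,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,-,-,+,+,+,-
ʊ,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,+,-,+,+,-,-
u,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,+,-,+,+,+,-
iː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,+,-,-,-,+,+
eː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,-,-,+,+
ɜː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,-,0,-,+,+
ɑː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,-,-,+,+,-,+,+
ɔː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,-,-,+,+,-,+
oː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,-,-,+,+,+,+
uː,+,+,-,+,-,-,-,-,+,-,-,0,0,0,+,+,-,+,+,+,+
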