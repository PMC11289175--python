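feature,weight
syl,1
son,1
cons,1
cont,0.5
delrel,0.25
lat,0.25
nas,0.25
strid,0.125
voi,0.125
sg,0.125
cg,0.125
ant,0.25
cor,0.125
distr,0.125
lab,0.25
hi,0.25
lo,0.25
back,0.25
round,0.25
tense,0.25
long,0.05
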