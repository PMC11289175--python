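viseme,phoneme,features
f,f,lower_lip_tuck
f,v,lower_lip_tuck
ch,ʃ,protrusion
ch,tʃ,protrusion
ch,dʒ,protrusion
w,w,protrusion;lip_rounding
p,b,labial_closure
p,p,labial_closure
p,m,labial_closure
j,j,lip_rounding
r,r,lip_rounding
r,ɹ,lip_rounding
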