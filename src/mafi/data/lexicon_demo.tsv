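bat	bæt
pat	pæt
cat	kæt
mat	mæt
rat	ræt
hat	hæt
moon	muːn
boot	buːt
food	fuːd
wash	wɒʃ
watch	wɒtʃ
chin	tʃɪn
ship	ʃɪp
sheep	ʃiːp
fish	fɪʃ
five	faɪv
love	lʌv
leaf	liːf
van	væn
voice	vɔɪs
red	red
ring	rɪŋ
web	web
wet	wet
yes	jes
yet	jet
you	juː
girl	ɡɜːl
go	ɡəʊ
dog	dɒɡ
duck	dʌk
king	kɪŋ
keep	kiːp
gate	ɡeɪt
thin	θɪn
this	ðɪs
sun	sʌn
zoo	zuː
measure	meʒə
jam	dʒæm
judge	dʒʌdʒ
lamp	læmp
nose	nəʊz
mouse	maʊs
mouth	maʊθ
tooth	tuːθ
thumb	θʌm
bird	bɜːd
ball	bɔːl
board	bɔːd
book	bʊk
put	pʊt
cup	kʌp
car	kɑː
park	pɑːk
farm	fɑːm
arm	ɑːm
need	niːd
needle	niːdəl
gorilla	ɡərɪlə
oxygen	ɒksɪdʒən
mug	mʌɡ
leek	liːk
change	tʃeɪndʒ
remove	rɪmuːv
officer	ɒfɪsə
mouthwash	maʊθwɒʃ
thermometer	θəmɒmɪtə
leather	leðə
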