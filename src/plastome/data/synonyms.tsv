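# Raw gene/product names mapped to canonical plastid gene symbols.
# Built by hand from common depositor spellings in red-algal plastid
# records; matched case-insensitively with whitespace collapsed.
heme oxygenase	pbsA
heme oxygenase 1	pbsA
phycobilin synthesis protein	pbsA
hemeoxygenase	pbsA
ho1	pbsA
hmox	pbsA
glutaredoxin	grx
grx1	grx
hypothetical chloroplast open reading frame 34	ycf34
hypothetical chloroplast open reading frame 35	ycf35
hypothetical chloroplast open reading frame 36	ycf36
hypothetical chloroplast open reading frame 37	ycf37
hypothetical chloroplast open reading frame 46	ycf46
hypothetical chloroplast open reading frame 91	ycf91
ycf46 protein	ycf46
photosystem ii protein d1	psbA
photosystem ii protein d2	psbD
ribulose-1,5-bisphosphate carboxylase/oxygenase large subunit	rbcL
ribulose 1,5-bisphosphate carboxylase large subunit	rbcL
ribulose-1,5-bisphosphate carboxylase/oxygenase small subunit	rbcS
rubisco large subunit	rbcL
elongation factor tu	tufA
cell division protein ftsh	ftsH
atp synthase cf1 alpha subunit	atpA
atp synthase cf1 beta subunit	atpB
cytochrome f	petA
cytochrome b6	petB
photosystem i p700 chlorophyll a apoprotein a1	psaA
photosystem i p700 chlorophyll a apoprotein a2	psaB
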