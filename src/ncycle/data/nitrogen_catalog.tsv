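protein	gene	ko	pathways
NarGHI/NxrAB	narG, narZ, nxrA	K00370	DNR;denitrification;nitrification
NarGHI/NxrAB	narH, narY, nxrB	K00371	DNR;denitrification;nitrification
NarGHI/NxrAB	narI, narV	K00374	DNR;denitrification;nitrification
NapAB	napA	K02567	DNR;denitrification
NapAB	napB	K02568	DNR;denitrification
NarB	narB	K00367	ANR
NR	NR	K10534	ANR
NasAB	nasA	K00372	ANR
NasAB	nasB	K00360	ANR
NirBD	nirB	K00362	ANR;DNR
NirBD	nirD	K00363	ANR;DNR
NrfAH	nrfA	K03385	DNR
NrfAH	nrfH	K15876	DNR
NIT-6	NIT-6	K17877	ANR
NirA	nirA	K00366	ANR
NirK	nirK	K00368	denitrification;anammox
NirS	nirS	K15864	denitrification;anammox
NorBC	norB	K04561	denitrification
NorBC	norC	K02305	denitrification
NosZ	nosZ	K00376	denitrification
NifDKH	nifD	K02586	nitrogen fixation
NifDKH	nifK	K02591	nitrogen fixation
NifDKH	nifH	K02588	nitrogen fixation
AnfG	anfG	K00531	nitrogen fixation
VnfDKGH	vnfD	K22896	nitrogen fixation
VnfDKGH	vnfK	K22897	nitrogen fixation
VnfDKGH	vnfG	K22898	nitrogen fixation
VnfDKGH	vnfH	K22899	nitrogen fixation
AmoCAB/MMO	pmoA-amoA	K10944	nitrification
AmoCAB/MMO	pmoB-amoB	K10945	nitrification
AmoCAB/MMO	pmoC-amoC	K10946	nitrification
Hao	hao	K10535	nitrification
Hzs	hzsC	K20932	anammox
Hzs	hzsB	K20933	anammox
Hzs	hzsA	K20934	anammox
Hdh	hdh	K20935	anammox
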