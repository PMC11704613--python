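metabolite_id	name	formula	monoisotopic_mass
glc__D	D-glucose	C6H12O6	180.06339
g6p	D-glucose 6-phosphate	C6H13O9P	260.02972
f6p	D-fructose 6-phosphate	C6H13O9P	260.02972
fdp	D-fructose 1,6-bisphosphate	C6H14O12P2	339.99605
dhap	dihydroxyacetone phosphate	C3H7O6P	169.99802
g3p	glyceraldehyde 3-phosphate	C3H7O6P	169.99802
3pg	3-phospho-D-glycerate	C3H7O7P	185.99294
pep	phosphoenolpyruvate	C3H5O6P	167.98237
pyr	pyruvate	C3H4O3	88.01604
cit	citrate	C6H8O7	192.02700
icit	isocitrate	C6H8O7	192.02700
akg	2-oxoglutarate	C5H6O5	146.02152
succ	succinate	C4H6O4	118.02661
fum	fumarate	C4H4O4	116.01096
mal__L	L-malate	C4H6O5	134.02152
oaa	oxaloacetate	C4H4O5	132.00587
accoa	acetyl-CoA	C23H38N7O17P3S	809.12577
coa	coenzyme A	C21H36N7O16P3S	767.11521
atp	ATP	C10H16N5O13P3	506.99575
adp	ADP	C10H15N5O10P2	427.02941
amp	AMP	C10H14N5O7P	347.06308
nad	NAD+	C21H27N7O14P2	663.10912
nadh	NADH	C21H29N7O14P2	665.12477
nadp	NADP+	C21H28N7O17P3	743.07545
nadph	NADPH	C21H30N7O17P3	745.09110
glu__L	L-glutamate	C5H9NO4	147.05316
gln__L	L-glutamine	C5H10N2O3	146.06914
asp__L	L-aspartate	C4H7NO4	133.03751
ala__L	L-alanine	C3H7NO2	89.04768
ser__L	L-serine	C3H7NO3	105.04259
thr__L	L-threonine	C4H9NO3	119.05824
lys__L	L-lysine	C6H14N2O2	146.10553
his__L	L-histidine	C6H9N3O2	155.06948
leu__L	L-leucine	C6H13NO2	131.09463
ile__L	L-isoleucine	C6H13NO2	131.09463
phe__L	L-phenylalanine	C9H11NO2	165.07898
trp__L	L-tryptophan	C11H12N2O2	204.08988
met__L	L-methionine	C5H11NO2S	149.05105
prpp	5-phospho-alpha-D-ribose 1-diphosphate	C5H13O14P3	389.95181
histd	L-histidinol	C6H11N3O	141.09021
hisp	L-histidinol phosphate	C6H12N3O4P	221.05654
eig3p	D-erythro-imidazolylglycerol 3-phosphate	C6H11N3O6P	252.03855
phom	O-phospho-L-homoserine	C4H10NO6P	199.02457
sl26da	N-succinyl-L-2,6-diaminoheptanedioate	C11H18N2O7	290.11140
3c3hmp	(2R,3S)-3-isopropylmalate	C7H12O5	176.06847
dxyl5p	1-deoxy-D-xylulose 5-phosphate	C5H11O7P	214.02424
2me4p	2-C-methyl-D-erythritol 4-phosphate	C5H13O7P	216.03989
26dap__M	meso-2,6-diaminoheptanedioate	C7H14N2O4	190.09536
asp4p	L-aspartyl-4-phosphate	C4H8NO7P	213.00384
hom__L	L-homoserine	C4H9NO3	119.05824
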