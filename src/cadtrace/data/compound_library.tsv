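# Synthetic curation of a pathway-annotated compound library for accurate-mass
# annotation: the cadaverine/putrescine catabolic neighbourhood, lysine
# degradation, phenylpropanoid biosynthesis and common plant metabolites.
# Pathway ids follow the KEGG map numbering for the corresponding pathways.
compound_id	name	formula	pathway_ids
cadaverine	cadaverine	C5H14N2	map00310;map00960;map01064
5-aminopentanal	5-aminopentanal	C5H11NO	map00960;map01064
5-aminopentanoate	5-aminopentanoate	C5H11NO2	map00310
delta-valerolactam	delta-valerolactam	C5H9NO	map00960
n-acetylcadaverine	N-acetylcadaverine	C7H16N2O	map00330
p-coumaroylcadaverine	p-coumaroylcadaverine	C14H20N2O2	map00940
delta1-piperideine	delta-1-piperideine	C5H9N	map00960;map01064
pelletierine	(R)-pelletierine	C8H15NO	map00960;map01064
slaframine	slaframine	C10H18N2O2	map01064
anabasine	anabasine	C10H14N2	map00960;map01064
3-quinuclidinol	3-quinuclidinol	C7H13NO	map01064
lentiginosine	lentiginosine	C8H15NO2	map01064
putrescine	putrescine	C4H12N2	map00330;map01064
spermidine	spermidine	C7H19N3	map00330
spermine	spermine	C10H26N4	map00330
agmatine	agmatine	C5H14N4	map00330
n-carbamoylputrescine	N-carbamoylputrescine	C5H13N3O	map00330
n-acetylputrescine	N-acetylputrescine	C6H14N2O	map00330
gamma-glutamylputrescine	gamma-L-glutamylputrescine	C9H19N3O3	map00330
p-coumaroylputrescine	p-coumaroylputrescine	C13H18N2O2	map00330;map00940
4-aminobutanal	4-aminobutanal	C4H9NO	map00330
gaba	gamma-aminobutyric acid	C4H9NO2	map00330
l-lysine	L-lysine	C6H14N2O2	map00310;map01064
l-saccharopine	L-saccharopine	C11H20N2O6	map00310
l-pipecolate	L-pipecolate	C6H11NO2	map00310
glutarate	glutarate	C5H8O4	map00310
l-ornithine	L-ornithine	C5H12N2O2	map00330;map01064
l-arginine	L-arginine	C6H14N4O2	map00330
l-citrulline	L-citrulline	C6H13N3O3	map00330
l-proline	L-proline	C5H9NO2	map00330
l-glutamate	L-glutamate	C5H9NO4	map00250;map00330
l-glutamine	L-glutamine	C5H10N2O3	map00250
l-aspartate	L-aspartate	C4H7NO4	map00250
l-asparagine	L-asparagine	C4H8N2O3	map00250
l-alanine	L-alanine	C3H7NO2	map00250
glycine	glycine	C2H5NO2	map00260
l-serine	L-serine	C3H7NO3	map00260
l-threonine	L-threonine	C4H9NO3	map00260
choline	choline	C5H13NO	map00260
glycine-betaine	glycine betaine	C5H11NO2	map00260
l-phenylalanine	L-phenylalanine	C9H11NO2	map00940
p-coumarate	p-coumaric acid	C9H8O3	map00940
ferulate	ferulic acid	C10H10O4	map00940
sinapate	sinapic acid	C11H12O5	map00940
sinapaldehyde	sinapaldehyde	C11H12O4	map00940
sinapyl-alcohol	sinapyl alcohol	C11H14O3	map00940
syringin	syringin	C17H24O9	map00940
p-coumaroyl-shikimate	p-coumaroyl shikimate	C16H16O7	map00940
caffeate	caffeic acid	C9H8O4	map00940
coniferyl-alcohol	coniferyl alcohol	C10H12O3	map00940
l-tyrosine	L-tyrosine	C9H11NO3	map00940
l-tryptophan	L-tryptophan	C11H12N2O2	map00400
l-histidine	L-histidine	C6H9N3O2	map00340
l-methionine	L-methionine	C5H11NO2S	map00270
l-cysteine	L-cysteine	C3H7NO2S	map00270
l-valine	L-valine	C5H11NO2	map00290
l-leucine	L-leucine	C6H13NO2	map00290
l-isoleucine	L-isoleucine	C6H13NO2	map00290
nicotinate	nicotinic acid	C6H5NO2	map00760;map01064
nicotinamide	nicotinamide	C6H6N2O	map00760
trigonelline	trigonelline	C7H7NO2	map00760
quinolinate	quinolinate	C7H5NO4	map00760
sucrose	sucrose	C12H22O11	map00500
d-glucose	D-glucose	C6H12O6	map00500
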