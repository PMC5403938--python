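region	hemisphere	structname
lh_bankssts	lh	bankssts
lh_caudalanteriorcingulate	lh	caudalanteriorcingulate
lh_caudalmiddlefrontal	lh	caudalmiddlefrontal
lh_cuneus	lh	cuneus
lh_entorhinal	lh	entorhinal
lh_frontalpole	lh	frontalpole
lh_fusiform	lh	fusiform
lh_inferiorparietal	lh	inferiorparietal
lh_inferiortemporal	lh	inferiortemporal
lh_insula	lh	insula
lh_isthmuscingulate	lh	isthmuscingulate
lh_lateraloccipital	lh	lateraloccipital
lh_lateralorbitofrontal	lh	lateralorbitofrontal
lh_lingual	lh	lingual
lh_medialorbitofrontal	lh	medialorbitofrontal
lh_middletemporal	lh	middletemporal
lh_paracentral	lh	paracentral
lh_parahippocampal	lh	parahippocampal
lh_parsopercularis	lh	parsopercularis
lh_parsorbitalis	lh	parsorbitalis
lh_parstriangularis	lh	parstriangularis
lh_pericalcarine	lh	pericalcarine
lh_postcentral	lh	postcentral
lh_posteriorcingulate	lh	posteriorcingulate
lh_precentral	lh	precentral
lh_precuneus	lh	precuneus
lh_rostralanteriorcingulate	lh	rostralanteriorcingulate
lh_rostralmiddlefrontal	lh	rostralmiddlefrontal
lh_superiorfrontal	lh	superiorfrontal
lh_superiorparietal	lh	superiorparietal
lh_superiortemporal	lh	superiortemporal
lh_supramarginal	lh	supramarginal
lh_temporalpole	lh	temporalpole
lh_transversetemporal	lh	transversetemporal
rh_bankssts	rh	bankssts
rh_caudalanteriorcingulate	rh	caudalanteriorcingulate
rh_caudalmiddlefrontal	rh	caudalmiddlefrontal
rh_cuneus	rh	cuneus
rh_entorhinal	rh	entorhinal
rh_frontalpole	rh	frontalpole
rh_fusiform	rh	fusiform
rh_inferiorparietal	rh	inferiorparietal
rh_inferiortemporal	rh	inferiortemporal
rh_insula	rh	insula
rh_isthmuscingulate	rh	isthmuscingulate
rh_lateraloccipital	rh	lateraloccipital
rh_lateralorbitofrontal	rh	lateralorbitofrontal
rh_lingual	rh	lingual
rh_medialorbitofrontal	rh	medialorbitofrontal
rh_middletemporal	rh	middletemporal
rh_paracentral	rh	paracentral
rh_parahippocampal	rh	parahippocampal
rh_parsopercularis	rh	parsopercularis
rh_parsorbitalis	rh	parsorbitalis
rh_parstriangularis	rh	parstriangularis
rh_pericalcarine	rh	pericalcarine
rh_postcentral	rh	postcentral
rh_posteriorcingulate	rh	posteriorcingulate
rh_precentral	rh	precentral
rh_precuneus	rh	precuneus
rh_rostralanteriorcingulate	rh	rostralanteriorcingulate
rh_rostralmiddlefrontal	rh	rostralmiddlefrontal
rh_superiorfrontal	rh	superiorfrontal
rh_superiorparietal	rh	superiorparietal
rh_superiortemporal	rh	superiortemporal
rh_supramarginal	rh	supramarginal
rh_temporalpole	rh	temporalpole
rh_transversetemporal	rh	transversetemporal
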