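region	x	y	z
lh_bankssts	-56.0	-45.0	6.0
lh_caudalanteriorcingulate	-5.0	20.0	30.0
lh_caudalmiddlefrontal	-36.0	12.0	48.0
lh_cuneus	-8.0	-80.0	27.0
lh_entorhinal	-24.0	-8.0	-30.0
lh_frontalpole	-9.0	60.0	-12.0
lh_fusiform	-36.0	-45.0	-20.0
lh_inferiorparietal	-42.0	-62.0	42.0
lh_inferiortemporal	-50.0	-32.0	-22.0
lh_insula	-36.0	-2.0	4.0
lh_isthmuscingulate	-8.0	-45.0	25.0
lh_lateraloccipital	-30.0	-88.0	6.0
lh_lateralorbitofrontal	-25.0	32.0	-16.0
lh_lingual	-14.0	-68.0	-6.0
lh_medialorbitofrontal	-7.0	40.0	-15.0
lh_middletemporal	-56.0	-30.0	-10.0
lh_paracentral	-8.0	-28.0	58.0
lh_parahippocampal	-25.0	-32.0	-18.0
lh_parsopercularis	-48.0	14.0	14.0
lh_parsorbitalis	-44.0	40.0	-8.0
lh_parstriangularis	-46.0	32.0	8.0
lh_pericalcarine	-10.0	-80.0	8.0
lh_postcentral	-42.0	-25.0	48.0
lh_posteriorcingulate	-6.0	-20.0	38.0
lh_precentral	-38.0	-12.0	48.0
lh_precuneus	-9.0	-58.0	40.0
lh_rostralanteriorcingulate	-6.0	34.0	12.0
lh_rostralmiddlefrontal	-32.0	42.0	18.0
lh_superiorfrontal	-12.0	28.0	52.0
lh_superiorparietal	-24.0	-58.0	58.0
lh_superiortemporal	-54.0	-18.0	2.0
lh_supramarginal	-52.0	-42.0	32.0
lh_temporalpole	-32.0	10.0	-38.0
lh_transversetemporal	-46.0	-22.0	10.0
rh_bankssts	56.0	-45.0	6.0
rh_caudalanteriorcingulate	5.0	20.0	30.0
rh_caudalmiddlefrontal	36.0	12.0	48.0
rh_cuneus	8.0	-80.0	27.0
rh_entorhinal	24.0	-8.0	-30.0
rh_frontalpole	9.0	60.0	-12.0
rh_fusiform	36.0	-45.0	-20.0
rh_inferiorparietal	42.0	-62.0	42.0
rh_inferiortemporal	50.0	-32.0	-22.0
rh_insula	36.0	-2.0	4.0
rh_isthmuscingulate	8.0	-45.0	25.0
rh_lateraloccipital	30.0	-88.0	6.0
rh_lateralorbitofrontal	25.0	32.0	-16.0
rh_lingual	14.0	-68.0	-6.0
rh_medialorbitofrontal	7.0	40.0	-15.0
rh_middletemporal	56.0	-30.0	-10.0
rh_paracentral	8.0	-28.0	58.0
rh_parahippocampal	25.0	-32.0	-18.0
rh_parsopercularis	48.0	14.0	14.0
rh_parsorbitalis	44.0	40.0	-8.0
rh_parstriangularis	46.0	32.0	8.0
rh_pericalcarine	10.0	-80.0	8.0
rh_postcentral	42.0	-25.0	48.0
rh_posteriorcingulate	6.0	-20.0	38.0
rh_precentral	38.0	-12.0	48.0
rh_precuneus	9.0	-58.0	40.0
rh_rostralanteriorcingulate	6.0	34.0	12.0
rh_rostralmiddlefrontal	32.0	42.0	18.0
rh_superiorfrontal	12.0	28.0	52.0
rh_superiorparietal	24.0	-58.0	58.0
rh_superiortemporal	54.0	-18.0	2.0
rh_supramarginal	52.0	-42.0	32.0
rh_temporalpole	32.0	10.0	-38.0
rh_transversetemporal	46.0	-22.0	10.0
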