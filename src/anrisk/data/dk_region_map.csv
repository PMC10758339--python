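feature_name,connectome_label
lh_bankssts_thickness,lh_bankssts
lh_caudalanteriorcingulate_thickness,lh_caudalanteriorcingulate
lh_caudalmiddlefrontal_thickness,lh_caudalmiddlefrontal
lh_cuneus_thickness,lh_cuneus
lh_entorhinal_thickness,lh_entorhinal
lh_fusiform_thickness,lh_fusiform
lh_inferiorparietal_thickness,lh_inferiorparietal
lh_inferiortemporal_thickness,lh_inferiortemporal
lh_isthmuscingulate_thickness,lh_isthmuscingulate
lh_lateraloccipital_thickness,lh_lateraloccipital
lh_lateralorbitofrontal_thickness,lh_lateralorbitofrontal
lh_lingual_thickness,lh_lingual
lh_medialorbitofrontal_thickness,lh_medialorbitofrontal
lh_middletemporal_thickness,lh_middletemporal
lh_parahippocampal_thickness,lh_parahippocampal
lh_paracentral_thickness,lh_paracentral
lh_parsopercularis_thickness,lh_parsopercularis
lh_parsorbitalis_thickness,lh_parsorbitalis
lh_parstriangularis_thickness,lh_parstriangularis
lh_pericalcarine_thickness,lh_pericalcarine
lh_postcentral_thickness,lh_postcentral
lh_posteriorcingulate_thickness,lh_posteriorcingulate
lh_precentral_thickness,lh_precentral
lh_precuneus_thickness,lh_precuneus
lh_rostralanteriorcingulate_thickness,lh_rostralanteriorcingulate
lh_rostralmiddlefrontal_thickness,lh_rostralmiddlefrontal
lh_superiorfrontal_thickness,lh_superiorfrontal
lh_superiorparietal_thickness,lh_superiorparietal
lh_superiortemporal_thickness,lh_superiortemporal
lh_supramarginal_thickness,lh_supramarginal
lh_temporalpole_thickness,lh_temporalpole
lh_transversetemporal_thickness,lh_transversetemporal
lh_frontalpole_thickness,lh_frontalpole
lh_insula_thickness,lh_insula
rh_bankssts_thickness,rh_bankssts
rh_caudalanteriorcingulate_thickness,rh_caudalanteriorcingulate
rh_caudalmiddlefrontal_thickness,rh_caudalmiddlefrontal
rh_cuneus_thickness,rh_cuneus
rh_entorhinal_thickness,rh_entorhinal
rh_fusiform_thickness,rh_fusiform
rh_inferiorparietal_thickness,rh_inferiorparietal
rh_inferiortemporal_thickness,rh_inferiortemporal
rh_isthmuscingulate_thickness,rh_isthmuscingulate
rh_lateraloccipital_thickness,rh_lateraloccipital
rh_lateralorbitofrontal_thickness,rh_lateralorbitofrontal
rh_lingual_thickness,rh_lingual
rh_medialorbitofrontal_thickness,rh_medialorbitofrontal
rh_middletemporal_thickness,rh_middletemporal
rh_parahippocampal_thickness,rh_parahippocampal
rh_paracentral_thickness,rh_paracentral
rh_parsopercularis_thickness,rh_parsopercularis
rh_parsorbitalis_thickness,rh_parsorbitalis
rh_parstriangularis_thickness,rh_parstriangularis
rh_pericalcarine_thickness,rh_pericalcarine
rh_postcentral_thickness,rh_postcentral
rh_posteriorcingulate_thickness,rh_posteriorcingulate
rh_precentral_thickness,rh_precentral
rh_precuneus_thickness,rh_precuneus
rh_rostralanteriorcingulate_thickness,rh_rostralanteriorcingulate
rh_rostralmiddlefrontal_thickness,rh_rostralmiddlefrontal
rh_superiorfrontal_thickness,rh_superiorfrontal
rh_superiorparietal_thickness,rh_superiorparietal
rh_superiortemporal_thickness,rh_superiortemporal
rh_supramarginal_thickness,rh_supramarginal
rh_temporalpole_thickness,rh_temporalpole
rh_transversetemporal_thickness,rh_transversetemporal
rh_frontalpole_thickness,rh_frontalpole
rh_insula_thickness,rh_insula
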