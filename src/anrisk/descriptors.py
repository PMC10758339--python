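"""Default morphometric feature set.

The analyses here operate on 110 regional measures: 68 Desikan-Killiany
cortical-thickness values (34 regions x 2 hemispheres) plus 42 subcortical
gray-matter and CSF-space volumes.  The exact composition of the non-cortical
measures in the motivating study design is not fully standardized across
FreeSurfer versions, so the default set below is a *plausible, clearly
synthetic reconstruction* built from standard FreeSurfer segmentation
names — suitable for the synthetic cohorts generated by
:mod:`anrisk.cohort`, not a claim about any particular dataset.
"""

from __future__ import annotations

from .data import FeatureDescriptor, FeatureKind

__all__ = [
    "DESIKAN_KILLIANY_REGIONS",
    "default_descriptors",
    "default_region_labels",
]

#: The 34 Desikan-Killiany cortical parcels, in standard FreeSurfer order.
DESIKAN_KILLIANY_REGIONS = (
    "bankssts",
    "caudalanteriorcingulate",
    "caudalmiddlefrontal",
    "cuneus",
    "entorhinal",
    "fusiform",
    "inferiorparietal",
    "inferiortemporal",
    "isthmuscingulate",
    "lateraloccipital",
    "lateralorbitofrontal",
    "lingual",
    "medialorbitofrontal",
    "middletemporal",
    "parahippocampal",
    "paracentral",
    "parsopercularis",
    "parsorbitalis",
    "parstriangularis",
    "pericalcarine",
    "postcentral",
    "posteriorcingulate",
    "precentral",
    "precuneus",
    "rostralanteriorcingulate",
    "rostralmiddlefrontal",
    "superiorfrontal",
    "superiorparietal",
    "superiortemporal",
    "supramarginal",
    "temporalpole",
    "transversetemporal",
    "frontalpole",
    "insula",
)

# Bilateral subcortical gray-matter structures (FreeSurfer aseg naming).
_SUBCORTICAL_PAIRS = (
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "Cerebellum-Cortex",
)

# Midline / global gray-matter summary volumes completing the GM set.
_SUBCORTICAL_MIDLINE = (
    "Brain-Stem",
    "Midbrain",
    "Pons",
    "Medulla",
    "SCP",
    "Optic-Chiasm",
    "CC-Total",
    "SubCortGrayVol",
    "lhCortexVol",
    "rhCortexVol",
    "TotalGrayVol",
    "CerebellumGMTotal",
)

# CSF / ventricular spaces.
_CSF_PAIRS = ("Lateral-Ventricle", "Inf-Lat-Vent", "choroid-plexus")
_CSF_MIDLINE = (
    "3rd-Ventricle",
    "4th-Ventricle",
    "5th-Ventricle",
    "CSF",
    "VentricleChoroidVol",
    "Total-CSF-Space",
)


def default_descriptors() -> list[FeatureDescriptor]:
    """The default 110-feature descriptor list (68 CT + 30 GM + 12 CSF)."""
    out: list[FeatureDescriptor] = []
    for hemi, prefix in (("left", "lh"), ("right", "rh")):
        for region in DESIKAN_KILLIANY_REGIONS:
            out.append(
                FeatureDescriptor(
                    name=f"{prefix}_{region}_thickness",
                    kind=FeatureKind.CORTICAL_THICKNESS,
                    hemisphere=hemi,
                    region_label=region,
                )
            )
    for hemi, prefix in (("left", "Left"), ("right", "Right")):
        for structure in _SUBCORTICAL_PAIRS:
            out.append(
                FeatureDescriptor(
                    name=f"{prefix}-{structure}",
                    kind=FeatureKind.SUBCORTICAL_GM_VOLUME,
                    hemisphere=hemi,
                    region_label=structure,
                )
            )
    for structure in _SUBCORTICAL_MIDLINE:
        out.append(
            FeatureDescriptor(
                name=structure,
                kind=FeatureKind.SUBCORTICAL_GM_VOLUME,
                hemisphere="bilateral",
                region_label=structure,
            )
        )
    for hemi, prefix in (("left", "Left"), ("right", "Right")):
        for structure in _CSF_PAIRS:
            out.append(
                FeatureDescriptor(
                    name=f"{prefix}-{structure}",
                    kind=FeatureKind.CSF_VOLUME,
                    hemisphere=hemi,
                    region_label=structure,
                )
            )
    for structure in _CSF_MIDLINE:
        out.append(
            FeatureDescriptor(
                name=structure,
                kind=FeatureKind.CSF_VOLUME,
                hemisphere="bilateral",
                region_label=structure,
            )
        )
    assert len(out) == 110
    return out


def default_region_labels() -> list[str]:
    """Connectome region labels matching the 68 cortical features, in order."""
    return [
        f"{prefix}_{region}"
        for prefix in ("lh", "rh")
        for region in DESIKAN_KILLIANY_REGIONS
    ]
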