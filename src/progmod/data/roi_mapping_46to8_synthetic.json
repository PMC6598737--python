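{
  "description": "Synthetic default mapping of 46 bilateral cortical/subcortical regions to 8 composite ROIs (whole_brain, hippocampal, occipital, frontal, entorhinal, temporal, parietal, ventricle). Region names follow Neuromorphometrics-style conventions; the grouping is a representative reconstruction, not a published atlas table.",
  "left_prefix": "Left ",
  "right_prefix": "Right ",
  "roi_groups": {
    "occipital": [
      "Occipital pole",
      "Inferior occipital gyrus",
      "Middle occipital gyrus",
      "Superior occipital gyrus",
      "Occipital fusiform gyrus",
      "Calcarine cortex"
    ],
    "parietal": [
      "Superior parietal lobule",
      "Angular gyrus",
      "Supramarginal gyrus",
      "Precuneus",
      "Postcentral gyrus",
      "Parietal operculum"
    ],
    "temporal": [
      "Superior temporal gyrus",
      "Middle temporal gyrus",
      "Inferior temporal gyrus",
      "Temporal pole",
      "Fusiform gyrus",
      "Transverse temporal gyrus",
      "Planum polare",
      "Planum temporale"
    ],
    "frontal": [
      "Superior frontal gyrus",
      "Middle frontal gyrus",
      "Inferior frontal gyrus pars opercularis",
      "Inferior frontal gyrus pars triangularis",
      "Inferior frontal gyrus pars orbitalis",
      "Precentral gyrus",
      "Supplementary motor cortex",
      "Medial frontal cortex",
      "Orbitofrontal gyrus",
      "Gyrus rectus",
      "Frontal operculum",
      "Frontal pole",
      "Subcallosal area",
      "Anterior cingulate gyrus"
    ],
    "entorhinal": [
      "Entorhinal area"
    ],
    "hippocampal": [
      "Hippocampus"
    ],
    "ventricle": [
      "Lateral ventricle",
      "Inferior lateral ventricle"
    ],
    "whole_brain": [
      "Anterior insula",
      "Posterior insula",
      "Middle cingulate gyrus",
      "Posterior cingulate gyrus",
      "Amygdala",
      "Parahippocampal gyrus",
      "Lingual gyrus",
      "Cuneus"
    ]
  },
  "drop": []
}
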