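"""AAL-90 cortical/subcortical parcellation labels.

The automated anatomical labeling (AAL) atlas divides the cerebrum into 90
regions (45 per hemisphere, cerebellum excluded). Region abbreviations follow
the conventional short names (e.g. ``HIP.L`` = left hippocampus, ``MCG.R`` =
right middle cingulate gyrus); regions are ordered in homologous left/right
pairs, left first, matching the atlas numbering.
"""

from __future__ import annotations

_AAL_BASE = [
    "PreCG",      # precentral gyrus
    "SFGdor",     # superior frontal gyrus, dorsolateral
    "ORBsup",     # superior frontal gyrus, orbital part
    "MFG",        # middle frontal gyrus
    "ORBmid",     # middle frontal gyrus, orbital part
    "IFGoperc",   # inferior frontal gyrus, opercular part
    "IFGtriang",  # inferior frontal gyrus, triangular part
    "ORBinf",     # inferior frontal gyrus, orbital part
    "ROL",        # rolandic operculum
    "SMA",        # supplementary motor area
    "OLF",        # olfactory cortex
    "SFGmed",     # superior frontal gyrus, medial
    "ORBsupmed",  # superior frontal gyrus, medial orbital
    "REC",        # gyrus rectus
    "INS",        # insula
    "ACG",        # anterior cingulate gyrus
    "MCG",        # middle (dorsal) cingulate gyrus
    "PCG",        # posterior cingulate gyrus
    "HIP",        # hippocampus
    "PHG",        # parahippocampal gyrus
    "AMYG",       # amygdala
    "CAL",        # calcarine fissure and surrounding cortex
    "CUN",        # cuneus
    "LING",       # lingual gyrus
    "SOG",        # superior occipital gyrus
    "MOG",        # middle occipital gyrus
    "IOG",        # inferior occipital gyrus
    "FFG",        # fusiform gyrus
    "PoCG",       # postcentral gyrus
    "SPG",        # superior parietal gyrus
    "IPL",        # inferior parietal lobule
    "SMG",        # supramarginal gyrus
    "ANG",        # angular gyrus
    "PCUN",       # precuneus
    "PCL",        # paracentral lobule
    "CAU",        # caudate nucleus
    "PUT",        # putamen
    "PAL",        # pallidum
    "THA",        # thalamus
    "HES",        # Heschl gyrus
    "STG",        # superior temporal gyrus
    "TPOsup",     # temporal pole: superior temporal gyrus
    "MTG",        # middle temporal gyrus
    "TPOmid",     # temporal pole: middle temporal gyrus
    "ITG",        # inferior temporal gyrus
]

#: The 90 AAL region abbreviations, in atlas order (L/R interleaved).
AAL90_LABELS: list[str] = [
    f"{name}.{hemi}" for name in _AAL_BASE for hemi in ("L", "R")
]

N_AAL_REGIONS = len(AAL90_LABELS)
assert N_AAL_REGIONS == 90


def generic_labels(n: int) -> list[str]:
    """Fallback ``ROI001 ...`` labels for non-atlas node counts."""
    width = max(3, len(str(n)))
    return [f"ROI{i + 1:0{width}d}" for i in range(n)]


def labels_for(n_rois: int) -> list[str]:
    """AAL-90 labels when ``n_rois`` is 90, generic labels otherwise."""
    return list(AAL90_LABELS) if n_rois == 90 else generic_labels(n_rois)
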