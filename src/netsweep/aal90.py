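"""AAL-90 cerebral parcellation labels.

Standard abbreviations for the 90 cerebral regions of the automated
anatomical labeling atlas, in atlas order (odd indices left hemisphere,
even indices right). Used as default node labels for 90-ROI networks;
other parcellations simply supply their own label list.
"""

_AAL45 = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "PCG", "HIP", "PHG", "AMYG", "CAL", "CUN", "LING",
    "SOG", "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG",
    "PCUN", "PCL", "CAU", "PUT", "PAL", "THA", "HES", "STG", "TPOsup",
    "MTG", "TPOmid", "ITG",
]

#: The 90 region labels, e.g. "PreCG.L", "PreCG.R", ..., "ITG.L", "ITG.R".
AAL90_LABELS: list[str] = [
    f"{name}.{hemi}" for name in _AAL45 for hemi in ("L", "R")
]


def generic_labels(n: int) -> list[str]:
    """Fallback labels ROI001..ROInnn for non-90-node networks."""
    return [f"ROI{i + 1:03d}" for i in range(n)]


def default_labels(n: int) -> list[str]:
    """AAL-90 abbreviations when n == 90, generic ROI labels otherwise."""
    return list(AAL90_LABELS) if n == 90 else generic_labels(n)
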