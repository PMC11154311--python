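"""Residue-range conventions for the Ras G-domain (PDB 5UHV numbering).

Residue numbers are 1-based crystal numbering throughout; no renumbering is
ever performed.  Switch ranges are the standard Ras literature defaults and
are configurable wherever they are consumed.
"""

#: Catalytic G-domain residue range (inclusive).
G_DOMAIN = (1, 165)

#: Switch I loop (contains Tyr32, Thr35, Tyr40).
SWITCH_I = (30, 40)

#: Switch II loop.
SWITCH_II = (58, 76)

#: beta-1 strand residues used for the membrane-tilt reaction coordinate.
BETA1 = (2, 5)

#: alpha-4 helix residue for the HVR-stretch reaction coordinate.
E132 = 132

#: HVR residue for the HVR-stretch reaction coordinate.
L184 = 184

#: Last HVR residue (farnesylated Cys186 in the full-length protein).
HVR_END = 186


def residue_indices(resids, lo, hi):
    """Return positions in ``resids`` whose value lies in [lo, hi]."""
    import numpy as np

    resids = np.asarray(resids)
    return np.flatnonzero((resids >= lo) & (resids <= hi))
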