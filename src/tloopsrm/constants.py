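"""Monoisotopic mass constants shared across the package.

Residue masses come from :mod:`pyteomics.mass`; modification and label
masses are fixed package-wide so that light/heavy precursor and fragment
m/z values are reproducible to 1e-4 Th.
"""

from pyteomics import mass as _pyt_mass

#: Monoisotopic residue masses for the 20 canonical amino acids (Da).
AA_MONO: dict[str, float] = {
    aa: _pyt_mass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Mass of a proton (Da); added once per charge.
PROTON = 1.007276

#: Monoisotopic mass of water (Da); peptide termini.
WATER = 18.010565

#: Mass shift of one phosphorylation (HPO3, Da).
PHOSPHO = 79.966331

#: Neutral loss of phosphoric acid (H3PO4, Da) from phosphorylated fragments.
NEUTRAL_LOSS_H3PO4 = 97.976896

#: Stable-isotope label shifts on the C-terminal residue of heavy standards:
#: 13C6,15N2-lysine and 13C6,15N4-arginine.
HEAVY_LABEL = {"K": 8.014199, "R": 10.008269}

#: Residues that can carry a phosphate in this assay.
PHOSPHO_RESIDUES = frozenset("STY")
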