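"""Physical constants, element masses and nucleic-acid lookup tables."""

from __future__ import annotations

import numpy as np

from ._stdbases import STANDARD_NUCLEOTIDES

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL = 0.0019872041

#: Default analysis temperature (K).
T_DEFAULT = 300.0

#: Standard atomic masses (u) for the elements occurring in DNA.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.973762,
}

#: Watson-Crick complement, one-letter codes.
COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: Accepted residue-name dialects, normalized to DA/DC/DG/DT.
RESIDUE_ALIASES = {
    "DA": "DA", "DC": "DC", "DG": "DG", "DT": "DT",
    "A": "DA", "C": "DC", "G": "DG", "T": "DT",
    "ADE": "DA", "CYT": "DC", "GUA": "DG", "THY": "DT",
}

PURINES = {"DA", "DG"}
PYRIMIDINES = {"DC", "DT"}

#: Base ring heavy atoms used for reference-frame fitting.
RING_ATOMS = {
    "DA": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "DG": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "DC": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "DT": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

#: All base (non-sugar, non-backbone) atoms, including hydrogens.
BASE_ATOMS = {
    "DA": ("N9", "C8", "N7", "C5", "C6", "N6", "N1", "C2", "N3", "C4",
           "H8", "H61", "H62", "H2"),
    "DG": ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
           "H8", "H1", "H21", "H22"),
    "DC": ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6",
           "H41", "H42", "H5", "H6"),
    "DT": ("N1", "C2", "O2", "N3", "C4", "O4", "C5", "C7", "C6",
           "H3", "H71", "H72", "H73", "H6"),
}

#: Sugar-phosphate backbone heavy atoms (RMSD-to-target default selection).
BACKBONE_ATOMS = ("P", "OP1", "OP2", "O5'", "C5'", "C4'", "C3'", "O3'",
                  "C2'", "C1'", "O4'")

#: Hydrogen-bond donor heavy atoms of the bases (atoms bearing polar H).
HB_DONORS = {
    "DA": ("N6",),
    "DG": ("N1", "N2"),
    "DC": ("N4",),
    "DT": ("N3",),
}

#: Hydrogen-bond acceptor atoms of the bases.
HB_ACCEPTORS = {
    "DA": ("N1", "N3", "N7"),
    "DG": ("N3", "N7", "O6"),
    "DC": ("O2", "N3"),
    "DT": ("O2", "O4"),
}

#: Donor heavy atom -> names of its covalent hydrogens.
DONOR_HYDROGENS = {
    ("DA", "N6"): ("H61", "H62"),
    ("DG", "N1"): ("H1",),
    ("DG", "N2"): ("H21", "H22"),
    ("DC", "N4"): ("H41", "H42"),
    ("DT", "N3"): ("H3",),
}

#: Glycosidic torsion atoms (O4'-C1'-N-C) per base family.
CHI_ATOMS = {
    "purine": ("O4'", "C1'", "N9", "C4"),
    "pyrimidine": ("O4'", "C1'", "N1", "C2"),
}

#: Fiber B-DNA helical step defaults.
FIBER_TWIST = 36.0
FIBER_RISE = 3.38


def standard_base_coords(base_type: str, atom_names) -> np.ndarray:
    """Coordinates of ``atom_names`` of the embedded standard nucleotide."""
    table = {name: np.asarray(xyz) for name, _elem, xyz in
             STANDARD_NUCLEOTIDES[base_type]}
    missing = [a for a in atom_names if a not in table]
    if missing:
        raise KeyError(f"no standard coordinates for {missing} in {base_type}")
    return np.array([table[a] for a in atom_names], dtype=float)
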