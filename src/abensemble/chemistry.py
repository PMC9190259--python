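"""Chemical reference tables: atomic masses, charged groups, aromatic rings,
hydrophobic atom typing.

Tables cover the 20 standard amino acids plus common water/ion residue
names. Hydrophobic typing follows the rule "carbon or sulfur atoms whose
bonded neighbours include no nitrogen or oxygen", precomputed per residue
template so no connectivity records are needed at run time.
"""

from __future__ import annotations

# standard atomic weights, Da
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "NA": 22.990,
    "CL": 35.45,
    "K": 39.098,
    "MG": 24.305,
    "CA": 40.078,
    "MN": 54.938,
    "ZN": 65.38,
    "F": 18.998,
    "BR": 79.904,
    "I": 126.904,
}

WATER_RESNAMES_DEFAULT = ("HOH", "WAT", "SOL", "TIP3", "TIP3P", "SPC")
ION_RESNAMES_DEFAULT = ("NA", "CL", "NA+", "CL-", "SOD", "CLA", "K", "MG", "CA", "MN", "ZN")

# positively charged side-chain N atoms (pH 7.4); HIP = protonated His
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIP": ("ND1", "NE2"),
}

# negatively charged side-chain O atoms
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# cation centres for cation-pi: Lys ammonium N and Arg guanidinium C
CATION_PI_ATOMS: dict[str, tuple[str, ...]] = {
    "LYS": ("NZ",),
    "ARG": ("CZ",),
}

# aromatic ring atom names; Trp contributes two rings
AROMATIC_RINGS: dict[str, tuple[tuple[str, ...], ...]] = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (
        ("CG", "CD1", "NE1", "CE2", "CD2"),
        ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    ),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "HID": (("CG", "ND1", "CD2", "CE1", "NE2"),),
    "HIE": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}

# C/S atoms with no covalently bonded N or O, per residue template
HYDROPHOBIC_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG"),
    "ASN": ("CB",),
    "ASP": ("CB",),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG"),
    "GLU": ("CB", "CG"),
    "GLY": (),
    "HIS": ("CB",),
    "HID": ("CB",),
    "HIE": ("CB",),
    "HIP": ("CB",),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG"),
    "SER": (),
    "THR": ("CG2",),
    "TRP": ("CB", "CG", "CD2", "CE3", "CZ3", "CH2", "CZ2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2"),
    "VAL": ("CB", "CG1", "CG2"),
}

BACKBONE_ATOMS = ("N", "CA", "C", "O")


def element_mass(element: str) -> float:
    """Standard atomic weight of *element* in Da."""
    key = element.strip().upper()
    try:
        return ATOMIC_MASSES[key]
    except KeyError:
        raise KeyError(f"no atomic mass tabulated for element {element!r}") from None
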