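"""Chemical reference tables shared across the geometric modules.

Radii follow the Chothia-style convention common to interface servers
(C 1.70, N 1.55, O 1.52, S 1.80 A); everything here is heavy-atom only,
consistent with analysing medium-resolution X-ray models that carry no
hydrogens.
"""

from __future__ import annotations

# van der Waals radii (Angstrom), heavy atoms. Overridable via SasaParams.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
    "F": 1.47,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "H": 1.20,  # present only if a caller opts in to hydrogens
}

AA3_TO_1: dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "U", "PYL": "O",
}

AA1_TO_3: dict[str, str] = {v: k for k, v in AA3_TO_1.items() if k not in ("MSE",)}

STANDARD_AA1 = set("ACDEFGHIKLMNPQRSTVWY")

# Hydrogen-bond donor heavy atoms per residue type (atom -> bonded heavy
# antecedents used for the angle proxy). Backbone N handled separately.
SIDECHAIN_DONORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ARG": {"NE": ("CD", "CZ"), "NH1": ("CZ",), "NH2": ("CZ",)},
    "LYS": {"NZ": ("CE",)},
    "ASN": {"ND2": ("CG",)},
    "GLN": {"NE2": ("CD",)},
    "HIS": {"ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1")},
    "SER": {"OG": ("CB",)},
    "THR": {"OG1": ("CB",)},
    "TYR": {"OH": ("CZ",)},
    "TRP": {"NE1": ("CD1", "CE2")},
    "CYS": {"SG": ("CB",)},
}

# Hydrogen-bond acceptor heavy atoms per residue type (atom -> antecedents).
SIDECHAIN_ACCEPTORS: dict[str, dict[str, tuple[str, ...]]] = {
    "ASP": {"OD1": ("CG",), "OD2": ("CG",)},
    "GLU": {"OE1": ("CD",), "OE2": ("CD",)},
    "ASN": {"OD1": ("CG",)},
    "GLN": {"OE1": ("CD",)},
    "HIS": {"ND1": ("CG", "CE1"), "NE2": ("CD2", "CE1")},
    "SER": {"OG": ("CB",)},
    "THR": {"OG1": ("CB",)},
    "TYR": {"OH": ("CZ",)},
    "MET": {"SD": ("CG", "CE")},
}

BACKBONE_DONOR = {"N": ("CA",)}
BACKBONE_ACCEPTOR = {"O": ("C",), "OXT": ("C",)}

# Charged side-chain atoms at physiological pH (for salt-bridge tagging).
POSITIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ARG": ("NE", "NH1", "NH2"),
    "LYS": ("NZ",),
    "HIS": ("ND1", "NE2"),
}
NEGATIVE_ATOMS: dict[str, tuple[str, ...]] = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}

# One-letter classification used by the substitution-effect rules.
POSITIVE_AA = set("KR")       # His treated as neutral for specificity rules
NEGATIVE_AA = set("DE")
HYDROPHOBIC_AA = set("AVLIMFWYPG")  # Trp/Tyr count as hydrophobic replacements
POLAR_AA = set("STNQCH")

# Side-chain heavy-atom counts (0 for Gly).
SIDECHAIN_HEAVY_ATOMS: dict[str, int] = {
    "G": 0, "A": 1, "S": 2, "C": 2, "T": 3, "P": 3, "V": 3,
    "D": 4, "N": 4, "I": 4, "L": 4, "M": 4, "E": 5, "Q": 5,
    "K": 5, "H": 6, "F": 7, "R": 7, "Y": 8, "W": 10,
}


def charge_sign(aa: str) -> int:
    """Nominal side-chain charge sign of a one-letter residue code."""
    if aa in POSITIVE_AA:
        return 1
    if aa in NEGATIVE_AA:
        return -1
    return 0


def has_sidechain_hbond_capacity(aa: str) -> bool:
    """True if the residue side chain can donate or accept a hydrogen bond."""
    aa3 = AA1_TO_3.get(aa)
    return aa3 in SIDECHAIN_DONORS or aa3 in SIDECHAIN_ACCEPTORS


def vdw_radius(element: str, table: dict[str, float] | None = None) -> float:
    tab = table or VDW_RADII
    key = element.upper()
    if key not in tab:
        raise KeyError(f"no van der Waals radius for element {element!r}")
    return tab[key]
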