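"""Embedded sidechain templates for the 20 standard amino acids.

Each template lists the sidechain atoms (plus the Calpha anchor), simplified
partial charges, charge-group labels and the bond list.  Charges are
schematic neutral-group values chosen so that every charge group carries an
integer net charge (0, or +/-1 for ionized groups); they are not taken from
any published force field — only group membership, integer net charge and
graph topology matter for transformation planning.

Hydrogen naming is template-local (HB1/HB2 for the two beta hydrogens of
branched residues, HB1..HB3 for alanine) so that the alanine common fragment
is an atom-id subfragment of every other sidechain.

The proline template omits the CD-N ring-closure bond: the backbone nitrogen
lies outside the sidechain fragment.
"""

from __future__ import annotations

from .errors import ValidationError
from .fragments import AtomNode, FragmentGraph

__all__ = ["sidechain_graph", "alanine_target", "standard_residues",
           "ONE_TO_THREE", "THREE_TO_ONE"]

ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}
THREE_TO_ONE = {v: k for k, v in ONE_TO_THREE.items()}

# name -> (atoms [(id, element, charge, group)], bonds)
_T: dict[str, tuple[list[tuple[str, str, float, str]], list[tuple[str, str]]]] = {}

_T["ALA"] = (
    [("CB", "C", -0.30, "beta"), ("HB1", "H", 0.10, "beta"),
     ("HB2", "H", 0.10, "beta"), ("HB3", "H", 0.10, "beta")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "HB3")],
)

_T["ARG"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.20, "gamma"), ("HG1", "H", 0.10, "gamma"), ("HG2", "H", 0.10, "gamma"),
     ("CD", "C", 0.10, "guanidinium"), ("HD1", "H", 0.10, "guanidinium"),
     ("HD2", "H", 0.10, "guanidinium"), ("NE", "N", -0.60, "guanidinium"),
     ("HE", "H", 0.40, "guanidinium"), ("CZ", "C", 0.90, "guanidinium"),
     ("NH1", "N", -0.80, "guanidinium"), ("HH11", "H", 0.40, "guanidinium"),
     ("HH12", "H", 0.40, "guanidinium"), ("NH2", "N", -0.80, "guanidinium"),
     ("HH21", "H", 0.40, "guanidinium"), ("HH22", "H", 0.40, "guanidinium")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "CD"), ("CD", "HD1"), ("CD", "HD2"),
     ("CD", "NE"), ("NE", "HE"), ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2"),
     ("NH1", "HH11"), ("NH1", "HH12"), ("NH2", "HH21"), ("NH2", "HH22")],
)

_T["ASN"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", 0.50, "carbonyl"), ("OD1", "O", -0.50, "carbonyl"),
     ("ND2", "N", -0.76, "amide"), ("HD21", "H", 0.38, "amide"),
     ("HD22", "H", 0.38, "amide")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "OD1"), ("CG", "ND2"), ("ND2", "HD21"), ("ND2", "HD22")],
)

_T["ASP"] = (
    [("CB", "C", -0.10, "beta"), ("HB1", "H", 0.05, "beta"), ("HB2", "H", 0.05, "beta"),
     ("CG", "C", 0.70, "carboxylate"), ("OD1", "O", -0.85, "carboxylate"),
     ("OD2", "O", -0.85, "carboxylate")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "OD1"), ("CG", "OD2")],
)

_T["CYS"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("SG", "S", -0.30, "thiol"), ("HG", "H", 0.30, "thiol")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "SG"), ("SG", "HG")],
)

_T["GLN"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.20, "gamma"), ("HG1", "H", 0.10, "gamma"), ("HG2", "H", 0.10, "gamma"),
     ("CD", "C", 0.50, "carbonyl"), ("OE1", "O", -0.50, "carbonyl"),
     ("NE2", "N", -0.76, "amide"), ("HE21", "H", 0.38, "amide"),
     ("HE22", "H", 0.38, "amide")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "CD"), ("CD", "OE1"), ("CD", "NE2"),
     ("NE2", "HE21"), ("NE2", "HE22")],
)

_T["GLU"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.10, "gamma"), ("HG1", "H", 0.05, "gamma"), ("HG2", "H", 0.05, "gamma"),
     ("CD", "C", 0.70, "carboxylate"), ("OE1", "O", -0.85, "carboxylate"),
     ("OE2", "O", -0.85, "carboxylate")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "CD"), ("CD", "OE1"), ("CD", "OE2")],
)

_T["GLY"] = (
    [("HA2", "H", 0.00, "alphaH")],
    [("CA", "HA2")],
)

# neutral His, proton on ND1
_T["HIS"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", 0.10, "imidazole"), ("ND1", "N", -0.40, "imidazole"),
     ("HD1", "H", 0.40, "imidazole"), ("CD2", "C", -0.10, "imidazole"),
     ("HD2", "H", 0.10, "imidazole"), ("CE1", "C", 0.20, "imidazole"),
     ("HE1", "H", 0.10, "imidazole"), ("NE2", "N", -0.40, "imidazole")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "ND1"), ("CG", "CD2"), ("ND1", "HD1"), ("ND1", "CE1"),
     ("CD2", "HD2"), ("CD2", "NE2"), ("CE1", "HE1"), ("CE1", "NE2")],
)

_T["ILE"] = (
    [("CB", "C", -0.10, "beta"), ("HB1", "H", 0.10, "beta"),
     ("CG2", "C", -0.30, "gamma2_methyl"), ("HG21", "H", 0.10, "gamma2_methyl"),
     ("HG22", "H", 0.10, "gamma2_methyl"), ("HG23", "H", 0.10, "gamma2_methyl"),
     ("CG1", "C", -0.20, "gamma1"), ("HG11", "H", 0.10, "gamma1"),
     ("HG12", "H", 0.10, "gamma1"),
     ("CD1", "C", -0.30, "delta_methyl"), ("HD11", "H", 0.10, "delta_methyl"),
     ("HD12", "H", 0.10, "delta_methyl"), ("HD13", "H", 0.10, "delta_methyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "CG1"), ("CB", "CG2"),
     ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23"),
     ("CG1", "HG11"), ("CG1", "HG12"), ("CG1", "CD1"),
     ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13")],
)

_T["LEU"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.10, "gamma"), ("HG1", "H", 0.10, "gamma"),
     ("CD1", "C", -0.30, "delta1_methyl"), ("HD11", "H", 0.10, "delta1_methyl"),
     ("HD12", "H", 0.10, "delta1_methyl"), ("HD13", "H", 0.10, "delta1_methyl"),
     ("CD2", "C", -0.30, "delta2_methyl"), ("HD21", "H", 0.10, "delta2_methyl"),
     ("HD22", "H", 0.10, "delta2_methyl"), ("HD23", "H", 0.10, "delta2_methyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "CD1"), ("CG", "CD2"),
     ("CD1", "HD11"), ("CD1", "HD12"), ("CD1", "HD13"),
     ("CD2", "HD21"), ("CD2", "HD22"), ("CD2", "HD23")],
)

_T["LYS"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.20, "gamma"), ("HG1", "H", 0.10, "gamma"), ("HG2", "H", 0.10, "gamma"),
     ("CD", "C", -0.20, "delta"), ("HD1", "H", 0.10, "delta"), ("HD2", "H", 0.10, "delta"),
     ("CE", "C", 0.20, "ammonium"), ("HE1", "H", 0.10, "ammonium"),
     ("HE2", "H", 0.10, "ammonium"), ("NZ", "N", -0.50, "ammonium"),
     ("HZ1", "H", 0.37, "ammonium"), ("HZ2", "H", 0.37, "ammonium"),
     ("HZ3", "H", 0.36, "ammonium")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "CD"), ("CD", "HD1"), ("CD", "HD2"),
     ("CD", "CE"), ("CE", "HE1"), ("CE", "HE2"), ("CE", "NZ"),
     ("NZ", "HZ1"), ("NZ", "HZ2"), ("NZ", "HZ3")],
)

_T["MET"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.10, "gamma"), ("HG1", "H", 0.05, "gamma"), ("HG2", "H", 0.05, "gamma"),
     ("SD", "S", -0.30, "thioether"), ("CE", "C", 0.00, "thioether"),
     ("HE1", "H", 0.10, "thioether"), ("HE2", "H", 0.10, "thioether"),
     ("HE3", "H", 0.10, "thioether")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "SD"), ("SD", "CE"),
     ("CE", "HE1"), ("CE", "HE2"), ("CE", "HE3")],
)

_T["PHE"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", 0.00, "ring"), ("CD1", "C", -0.10, "ring"), ("HD1", "H", 0.10, "ring"),
     ("CD2", "C", -0.10, "ring"), ("HD2", "H", 0.10, "ring"),
     ("CE1", "C", -0.10, "ring"), ("HE1", "H", 0.10, "ring"),
     ("CE2", "C", -0.10, "ring"), ("HE2", "H", 0.10, "ring"),
     ("CZ", "C", -0.10, "ring"), ("HZ", "H", 0.10, "ring")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "CD1"), ("CG", "CD2"), ("CD1", "HD1"), ("CD1", "CE1"),
     ("CD2", "HD2"), ("CD2", "CE2"), ("CE1", "HE1"), ("CE1", "CZ"),
     ("CE2", "HE2"), ("CE2", "CZ"), ("CZ", "HZ")],
)

_T["PRO"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", -0.20, "gamma"), ("HG1", "H", 0.10, "gamma"), ("HG2", "H", 0.10, "gamma"),
     ("CD", "C", -0.20, "delta"), ("HD1", "H", 0.10, "delta"), ("HD2", "H", 0.10, "delta")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "HG1"), ("CG", "HG2"), ("CG", "CD"), ("CD", "HD1"), ("CD", "HD2")],
)

_T["SER"] = (
    [("CB", "C", -0.10, "beta"), ("HB1", "H", 0.05, "beta"), ("HB2", "H", 0.05, "beta"),
     ("OG", "O", -0.40, "hydroxyl"), ("HG", "H", 0.40, "hydroxyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "OG"), ("OG", "HG")],
)

_T["THR"] = (
    [("CB", "C", 0.00, "beta"), ("HB1", "H", 0.00, "beta"),
     ("OG1", "O", -0.40, "hydroxyl"), ("HG1", "H", 0.40, "hydroxyl"),
     ("CG2", "C", -0.30, "gamma_methyl"), ("HG21", "H", 0.10, "gamma_methyl"),
     ("HG22", "H", 0.10, "gamma_methyl"), ("HG23", "H", 0.10, "gamma_methyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "OG1"), ("CB", "CG2"),
     ("OG1", "HG1"), ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")],
)

_T["TRP"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", 0.00, "pyrrole"), ("CD1", "C", -0.10, "pyrrole"),
     ("HD1", "H", 0.10, "pyrrole"), ("NE1", "N", -0.40, "pyrrole"),
     ("HE1", "H", 0.40, "pyrrole"), ("CD2", "C", 0.00, "pyrrole"),
     ("CE2", "C", 0.00, "pyrrole"),
     ("CE3", "C", -0.10, "benzo"), ("HE3", "H", 0.10, "benzo"),
     ("CZ2", "C", -0.10, "benzo"), ("HZ2", "H", 0.10, "benzo"),
     ("CZ3", "C", -0.10, "benzo"), ("HZ3", "H", 0.10, "benzo"),
     ("CH2", "C", -0.10, "benzo"), ("HH2", "H", 0.10, "benzo")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "CD1"), ("CG", "CD2"), ("CD1", "HD1"), ("CD1", "NE1"),
     ("NE1", "HE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
     ("CE2", "CZ2"), ("CE3", "HE3"), ("CE3", "CZ3"),
     ("CZ2", "HZ2"), ("CZ2", "CH2"), ("CZ3", "HZ3"), ("CZ3", "CH2"),
     ("CH2", "HH2")],
)

_T["TYR"] = (
    [("CB", "C", -0.20, "beta"), ("HB1", "H", 0.10, "beta"), ("HB2", "H", 0.10, "beta"),
     ("CG", "C", 0.00, "ring"), ("CD1", "C", -0.10, "ring"), ("HD1", "H", 0.10, "ring"),
     ("CD2", "C", -0.10, "ring"), ("HD2", "H", 0.10, "ring"),
     ("CE1", "C", -0.10, "ring"), ("HE1", "H", 0.10, "ring"),
     ("CE2", "C", -0.10, "ring"), ("HE2", "H", 0.10, "ring"),
     ("CZ", "C", 0.15, "hydroxyl"), ("OH", "O", -0.55, "hydroxyl"),
     ("HH", "H", 0.40, "hydroxyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "HB2"), ("CB", "CG"),
     ("CG", "CD1"), ("CG", "CD2"), ("CD1", "HD1"), ("CD1", "CE1"),
     ("CD2", "HD2"), ("CD2", "CE2"), ("CE1", "HE1"), ("CE1", "CZ"),
     ("CE2", "HE2"), ("CE2", "CZ"), ("CZ", "OH"), ("OH", "HH")],
)

_T["VAL"] = (
    [("CB", "C", -0.10, "beta"), ("HB1", "H", 0.10, "beta"),
     ("CG1", "C", -0.30, "gamma1_methyl"), ("HG11", "H", 0.10, "gamma1_methyl"),
     ("HG12", "H", 0.10, "gamma1_methyl"), ("HG13", "H", 0.10, "gamma1_methyl"),
     ("CG2", "C", -0.30, "gamma2_methyl"), ("HG21", "H", 0.10, "gamma2_methyl"),
     ("HG22", "H", 0.10, "gamma2_methyl"), ("HG23", "H", 0.10, "gamma2_methyl")],
    [("CA", "CB"), ("CB", "HB1"), ("CB", "CG1"), ("CB", "CG2"),
     ("CG1", "HG11"), ("CG1", "HG12"), ("CG1", "HG13"),
     ("CG2", "HG21"), ("CG2", "HG22"), ("CG2", "HG23")],
)


def standard_residues() -> list[str]:
    """Three-letter codes of the 20 standard residues with templates."""
    return sorted(_T)


def sidechain_graph(residue: str) -> FragmentGraph:
    """Build the anchored sidechain graph for a standard residue.

    ``residue`` may be a one- or three-letter code.  The returned graph
    includes the Calpha anchor (charge 0, group ``anchor``).
    """
    name = residue.upper()
    if len(name) == 1:
        name = ONE_TO_THREE.get(name, name)
    if name not in _T:
        raise ValidationError(f"unknown residue {residue!r}")
    atoms_spec, bonds = _T[name]
    atoms = (AtomNode("CA", "C", 0.0, "anchor"),) + tuple(
        AtomNode(i, e, q, g) for i, e, q, g in atoms_spec)
    return FragmentGraph(atoms, tuple(bonds), anchor="CA")


def alanine_target() -> FragmentGraph:
    """Alanine as a common target fragment.

    Only the atoms shared with every other sidechain (CA, CB, HB1) are
    listed; the remaining beta hydrogens of the real end state are created by
    the final recharge stage of the plan.
    """
    atoms = (AtomNode("CA", "C", 0.0, "anchor"),
             AtomNode("CB", "C", -0.10, "beta"),
             AtomNode("HB1", "H", 0.10, "beta"))
    bonds = (("CA", "CB"), ("CB", "HB1"))
    return FragmentGraph(atoms, bonds, anchor="CA")
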