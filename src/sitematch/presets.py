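"""Bundled residue representations and their generators.

Three presets ship with the package, mirroring structure descriptions in
common use for local comparison:

* ``coarse_ca`` — one point per residue at the CA, any residue matches any
  other.  The description fold-comparison methods use; also effective for
  main-chain-anchored binding sites (anion nests and similar).
* ``ca_centroid_blosum`` — CA plus the geometric centroid of the side
  chain, substitutions restricted to residue pairs scoring at least -1 in
  BLOSUM62.  Residues pair as single entities, so the extra point costs no
  search time.
* ``chemgroups`` — side-chain chemical groups (carboxylate, amide,
  guanidinium, hydroxyl, imidazole, aromatic ring, sulfur, aliphatic) as
  independent pseudoatoms, with no main-chain matches; one residue may
  match several residues through different groups.

``ca_centroid_blosum.rep`` is generated from the BLOSUM62 substitution
matrix (one equivalence rule per allowed residue pair); glycine, which has
no side chain, carries a degenerate side-chain centroid at its CA so that
every rule pairs two points.
"""

from __future__ import annotations

from importlib import resources

from .representation import Representation, parse_representation

__all__ = [
    "PRESET_NAMES",
    "load_preset",
    "preset_text",
    "generate_coarse_ca",
    "generate_ca_centroid_blosum",
    "generate_chemgroups",
]

PRESET_NAMES = ("coarse_ca", "ca_centroid_blosum", "chemgroups")

STANDARD_AA = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

_ONE_LETTER = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

_SIDE_CHAIN = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": ("CA",),  # degenerate side-chain centroid
    "HIS": ("CB", "CG", "ND1", "CD2", "CE1", "NE2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "LYS": ("CB", "CG", "CD", "CE", "NZ"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PHE": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "PRO": ("CB", "CG", "CD"),
    "SER": ("CB", "OG"),
    "THR": ("CB", "OG1", "CG2"),
    "TRP": ("CB", "CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "TYR": ("CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"),
    "VAL": ("CB", "CG1", "CG2"),
}


def generate_coarse_ca() -> str:
    return (
        "# Coarse representation: CA only, any residue substitution.\n"
        "mode grouped\n"
        "def * CA\n"
        "* *\n"
    )


def generate_ca_centroid_blosum(min_score: int = -1) -> str:
    """CA + side-chain centroid, substitutions with BLOSUM62 >= min_score."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    lines = [
        "# CA + side-chain centroid; substitutions restricted to BLOSUM62 >= "
        f"{min_score}.",
        "mode grouped",
    ]
    for res in STANDARD_AA:
        atoms = ",".join(_SIDE_CHAIN[res])
        lines.append(f"def {res} CA avg({atoms}):SCC")
    for i, ra in enumerate(STANDARD_AA):
        for rb in STANDARD_AA[i:]:
            score = blosum[_ONE_LETTER[ra], _ONE_LETTER[rb]]
            if score >= min_score:
                lines.append(ra if ra == rb else f"{ra} {rb}")
    return "\n".join(lines) + "\n"


def generate_chemgroups() -> str:
    """Side-chain chemical groups as independent pseudoatoms, no main chain.

    Glycine, having no side chain, is represented by its CA and restricted
    to matching other glycines so the preset still covers all 20 residues
    without introducing cross-residue main-chain matches.
    """
    return "\n".join(
        [
            "# Side-chain chemical groups, matched as independent entities.",
            "mode independent",
            "def ALA CB",
            "def ARG avg(NE,CZ,NH1,NH2):GUA",
            "def ASN avg(OD1,ND2):AMI",
            "def ASP avg(OD1,OD2):CRX",
            "def CYS SG",
            "def GLN avg(OE1,NE2):AMI",
            "def GLU avg(OE1,OE2):CRX",
            "def GLY CA",
            "def HIS avg(ND1,NE2):IMI avg(CG,ND1,CD2,CE1,NE2):RING",
            "def ILE avg(CG2,CD1):ALI",
            "def LEU avg(CD1,CD2):ALI",
            "def LYS NZ",
            "def MET SD",
            "def PHE avg(CG,CD1,CD2,CE1,CE2,CZ):RING",
            "def PRO avg(CB,CG,CD):ALI",
            "def SER OG",
            "def THR OG1",
            "def TRP NE1 avg(CD2,CE2,CE3,CZ2,CZ3,CH2):RING",
            "def TYR OH avg(CG,CD1,CD2,CE1,CE2,CZ):RING",
            "def VAL avg(CG1,CG2):ALI",
            "# hydroxyl / hydrogen-bonding oxygens",
            "SER THR TYR.(OH)",
            "# carboxylates",
            "ASP GLU",
            "# amides",
            "ASN GLN",
            "# aromatic ring centroids",
            "PHE.(RING) TYR.(RING) TRP.(RING) HIS.(RING)",
            "# positively chargeable / donor nitrogens",
            "LYS ARG.(GUA) HIS.(IMI) TRP.(NE1)",
            "# sulfur",
            "CYS MET",
            "# aliphatic side chains",
            "ALA VAL.(ALI) LEU.(ALI) ILE.(ALI) PRO.(ALI)",
            "# glycine matches glycine only",
            "GLY",
            "",
        ]
    )


_GENERATORS = {
    "coarse_ca": generate_coarse_ca,
    "ca_centroid_blosum": generate_ca_centroid_blosum,
    "chemgroups": generate_chemgroups,
}


def preset_text(name: str) -> str:
    """Raw text of a shipped preset file."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return resources.files("sitematch").joinpath("presets", f"{name}.rep").read_text()


def load_preset(name: str) -> Representation:
    """Parse a shipped preset into a Representation."""
    return parse_representation(preset_text(name), name=name)
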