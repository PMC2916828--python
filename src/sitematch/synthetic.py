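"""Synthetic PDB-like structures, planted-motif pairs, and decoy libraries.

The generator produces geometrically plausible toy structures: residues
carry real backbone and side-chain atom names, CA positions are packed with
a minimum separation, and side-chain atoms sit at idealized offsets from
the CA.  It makes no claim to stereochemistry — bond geometry and
Ramachandran validity are not modelled — which is sufficient for exercising
representation projection, superposition and search, and deliberately no
more.  Planted-motif pairs embed a shared residue constellation into two
decoy clouds, with the second copy rigidly moved and Gaussian-perturbed, and
return the ground-truth correspondence for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structure import Atom, Residue, StructureModel, model_to_pdb

__all__ = ["MotifSpec", "make_structure", "plant_motif", "make_ligand_complex", "SIDE_CHAIN_ATOMS"]

SIDE_CHAIN_ATOMS: dict[str, tuple[str, ...]] = {
    "ALA": ("CB",),
    "ARG": ("CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"),
    "ASN": ("CB", "CG", "OD1", "ND2"),
    "ASP": ("CB", "CG", "OD1", "OD2"),
    "CYS": ("CB", "SG"),
    "GLN": ("CB", "CG", "CD", "OE1", "NE2"),
    "GLU": ("CB", "CG", "CD", "OE1", "OE2"),
    "GLY": (),
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

STANDARD_AA = tuple(sorted(SIDE_CHAIN_ATOMS))

_ELEMENT_OVERRIDES = {"N": "N", "O": "O", "S": "S"}


def _element_of(atom_name: str) -> str:
    return _ELEMENT_OVERRIDES.get(atom_name[0], atom_name[0])


@dataclass(frozen=True)
class MotifSpec:
    """Conditions for a planted-motif experiment."""

    k: int = 8
    residue_names: tuple[str, ...] = ()
    noise_sigma: float = 0.1  # Angstrom, isotropic per coordinate
    decoys: int = 30  # per side
    seed: int = 0
    box_size: float | None = None  # Angstrom; None = protein-like density

    def __post_init__(self):
        if self.k < 1 or self.noise_sigma < 0 or self.decoys < 0:
            raise ValueError("invalid motif spec")


def _default_box(n_residues: int, vol_per_residue: float = 120.0) -> float:
    # 120 A^3 per residue is the packing density of folded protein cores
    return max(10.0, (vol_per_residue * n_residues) ** (1.0 / 3.0))


# Residues selected around a binding site line a pocket rather than fill a
# core; ~400 A^3 per residue matches that patch-like spread.  It is also the
# regime in which a planted-motif experiment is well-posed: at core packing
# density an 8-point constellation within a 0.7 A threshold is no longer
# rare among random decoys, so chance matches outgrow the motif itself.
_SITE_VOLUME_PER_RESIDUE = 400.0


def _sample_ca_positions(
    rng: np.random.Generator, n: int, box: float, min_dist: float = 3.5, existing=None
) -> np.ndarray:
    placed = [] if existing is None else [np.asarray(p) for p in existing]
    out = []
    for _ in range(n):
        for _attempt in range(2000):
            p = rng.uniform(0.0, box, size=3)
            if all(np.linalg.norm(p - q) >= min_dist for q in placed):
                placed.append(p)
                out.append(p)
                break
        else:
            raise RuntimeError(f"could not pack {n} CA positions into a {box:.1f} A box")
    return np.array(out)


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _residue_atoms(rng: np.random.Generator, name: str, ca: np.ndarray) -> list[Atom]:
    atoms = [Atom("CA", "C", tuple(ca))]
    atoms.insert(0, Atom("N", "N", tuple(ca + 1.46 * _unit(rng))))
    c = ca + 1.52 * _unit(rng)
    atoms.append(Atom("C", "C", tuple(c)))
    atoms.append(Atom("O", "O", tuple(c + 1.23 * _unit(rng))))
    side = SIDE_CHAIN_ATOMS[name]
    if side:
        direction = _unit(rng)
        prev = ca
        for i, an in enumerate(side):
            step = direction * 1.5 + 0.6 * _unit(rng)
            pos = prev + step / np.linalg.norm(step) * 1.5
            atoms.append(Atom(an, _element_of(an), tuple(pos)))
            prev = pos if an.startswith(("C", "S")) else prev
    return atoms


def _assemble(model_id: str, names, ca_positions, rng) -> StructureModel:
    residues = []
    for i, (name, ca) in enumerate(zip(names, ca_positions), start=1):
        residues.append(
            Residue(
                name=name,
                seq_id=i,
                icode="",
                chain_id="A",
                atoms=_residue_atoms(rng, name, np.asarray(ca)),
            )
        )
    return StructureModel(id=model_id, chains={"A": residues})


def make_structure(
    n_residues: int,
    residue_alphabet=STANDARD_AA,
    seed: int = 0,
    box_size: float | None = None,
    model_id: str = "synthetic",
) -> tuple[StructureModel, str]:
    """A random toy structure plus its PDB text, deterministic per seed.

    CA positions are sampled uniformly in a cubic box (protein-like density
    by default) with a 3.5 A minimum CA-CA separation.
    """
    if n_residues < 1:
        raise ValueError("need at least one residue")
    rng = np.random.default_rng(seed)
    box = box_size if box_size is not None else _default_box(n_residues)
    names = [residue_alphabet[i] for i in rng.integers(0, len(residue_alphabet), n_residues)]
    cas = _sample_ca_positions(rng, n_residues, box)
    model = _assemble(model_id, names, cas, rng)
    return model, model_to_pdb(model)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


@dataclass
class PlantedMotif:
    model_a: StructureModel
    model_b: StructureModel
    # ground truth as ((chain, seq_id) in A, (chain, seq_id) in B) pairs
    correspondence: list[tuple[tuple[str, int], tuple[str, int]]] = field(default_factory=list)


def plant_motif(spec: MotifSpec, motif_ca=None) -> PlantedMotif:
    """Embed one k-residue motif in two decoy structures.

    Both structures contain the same motif constellation; the second copy is
    perturbed by isotropic Gaussian noise of ``noise_sigma`` per coordinate
    and a random proper rigid motion, and each copy is surrounded by
    ``decoys`` unrelated residues.  Residue order within each chain is
    shuffled so recovery cannot rely on sequence position.

    ``motif_ca`` fixes the motif CA constellation (a (k, 3) array) instead
    of sampling one — used to implant one motif into many independent decoy
    structures, e.g. when building a screening library.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.residue_names) or [
        STANDARD_AA[i] for i in rng.integers(0, len(STANDARD_AA), spec.k)
    ]
    if len(names) != spec.k:
        raise ValueError("residue_names length must equal k")
    n_total = spec.k + spec.decoys
    box = (
        spec.box_size
        if spec.box_size is not None
        else _default_box(n_total, _SITE_VOLUME_PER_RESIDUE)
    )

    if motif_ca is not None:
        motif_ca = np.asarray(motif_ca, dtype=float)
        if motif_ca.shape != (spec.k, 3):
            raise ValueError("motif_ca must have shape (k, 3)")
    else:
        motif_ca = _sample_ca_positions(rng, spec.k, box)

    def build_side(motif_coords, tag):
        decoy_ca = (
            _sample_ca_positions(rng, spec.decoys, box, existing=motif_coords)
            if spec.decoys
            else np.empty((0, 3))
        )
        all_names = names + [
            STANDARD_AA[i] for i in rng.integers(0, len(STANDARD_AA), spec.decoys)
        ]
        all_ca = np.concatenate([motif_coords, decoy_ca])
        order = rng.permutation(n_total)
        names_p = [all_names[i] for i in order]
        ca_p = all_ca[order]
        model = _assemble(f"planted_{tag}_{spec.seed}", names_p, ca_p, rng)
        # seq_id of original index i is position-of-i-in-order + 1
        seqid_of = {int(orig): int(pos) + 1 for pos, orig in enumerate(order)}
        return model, [seqid_of[i] for i in range(spec.k)]

    model_a, motif_ids_a = build_side(motif_ca, "a")

    rot = _random_rotation(rng)
    trans = rng.uniform(-20.0, 20.0, size=3)
    moved = motif_ca @ rot.T + trans + rng.normal(0.0, spec.noise_sigma, size=motif_ca.shape)
    model_b, motif_ids_b = build_side(moved, "b")

    corr = [
        (("A", ia), ("A", ib)) for ia, ib in zip(motif_ids_a, motif_ids_b)
    ]
    return PlantedMotif(model_a=model_a, model_b=model_b, correspondence=corr)


def make_ligand_complex(
    model: StructureModel,
    ligand_name: str,
    element: str,
    anchor_residues: list[tuple[str, int]],
    distance: float,
    seed: int = 0,
) -> StructureModel:
    """Add a one-atom hetero ligand at a set distance from the first anchor.

    The atom is placed ``distance`` Angstroms from the first atom of the
    first anchor residue, in a direction that leaves it at least 1.0 A from
    every other atom; placement failure raises ``RuntimeError``.
    """
    rng = np.random.default_rng(seed)
    anchors = {(c, s) for c, s in anchor_residues}
    first = None
    for res in model.polymer_residues():
        if (res.chain_id, res.seq_id) in anchors:
            first = res
            break
    if first is None:
        raise ValueError("anchor residues not found in model")
    origin = first.atoms[0].xyz
    others = np.array(
        [a.xyz for r in model.polymer_residues() for a in r.atoms]
        + [a.xyz for r in model.ligands for a in r.atoms]
    )
    for _attempt in range(500):
        pos = origin + distance * _unit(rng)
        d = np.linalg.norm(others - pos, axis=1)
        if (d >= 1.0).all():
            lig = Residue(
                name=ligand_name,
                seq_id=max((r.seq_id for r in model.polymer_residues()), default=0) + 100,
                icode="",
                chain_id=first.chain_id,
                atoms=[Atom(element.upper(), element.upper(), tuple(pos), is_hetero=True)],
            )
            out = StructureModel(
                id=model.id, chains=dict(model.chains), ligands=list(model.ligands) + [lig]
            )
            return out
    raise RuntimeError("could not place ligand atom without a clash")
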