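"""Projection of a selected structure into its pseudoatom representation.

Each selected residue that resolves to a definition contributes pseudoatoms
per that definition's recipes; the pseudoatoms are grouped into match units
— whole residues in grouped mode, single pseudoatoms in independent-atom
mode — which are the elements the search pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .representation import Representation, resolve_def
from .structure import Residue, Selection, StructureModel, select_residues

logger = logging.getLogger(__name__)

__all__ = ["Pseudoatom", "MatchUnit", "PseudoatomSet", "centroid", "build_pseudoatoms", "dump_pseudoatoms_pdb"]


@dataclass(frozen=True)
class Pseudoatom:
    coords: np.ndarray
    recipe_name: str
    residue_ref: tuple[str, int, str, str]  # chain, seq_id, icode, residue name
    pattern_tag: Optional[str] = None  # set for '\' wildcard products


@dataclass
class MatchUnit:
    """Smallest independently pairable element of a representation.

    Grouped mode: all pseudoatoms of one residue.  Independent mode: a
    single pseudoatom.
    """

    unit_id: int
    residue_ref: tuple[str, int, str, str]
    pseudoatoms: list[Pseudoatom] = field(default_factory=list)

    @property
    def residue_name(self) -> str:
        return self.residue_ref[3]

    @property
    def residue_label(self) -> str:
        chain, seq, icode, name = self.residue_ref
        return f"{chain}:{name}:{seq}{icode}"

    def get(self, recipe_name: str) -> Optional[Pseudoatom]:
        for p in self.pseudoatoms:
            if p.recipe_name == recipe_name:
                return p
        return None

    # identity used for pairing in independent mode: the pattern a wildcard
    # pseudoatom came from, or the recipe name otherwise
    @property
    def recipe_key(self) -> str:
        p = self.pseudoatoms[0]
        return ("\\" + p.pattern_tag) if p.pattern_tag else p.recipe_name


@dataclass
class PseudoatomSet:
    units: list[MatchUnit]
    source: Optional[Selection] = None
    representation: str = ""
    independent: bool = False

    def __len__(self) -> int:
        return len(self.units)

    def n_pseudoatoms(self) -> int:
        return sum(len(u.pseudoatoms) for u in self.units)


def centroid(coords) -> np.ndarray:
    """Arithmetic mean of a non-empty coordinate list, per axis."""
    arr = np.asarray(coords, dtype=float).reshape(-1, 3)
    if len(arr) == 0:
        raise ValueError("centroid of an empty atom list")
    return arr.mean(axis=0)


def _residue_pseudoatoms(res: Residue, rep: Representation) -> list[Pseudoatom]:
    d = resolve_def(res.name, rep)
    if d is None:
        return []
    ref = (res.chain_id, res.seq_id, res.icode, res.name.upper())
    out: list[Pseudoatom] = []
    for recipe in d.recipes:
        if recipe.kind == "atom":
            a = res.get_atom(recipe.atoms[0])
            if a is not None:
                out.append(Pseudoatom(a.xyz, recipe.name, ref))
        elif recipe.kind == "centroid":
            present = [res.get_atom(n) for n in recipe.atoms]
            coords = [a.xyz for a in present if a is not None]
            if coords:
                if len(coords) < len(recipe.atoms):
                    logger.warning(
                        "%s: centroid %s averaged over %d of %d atoms",
                        res.label, recipe.name, len(coords), len(recipe.atoms),
                    )
                out.append(Pseudoatom(centroid(coords), recipe.name, ref))
        else:  # pattern: one pseudoatom per matching atom, named after it
            allow_h = "H" in recipe.pattern
            for a in res.atoms:
                if a.element.upper() in ("H", "D") and not allow_h:
                    continue
                if recipe.pattern in a.name.upper():
                    out.append(Pseudoatom(a.xyz, a.name.upper(), ref, pattern_tag=recipe.pattern))
    return out


def build_pseudoatoms(
    model: StructureModel, sel: Selection, rep: Representation
) -> PseudoatomSet:
    """Project the selected residues of a model into a PseudoatomSet.

    Residues without a resolvable definition are excluded; residues whose
    recipes yield no pseudoatom (all atoms missing) are dropped with a
    warning.  Missing atoms never abort the projection.
    """
    units: list[MatchUnit] = []
    next_id = 0
    for res in select_residues(model, sel):
        if resolve_def(res.name, rep) is None:
            continue
        psa = _residue_pseudoatoms(res, rep)
        if not psa:
            logger.warning("%s: no pseudoatoms could be built, residue dropped", res.label)
            continue
        ref = (res.chain_id, res.seq_id, res.icode, res.name.upper())
        if rep.independent_atoms:
            for p in psa:
                units.append(MatchUnit(unit_id=next_id, residue_ref=ref, pseudoatoms=[p]))
                next_id += 1
        else:
            units.append(MatchUnit(unit_id=next_id, residue_ref=ref, pseudoatoms=psa))
            next_id += 1
    return PseudoatomSet(
        units=units, source=sel, representation=rep.name, independent=rep.independent_atoms
    )


def dump_pseudoatoms_pdb(pset: PseudoatomSet) -> str:
    """Debug dump: pseudoatoms as HETATM records for visual inspection."""
    lines = []
    serial = 1
    for u in pset.units:
        chain, seq, icode, resname = u.residue_ref
        for p in u.pseudoatoms:
            x, y, z = p.coords
            name = p.recipe_name[:4].replace("\\", "X")
            lines.append(
                f"HETATM{serial:5d} {name:<4s} {resname[:3]:<3s}{chain[:1]:>2s}"
                f"{seq:4d}{(icode or ' ')[:1]}   {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            )
            serial += 1
    return "\n".join(lines) + ("\nEND\n" if lines else "END\n")
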