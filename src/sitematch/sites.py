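"""Binding-site selection and site-versus-site comparison.

Binding sites are selected geometrically: a polymer residue belongs to the
site of a ligand when any of its atoms lies within a distance cutoff of any
ligand atom.  This is the standard ligand-contact definition; comparisons of
known site pairs from the literature can be reproduced by selecting contact
residues in both structures and searching under the chosen representation.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .pseudoatoms import PseudoatomSet, build_pseudoatoms
from .representation import Representation
from .search import Match, SearchParams, find_matches
from .structure import Residue, Selection, StructureModel

__all__ = ["ligand_contact_residues", "site_selection", "compare_sites"]

CONTACT_CUTOFF = 4.5  # Angstrom, conventional ligand-contact distance


def ligand_contact_residues(
    model: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    ligand_names: Optional[Sequence[str]] = None,
    chain_id: Optional[str] = None,
) -> list[Residue]:
    """Polymer residues with any atom within ``cutoff`` of a ligand atom.

    ``ligand_names`` restricts which hetero residues count as the ligand
    (default: all non-water ligands); ``chain_id`` restricts the polymer
    side.  Returns residues in chain order.
    """
    want = {n.upper() for n in ligand_names} if ligand_names else None
    lig_coords = []
    for res in model.ligands:
        if res.name.upper() in ("HOH", "WAT", "DOD"):
            continue
        if want is not None and res.name.upper() not in want:
            continue
        lig_coords.extend(a.xyz for a in res.atoms)
    if not lig_coords:
        return []
    lig = np.array(lig_coords)
    out = []
    for res in model.polymer_residues():
        if chain_id is not None and res.chain_id != chain_id:
            continue
        coords = np.array([a.xyz for a in res.atoms])
        d = np.linalg.norm(coords[:, None, :] - lig[None, :, :], axis=-1)
        if d.min() < cutoff:
            out.append(res)
    return out


def site_selection(
    model: StructureModel,
    cutoff: float = CONTACT_CUTOFF,
    ligand_names: Optional[Sequence[str]] = None,
    chain_id: Optional[str] = None,
) -> list[Selection]:
    """Selections (one per chain) covering the ligand-contact residues."""
    residues = ligand_contact_residues(model, cutoff, ligand_names, chain_id)
    by_chain: dict[str, set[int]] = {}
    for res in residues:
        by_chain.setdefault(res.chain_id, set()).add(res.seq_id)
    return [
        Selection(structure=model.id, chain_id=c, residue_ids=frozenset(ids))
        for c, ids in sorted(by_chain.items())
    ]


def compare_sites(
    model_a: StructureModel,
    model_b: StructureModel,
    rep: Representation,
    params: SearchParams | None = None,
    cutoff: float = CONTACT_CUTOFF,
    ligands_a: Optional[Sequence[str]] = None,
    ligands_b: Optional[Sequence[str]] = None,
    chain_a: Optional[str] = None,
    chain_b: Optional[str] = None,
) -> list[Match]:
    """All maximum matches between the ligand-contact sites of two models.

    Contact residues of each model (possibly restricted to one chain and to
    named ligands) are pooled across chains into one pseudoatom set per
    model before searching.
    """
    params = params or SearchParams()

    def build(model, lig_names, chain):
        sels = site_selection(model, cutoff, lig_names, chain)
        units = []
        pset = None
        for sel in sels:
            part = build_pseudoatoms(model, sel, rep)
            units.extend(part.units)
            pset = part
        if pset is None:
            return PseudoatomSet(units=[], representation=rep.name, independent=rep.independent_atoms)
        for i, u in enumerate(units):
            u.unit_id = i
        return PseudoatomSet(
            units=units,
            source=None,
            representation=rep.name,
            independent=rep.independent_atoms,
        )

    set_a = build(model_a, ligands_a, chain_a)
    set_b = build(model_b, ligands_b, chain_b)
    return find_matches(set_a, set_b, rep, params)
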