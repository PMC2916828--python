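"""Database screening: scan a probe motif against many chains and rank hits.

Hits are ranked by decreasing match size first and increasing RMSD second —
RMSD alone separates little because the search extends matches until they
are just under the threshold.  Hits can be validated by an orthogonal
criterion, proximity of a matched residue to a qualifying ligand atom
(e.g. phosphorus within 4.5 A for a phosphate-binding probe), and a ranked
hit list is scored against the validation labels by ROC AUC.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .pseudoatoms import PseudoatomSet, build_pseudoatoms
from .representation import Representation
from .search import Match, SearchBudgetError, SearchParams, find_matches
from .structure import Selection, StructureModel, ligand_atoms, read_pdb

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningHit",
    "screen",
    "filter_background",
    "proximity_validate",
    "roc_auc",
    "hits_to_table",
]


@dataclass
class ScreeningHit:
    target_id: str
    match: Match
    validated: Optional[bool] = None
    min_ligand_distance: float = math.inf

    @property
    def rank_key(self) -> tuple[int, float]:
        return (-self.match.size_units, self.match.rmsd)


def screen(
    probe: PseudoatomSet,
    targets: Sequence[Selection],
    rep: Representation,
    params: SearchParams | None = None,
    loader: Callable[[str], StructureModel] = read_pdb,
) -> list[ScreeningHit]:
    """Compare the probe against every target selection and rank the hits.

    One hit per target with a non-empty result, carrying that target's best
    maximum match.  Unreadable or over-budget targets are logged and
    skipped, never fatal.  The hit order is deterministic — rank key, then
    target id — and independent of the order targets are processed in.
    """
    params = params or SearchParams()
    hits: list[ScreeningHit] = []
    for sel in targets:
        target_id = f"{sel.structure}:{sel.chain_id}"
        try:
            model = loader(sel.structure)
            pset = build_pseudoatoms(model, sel, rep)
            matches = find_matches(probe, pset, rep, params)
        except SearchBudgetError as exc:
            logger.warning("target %s skipped: %s", target_id, exc)
            continue
        except (OSError, ValueError) as exc:
            logger.warning("target %s skipped: %s", target_id, exc)
            continue
        if matches:
            hits.append(ScreeningHit(target_id=target_id, match=matches[0]))
    hits.sort(key=lambda h: (h.rank_key, h.target_id))
    return hits


def filter_background(hits: Sequence[ScreeningHit], min_size: int) -> list[ScreeningHit]:
    """Discard background-noise hits smaller than ``min_size`` units.

    Strict less-than: hits of exactly ``min_size`` are retained.  Order is
    preserved.
    """
    return [h for h in hits if h.match.size_units >= min_size]


def proximity_validate(
    hit: ScreeningHit,
    model: StructureModel,
    element: Optional[str] = "P",
    cutoff: float = 4.5,
) -> tuple[bool, float]:
    """Validate a hit by matched-residue proximity to a qualifying ligand atom.

    True iff the minimum distance between any atom of a matched target
    residue and any ligand atom of the given element is strictly below
    ``cutoff`` (no ligands: False with infinite distance).  Updates and
    returns the hit's ``validated`` flag and minimum distance.
    """
    lig = ligand_atoms(model, element_filter=element)
    matched_keys = set()
    for _, label in hit.match.residue_pairs:
        chain, _name, seqid = label.split(":")
        matched_keys.add((chain, seqid))
    atoms = []
    for res in model.polymer_residues():
        icode = res.icode.strip()
        if (res.chain_id, f"{res.seq_id}{icode}") in matched_keys:
            atoms.extend(a.xyz for a in res.atoms)
    if not lig or not atoms:
        hit.validated = False
        hit.min_ligand_distance = math.inf
        return False, math.inf
    pa = np.array(atoms)
    pl = np.array([a.xyz for a in lig])
    d = np.linalg.norm(pa[:, None, :] - pl[None, :, :], axis=-1)
    dmin = float(d.min())
    hit.validated = dmin < cutoff
    hit.min_ligand_distance = dmin
    return hit.validated, dmin


def roc_auc(ranked_labels: Sequence[bool], rank_keys: Optional[Sequence] = None) -> float:
    """Area under the ROC curve of a ranked boolean label list.

    ``ranked_labels`` are ordered best-first.  Mann-Whitney formulation:
    AUC = P(positive ranked above negative), ties counted half.  When
    ``rank_keys`` is given, entries sharing a key are tied and share the
    midrank.  Raises ``ValueError`` when one class is absent.
    """
    labels = np.asarray(ranked_labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("undefined AUC: need at least one positive and one negative")
    # score: higher = better-ranked; equal keys get equal scores
    if rank_keys is None:
        scores = -np.arange(len(labels), dtype=float)
    else:
        if len(rank_keys) != len(labels):
            raise ValueError("rank_keys length mismatch")
        uniq: dict = {}
        for k in rank_keys:
            if k not in uniq:
                uniq[k] = -len(uniq)
        scores = np.array([uniq[k] for k in rank_keys], dtype=float)
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # midranks, ascending
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def hits_to_table(hits: Sequence[ScreeningHit]) -> pd.DataFrame:
    """Hit list as a table (one row per hit, TSV-ready)."""
    rows = []
    for h in hits:
        rows.append(
            {
                "target_id": h.target_id,
                "size_units": h.match.size_units,
                "size_pseudoatoms": h.match.size_pseudoatoms,
                "rmsd": round(h.match.rmsd, 4),
                "validated": h.validated,
                "min_ligand_distance": (
                    round(h.min_ligand_distance, 3)
                    if math.isfinite(h.min_ligand_distance)
                    else ""
                ),
                "paired_residues": ";".join(
                    f"{a}={b}" for a, b in h.match.residue_pairs
                ),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "target_id",
            "size_units",
            "size_pseudoatoms",
            "rmsd",
            "validated",
            "min_ligand_distance",
            "paired_residues",
        ],
    )
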