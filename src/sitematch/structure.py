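"""PDB structure reading, residue selection, and ligand access.

Reading is delegated to gemmi; this module applies the policies the rest of
the package relies on: first model only, one conformer per atom (highest
occupancy, ties broken toward blank/'A' altloc), hetero residues routed to a
ligand list unless they are peptide-like (modified amino acids carrying N,
CA and C), and author residue numbering kept verbatim.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "Residue",
    "StructureModel",
    "Selection",
    "read_pdb",
    "read_pdb_string",
    "read_selection_list",
    "select_residues",
    "ligand_atoms",
    "model_to_pdb",
]

WATER_NAMES = {"HOH", "WAT", "DOD"}
_BACKBONE = {"N", "CA", "C"}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    coords: tuple[float, float, float]
    altloc: str = ""
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.coords, dtype=float)


@dataclass
class Residue:
    name: str
    seq_id: int
    icode: str
    chain_id: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_id, self.icode)

    def get_atom(self, name: str) -> Optional[Atom]:
        name = name.upper()
        for a in self.atoms:
            if a.name.upper() == name:
                return a
        return None

    @property
    def label(self) -> str:
        icode = self.icode.strip()
        return f"{self.chain_id}:{self.name}:{self.seq_id}{icode}"


@dataclass
class StructureModel:
    id: str
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    ligands: list[Residue] = field(default_factory=list)

    def polymer_residues(self) -> Iterable[Residue]:
        for residues in self.chains.values():
            yield from residues

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.polymer_residues()) + sum(
            len(r.atoms) for r in self.ligands
        )


@dataclass(frozen=True)
class Selection:
    structure: str  # path or model id
    chain_id: str
    residue_ids: Optional[frozenset[int]] = None  # None = whole chain

    def contains(self, residue: Residue) -> bool:
        if residue.chain_id != self.chain_id:
            return False
        return self.residue_ids is None or residue.seq_id in self.residue_ids


def _prescan(text: str) -> str:
    """Drop coordinate lines with unparseable numeric fields, with a warning."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line) >= 54:
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
                if len(line) >= 60 and line[54:60].strip():
                    float(line[54:60])
            except ValueError:
                logger.warning("line %d: malformed coordinate field, record skipped", lineno)
                continue
        out.append(line)
    return "\n".join(out) + "\n"


def _pick_conformers(res: gemmi.Residue) -> list[gemmi.Atom]:
    """One atom per name: highest occupancy, ties toward blank/'A' altloc."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    chosen = []
    for name, alts in by_name.items():
        alts.sort(key=lambda a: (-a.occ, a.altloc.strip("\x00") or " "))
        chosen.append(alts[0])
    chosen.sort(key=lambda a: a.serial)
    return chosen


def _convert_residue(ch: gemmi.Chain, res: gemmi.Residue) -> Residue:
    atoms = []
    is_het = res.het_flag == "H"
    for a in _pick_conformers(res):
        atoms.append(
            Atom(
                name=a.name,
                element=a.element.name,
                coords=(a.pos.x, a.pos.y, a.pos.z),
                altloc=(a.altloc.strip("\x00") or ""),
                occupancy=float(a.occ),
                is_hetero=is_het,
            )
        )
    return Residue(
        name=res.name,
        seq_id=res.seqid.num,
        icode=(res.seqid.icode or " ").strip() or "",
        chain_id=ch.name,
        atoms=atoms,
    )


def read_pdb_string(text: str, model_id: str = "model") -> StructureModel:
    """Parse PDB-format text into a StructureModel (first model only)."""
    st = gemmi.read_pdb_string(_prescan(text))
    if len(st) == 0:
        raise ValueError(f"{model_id}: no coordinate records")
    gmodel = st[0]
    model = StructureModel(id=model_id)
    n_atoms = 0
    for ch in gmodel:
        for gres in ch:
            res = _convert_residue(ch, gres)
            n_atoms += len(res.atoms)
            peptide_like = _BACKBONE.issubset({a.name for a in res.atoms})
            if gres.het_flag == "H" and not peptide_like:
                model.ligands.append(res)
            else:
                model.chains.setdefault(ch.name, []).append(res)
    if n_atoms == 0:
        raise ValueError(f"{model_id}: no coordinate records")
    return model


def read_pdb(path: str | os.PathLike) -> StructureModel:
    """Read a PDB file from disk.

    Keeps model 1 of multi-model files, the highest-occupancy alternate
    conformer, and hydrogens; HETATM residues go to ``ligands`` unless they
    are peptide-like (modified amino acids in the chain).
    """
    path = os.fspath(path)
    try:
        with open(path) as fh:
            text = fh.read()
    except OSError as exc:
        raise ValueError(f"cannot read structure file {path!r}: {exc}") from exc
    model_id = os.path.splitext(os.path.basename(path))[0]
    return read_pdb_string(text, model_id=model_id)


def _parse_ranges(spec: str) -> frozenset[int]:
    ids: set[int] = set()
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part[1:]:  # allow negative seq ids
            lo_s, hi_s = part[1:].split("-", 1)
            lo = int(part[0] + lo_s)
            hi = int(hi_s)
            if hi < lo:
                raise ValueError(f"empty residue range {part!r}")
            ids.update(range(lo, hi + 1))
        else:
            ids.add(int(part))
    return frozenset(ids)


def read_selection_list(path: str | os.PathLike, base_dir: Optional[str] = None) -> list[Selection]:
    """Parse a selection list file: one ``structure [chain [ranges]]`` per line.

    An omitted chain expands to one Selection per chain of the structure
    (the file is read to enumerate them); omitted ranges mean the whole
    chain.  Ranges are comma-separated and inclusive, e.g. ``10-20,25``.
    Raises ``ValueError`` for a missing structure file or unknown chain.
    """
    path = os.fspath(path)
    if base_dir is None:
        base_dir = os.path.dirname(path)
    selections: list[Selection] = []
    cache: dict[str, StructureModel] = {}

    def load(p: str) -> StructureModel:
        if p not in cache:
            cache[p] = read_pdb(p)
        return cache[p]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            tokens = line.split()
            spath = tokens[0]
            if not os.path.isabs(spath):
                spath = os.path.join(base_dir, spath)
            model = load(spath)  # missing file surfaces here with the path
            if len(tokens) == 1:
                for chain_id in model.chains:
                    selections.append(Selection(structure=spath, chain_id=chain_id))
                continue
            chain_id = tokens[1]
            if chain_id not in model.chains:
                raise ValueError(
                    f"line {lineno}: unknown chain {chain_id!r} in {tokens[0]}"
                )
            if len(tokens) == 2:
                selections.append(Selection(structure=spath, chain_id=chain_id))
            else:
                try:
                    ids = _parse_ranges(" ".join(tokens[2:]).replace(" ", ""))
                except ValueError as exc:
                    raise ValueError(f"line {lineno}: bad residue range: {exc}") from exc
                selections.append(
                    Selection(structure=spath, chain_id=chain_id, residue_ids=ids)
                )
    return selections


def select_residues(model: StructureModel, sel: Selection) -> list[Residue]:
    """Residues of the model covered by the selection, in chain order."""
    if sel.chain_id not in model.chains:
        raise ValueError(f"{model.id}: unknown chain {sel.chain_id!r}")
    return [r for r in model.chains[sel.chain_id] if sel.contains(r)]


def ligand_atoms(model: StructureModel, element_filter: Optional[str] = None) -> list[Atom]:
    """Atoms of the model's ligand residues, water excluded.

    ``element_filter`` restricts to one element symbol (case-insensitive),
    e.g. ``"P"`` for phosphorus-proximity validation.
    """
    out = []
    want = element_filter.upper() if element_filter else None
    for res in model.ligands:
        if res.name.upper() in WATER_NAMES:
            continue
        for a in res.atoms:
            if want is None or a.element.upper() == want:
                out.append(a)
    return out


def model_to_pdb(model: StructureModel, transform=None) -> str:
    """Render a StructureModel as PDB text (via gemmi).

    ``transform`` optionally applies a :class:`~sitematch.superpose.Superposition`
    to every coordinate before writing (used for superposed-target output).
    """
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")

    def add(chain: gemmi.Chain, res: Residue, hetero: bool):
        gres = gemmi.Residue()
        gres.name = res.name
        gres.seqid = gemmi.SeqId(res.seq_id, res.icode or " ")
        gres.het_flag = "H" if hetero else "A"
        for a in res.atoms:
            ga = gemmi.Atom()
            ga.name = a.name
            xyz = a.xyz if transform is None else transform.apply(a.xyz)
            xyz = np.atleast_2d(xyz)[0]
            ga.pos = gemmi.Position(*map(float, xyz))
            ga.element = gemmi.Element(a.element or a.name[0])
            ga.occ = a.occupancy
            gres.add_atom(ga)
        chain.add_residue(gres)

    # one gemmi chain per chain id, polymer residues first, then ligands
    by_chain: dict[str, list[tuple[Residue, bool]]] = {}
    for chain_id, residues in model.chains.items():
        by_chain.setdefault(chain_id, []).extend((r, False) for r in residues)
    for res in model.ligands:
        by_chain.setdefault(res.chain_id or "L", []).append((res, True))
    for chain_id, entries in by_chain.items():
        ch = gemmi.Chain(chain_id)
        for res, hetero in entries:
            add(ch, res, hetero)
        gmodel.add_chain(ch)
    st.add_model(gmodel)
    return st.make_pdb_string()
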