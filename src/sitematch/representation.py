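"""The residue-definition mini-language.

A representation file tells the program how residues are projected into
pseudoatoms and which residues (or residue fragments) are allowed to pair.
The grammar is line-oriented:

* ``def RES item [item ...]`` — define the pseudoatoms representing residue
  ``RES`` (a 3-letter code, or ``*`` meaning "any residue without a more
  specific definition").  Each item is a PDB atom name (``CA``), a centroid
  ``avg(A1,A2,...):NAME`` over a list of atom names, or a name pattern
  ``\\SUB`` selecting every atom whose name contains ``SUB``.  Items may also
  be joined with ``;`` (``\\N;\\O`` is two pattern items).
* an equivalence line — a whitespace-separated list of members, each ``RES``
  or ``RES.(recipe[,recipe...])``, declaring those residues (restricted to
  the named fragments, in the written order) mutually matchable.  Pseudoatoms
  are paired in the order they appear.
* ``mode independent|grouped`` — whether each pseudoatom is matched as an
  independent unit or all of a residue's pseudoatoms move together.
* ``#`` starts a comment; blank lines are ignored.

Residue and atom names are case-insensitive and stored uppercased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = [
    "PseudoatomRecipe",
    "ResidueDef",
    "EquivalenceRule",
    "Representation",
    "RepresentationError",
    "parse_representation",
    "serialize_representation",
    "resolve_def",
    "allowed_pairings",
]

WILDCARD = "*"


class RepresentationError(ValueError):
    """Malformed or inconsistent residue-definition input."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class PseudoatomRecipe:
    """How one pseudoatom of a residue is computed.

    kind is ``atom`` (a single named atom), ``centroid`` (geometric centroid
    of the listed atoms) or ``pattern`` (every atom whose name contains the
    substring — one pseudoatom per matching atom).
    """

    name: str
    kind: str  # atom | centroid | pattern
    atoms: tuple[str, ...] = ()
    pattern: str = ""

    def __post_init__(self):
        if self.kind == "centroid" and not self.atoms:
            raise RepresentationError(f"centroid recipe {self.name!r} lists no atoms")


@dataclass(frozen=True)
class ResidueDef:
    residue_name: str
    recipes: tuple[PseudoatomRecipe, ...]

    def __post_init__(self):
        if not self.recipes:
            raise RepresentationError(f"def {self.residue_name} has no pseudoatoms")
        names = [r.name for r in self.recipes]
        if len(set(names)) != len(names):
            raise RepresentationError(
                f"duplicate pseudoatom name in def {self.residue_name}"
            )

    def recipe_names(self) -> tuple[str, ...]:
        return tuple(r.name for r in self.recipes)


@dataclass(frozen=True)
class EquivalenceRule:
    """A set of mutually matchable residues, optionally fragment-restricted.

    members are ``(residue_name, fragment)`` where fragment is None (use all
    of the residue's recipes, in definition order) or an ordered tuple of
    recipe names.
    """

    members: tuple[tuple[str, Optional[tuple[str, ...]]], ...]


@dataclass
class Representation:
    defs: dict[str, ResidueDef] = field(default_factory=dict)
    rules: tuple[EquivalenceRule, ...] = ()
    independent_atoms: bool = False
    name: str = "custom"


_ATOM_RE = re.compile(r"^[A-Z0-9'\*]+$")
_AVG_RE = re.compile(r"^AVG\((?P<atoms>[^)]+)\):(?P<name>\S+)$", re.IGNORECASE)
_MEMBER_RE = re.compile(r"^(?P<res>[^.\s]+)(?:\.\((?P<frag>[^)]+)\))?$")


def _parse_recipe_item(item: str, lineno: int) -> PseudoatomRecipe:
    m = _AVG_RE.match(item)
    if m:
        atoms = tuple(a.strip().upper() for a in m.group("atoms").split(","))
        if any(not a for a in atoms):
            raise RepresentationError(f"empty atom name in {item!r}", lineno)
        return PseudoatomRecipe(name=m.group("name").upper(), kind="centroid", atoms=atoms)
    if item.startswith("\\"):
        sub = item[1:].upper()
        if not sub:
            raise RepresentationError("empty pattern after backslash", lineno)
        return PseudoatomRecipe(name="\\" + sub, kind="pattern", pattern=sub)
    atom = item.upper()
    if not _ATOM_RE.match(atom):
        raise RepresentationError(f"malformed pseudoatom item {item!r}", lineno)
    return PseudoatomRecipe(name=atom, kind="atom", atoms=(atom,))


def _member_fragment_len(
    member: tuple[str, Optional[tuple[str, ...]]], defs: dict[str, ResidueDef]
) -> Optional[int]:
    res, frag = member
    if frag is not None:
        return len(frag)
    d = defs.get(res)
    return len(d.recipes) if d is not None else None


def parse_representation(text: str, name: str = "custom") -> Representation:
    """Parse residue-definition file content into a validated Representation.

    Raises :class:`RepresentationError` (with the offending line number) on
    malformed statements, duplicate residue defs, equivalences with
    mismatched fragment counts, or references to undefined residues/recipes.
    """
    defs: dict[str, ResidueDef] = {}
    raw_rules: list[tuple[int, tuple[tuple[str, Optional[tuple[str, ...]]], ...]]] = []
    mode: Optional[bool] = None

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        head = tokens[0].lower()
        if head == "def":
            if len(tokens) < 3:
                raise RepresentationError("def needs a residue name and >=1 item", lineno)
            res = tokens[1].upper()
            if res in defs:
                raise RepresentationError(f"duplicate definition for {res}", lineno)
            items: list[str] = []
            for tok in tokens[2:]:
                items.extend(p for p in tok.split(";") if p)
            recipes = tuple(_parse_recipe_item(it, lineno) for it in items)
            try:
                defs[res] = ResidueDef(residue_name=res, recipes=recipes)
            except RepresentationError as exc:
                raise RepresentationError(str(exc), lineno) from None
        elif head == "mode":
            if len(tokens) != 2 or tokens[1].lower() not in ("independent", "grouped"):
                raise RepresentationError("mode must be 'independent' or 'grouped'", lineno)
            mode = tokens[1].lower() == "independent"
        else:
            members = []
            for tok in tokens:
                m = _MEMBER_RE.match(tok)
                if not m:
                    raise RepresentationError(f"malformed equivalence member {tok!r}", lineno)
                res = m.group("res").upper()
                frag = m.group("frag")
                frag_t = (
                    tuple(f.strip().upper() for f in frag.split(",")) if frag else None
                )
                members.append((res, frag_t))
            raw_rules.append((lineno, tuple(members)))

    if not defs:
        raise RepresentationError("no residue definitions")

    # validate rules against defs
    rules: list[EquivalenceRule] = []
    for lineno, members in raw_rules:
        lengths = set()
        for res, frag in members:
            d = defs.get(res)
            if d is None and res != WILDCARD:
                raise RepresentationError(f"equivalence references undefined residue {res}", lineno)
            if frag is not None:
                check_def = d if d is not None else defs.get(WILDCARD)
                if check_def is not None:
                    known = set(check_def.recipe_names())
                    for f in frag:
                        if f not in known:
                            raise RepresentationError(
                                f"equivalence references undefined recipe {f!r} of {res}", lineno
                            )
            ln = _member_fragment_len((res, frag), defs)
            if ln is not None:
                lengths.add(ln)
        if len(lengths) > 1:
            raise RepresentationError(
                f"equivalence members pair different numbers of fragments: {sorted(lengths)}",
                lineno,
            )
        rules.append(EquivalenceRule(members=members))

    rep = Representation(
        defs=defs,
        rules=tuple(rules),
        independent_atoms=bool(mode) if mode is not None else False,
        name=name,
    )
    if not rep.independent_atoms:
        for d in defs.values():
            if any(r.kind == "pattern" for r in d.recipes):
                raise RepresentationError(
                    f"pattern recipes (def {d.residue_name}) require 'mode independent': "
                    "ordered residue-level pairing is undefined for a variable "
                    "number of atoms"
                )
    return rep


def serialize_representation(rep: Representation) -> str:
    """Write a Representation back out in the definition-file syntax."""
    lines = [f"mode {'independent' if rep.independent_atoms else 'grouped'}"]
    for res, d in rep.defs.items():
        items = []
        for r in d.recipes:
            if r.kind == "atom":
                items.append(r.name)
            elif r.kind == "pattern":
                items.append("\\" + r.pattern)
            else:
                items.append(f"avg({','.join(r.atoms)}):{r.name}")
        lines.append(f"def {res} {' '.join(items)}")
    for rule in rep.rules:
        toks = []
        for res, frag in rule.members:
            toks.append(res if frag is None else f"{res}.({','.join(frag)})")
        lines.append(" ".join(toks))
    return "\n".join(lines) + "\n"


def resolve_def(residue_name: str, rep: Representation) -> Optional[ResidueDef]:
    """Definition applying to a residue: exact name first, then ``*``, else None.

    A residue that resolves to nothing is simply excluded from the
    representation.
    """
    res = residue_name.upper()
    if res in rep.defs:
        return rep.defs[res]
    return rep.defs.get(WILDCARD)


def _member_matches(member_res: str, residue_name: str, rep: Representation) -> bool:
    if member_res == WILDCARD:
        return resolve_def(residue_name, rep) is not None
    return member_res == residue_name


def _selected_recipes(
    member: tuple[str, Optional[tuple[str, ...]]],
    residue_name: str,
    rep: Representation,
) -> Optional[tuple[PseudoatomRecipe, ...]]:
    d = resolve_def(residue_name, rep)
    if d is None:
        return None
    _, frag = member
    if frag is None:
        return d.recipes
    by_name = {r.name: r for r in d.recipes}
    try:
        return tuple(by_name[f] for f in frag)
    except KeyError:
        return None  # fragment names absent from this residue's def: rule inapplicable


def allowed_pairings(
    residue_a: str, residue_b: str, rep: Representation
) -> list[tuple[tuple[str, str], ...]]:
    """All recipe-to-recipe correspondences the rules allow for a residue pair.

    Returns one correspondence (an ordered tuple of ``(recipe_a, recipe_b)``
    name pairs) per applicable rule-member combination, deduplicated, in rule
    order.  Empty list iff no rule links the two residue names.  A rule
    listing k members allows every ordered member pair, including a member
    with itself, so a single-member rule ``HIS`` makes HIS self-matchable.
    Recipes are paired positionally; a pair of pattern recipes is kept only
    when both sides come from the same pattern (atoms of the same type), and
    a pattern never pairs with a non-pattern recipe.
    """
    ra = residue_a.upper()
    rb = residue_b.upper()
    out: list[tuple[tuple[str, str], ...]] = []
    seen = set()
    for rule in rep.rules:
        for ma in rule.members:
            if not _member_matches(ma[0], ra, rep):
                continue
            sel_a = _selected_recipes(ma, ra, rep)
            if sel_a is None:
                continue
            for mb in rule.members:
                if not _member_matches(mb[0], rb, rep):
                    continue
                sel_b = _selected_recipes(mb, rb, rep)
                if sel_b is None or len(sel_a) != len(sel_b):
                    continue
                pairs = []
                for qa, qb in zip(sel_a, sel_b):
                    pat_a = qa.kind == "pattern"
                    pat_b = qb.kind == "pattern"
                    if pat_a != pat_b:
                        continue
                    if pat_a and qa.pattern != qb.pattern:
                        continue
                    pairs.append((qa.name, qb.name))
                if not pairs:
                    continue
                corr = tuple(pairs)
                if corr not in seen:
                    seen.add(corr)
                    out.append(corr)
    return out
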