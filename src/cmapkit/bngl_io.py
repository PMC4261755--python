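"""Parsing of a practical BNGL subset and plain-text layout position files.

The parser targets the structural content a contact map needs: molecule type
declarations, pattern-based reaction rules, seed species, and observables.
Rate expressions, parameters, and functions are carried or skipped as opaque
text and never evaluated; compartments and energy patterns are out of scope.

Layout position files store element → (x, y) assignments so that a layout
chosen for one model can be pinned across a whole family (and shared between
researchers together with the model files).  The native dialect is::

    #cmapkit-layout v1
    <ElementId> <TAB> <x> <TAB> <y>

Whitespace-delimited ``identifier x y`` triples are also accepted on input.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field

__all__ = [
    "BnglParseError",
    "BnglWarning",
    "LayoutFileError",
    "ComponentDecl",
    "MoleculeType",
    "PatternComponent",
    "PatternMolecule",
    "Rule",
    "Model",
    "StoredLayout",
    "parse_bngl",
    "read_layout_file",
    "write_layout_file",
    "LAYOUT_HEADER",
]

LAYOUT_HEADER = "#cmapkit-layout v1"


class BnglParseError(ValueError):
    """Raised on malformed BNGL input (with rule / line context)."""


class BnglWarning(UserWarning):
    """Non-fatal irregularity in BNGL input (unknown block, new state, ...)."""


class LayoutFileError(ValueError):
    """Raised on malformed layout position files."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class ComponentDecl:
    """A declared component: name, 1-based occurrence index, allowed states."""

    name: str
    occurrence: int
    states: list[str] = field(default_factory=list)


@dataclass
class MoleculeType:
    """A molecule type with its ordered component declarations.

    A molecule declared with no components carries one implicit
    whole-molecule component named after the molecule itself.
    """

    name: str
    components: list[ComponentDecl] = field(default_factory=list)

    def component(self, name: str, occurrence: int) -> ComponentDecl | None:
        for c in self.components:
            if c.name == name and c.occurrence == occurrence:
                return c
        return None


# bond status values
BOND_NONE = "none"
BOND_WILD_BOUND = "+"  # "!+": bound to an unspecified partner
BOND_WILD_ANY = "?"  # "!?": bound or unbound


@dataclass
class PatternComponent:
    name: str
    occurrence: int  # resolved positionally against the declaration
    state: str | None = None
    bond: str = BOND_NONE  # BOND_NONE | numbered tag (str digits) | "+" | "?"


@dataclass
class PatternMolecule:
    name: str
    components: list[PatternComponent] = field(default_factory=list)


@dataclass
class Rule:
    """One reaction rule statement; reversible rules stay a single object."""

    label: str | None
    reactants: list[list[PatternMolecule]]  # one list per complex
    products: list[list[PatternMolecule]]
    reversible: bool
    rate_expressions: list[str]
    is_synthesis: bool = False  # empty reactant side
    is_degradation: bool = False  # empty product side

    def molecules(self, side: str) -> list[PatternMolecule]:
        groups = self.reactants if side == "reactants" else self.products
        return [m for g in groups for m in g]


@dataclass
class Model:
    name: str
    molecule_types: list[MoleculeType] = field(default_factory=list)
    rules: list[Rule] = field(default_factory=list)
    seed_species: list[str] = field(default_factory=list)
    observables: list[tuple[str, str]] = field(default_factory=list)
    source_path: str = ""

    def molecule_type(self, name: str) -> MoleculeType | None:
        for mt in self.molecule_types:
            if mt.name == name:
                return mt
        return None


@dataclass
class StoredLayout:
    """Persistent element → (x, y) assignment in abstract layout units."""

    name: str = ""
    positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    version: str = "v1"


# ---------------------------------------------------------------------------
# pattern-level parsing

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_BLOCK_ALIASES = {
    "parameters": "parameters",
    "molecule types": "molecule types",
    "molecules": "molecule types",
    "species": "seed species",
    "seed species": "seed species",
    "observables": "observables",
    "functions": "functions",
    "reaction rules": "reaction rules",
}
_TOLERATED_BLOCKS = {"parameters", "functions", "compartments", "actions",
                     "energy patterns", "population maps"}


def _parse_component(text: str, where: str, declaration: bool) -> tuple[str, list[str], str]:
    """Parse one component token → (name, states, bond).

    In declaration mode several ``~state`` labels may be listed and bonds are
    rejected; in pattern mode at most one state is allowed.
    """
    m = _NAME_RE.match(text)
    if not m:
        raise BnglParseError(f"{where}: bad component syntax {text!r}")
    name = m.group(0)
    rest = text[m.end():]
    states: list[str] = []
    bond = BOND_NONE
    while rest:
        if rest.startswith("~"):
            sm = re.match(r"~([A-Za-z0-9_]+|\?)", rest)
            if not sm:
                raise BnglParseError(f"{where}: bad state syntax in {text!r}")
            states.append(sm.group(1))
            rest = rest[sm.end():]
        elif rest.startswith("!"):
            bm = re.match(r"!(\d+|\+|\?)", rest)
            if not bm:
                raise BnglParseError(f"{where}: bad bond syntax in {text!r}")
            if bond != BOND_NONE:
                raise BnglParseError(f"{where}: multiple bonds on one component in {text!r}")
            bond = bm.group(1)
            rest = rest[bm.end():]
        elif rest.startswith("%"):  # label tags (e.g. %1) — tolerated, ignored
            lm = re.match(r"%[A-Za-z0-9_]+", rest)
            rest = rest[lm.end():] if lm else ""
        else:
            raise BnglParseError(f"{where}: trailing junk {rest!r} in component {text!r}")
    if declaration and bond != BOND_NONE:
        raise BnglParseError(f"{where}: bond not allowed in a declaration: {text!r}")
    if not declaration and len(states) > 1:
        raise BnglParseError(f"{where}: more than one state on pattern component {text!r}")
    return name, states, bond


def _split_components(body: str, where: str) -> list[str]:
    parts = [p.strip() for p in body.split(",")]
    if parts == [""]:
        return []
    if any(p == "" for p in parts):
        raise BnglParseError(f"{where}: empty component in ({body!r})")
    return parts


def _parse_molecule(text: str, where: str, declaration: bool) -> tuple[str, list[tuple[str, list[str], str]]]:
    text = text.strip()
    m = _NAME_RE.match(text)
    if not m:
        raise BnglParseError(f"{where}: bad molecule syntax {text!r}")
    name = m.group(0)
    rest = text[m.end():]
    if rest == "":
        return name, []
    if not (rest.startswith("(") and rest.endswith(")")):
        raise BnglParseError(f"{where}: bad molecule syntax {text!r}")
    body = rest[1:-1]
    return name, [_parse_component(tok, where, declaration) for tok in _split_components(body, where)]


def _parse_pattern_molecule(text: str, where: str) -> PatternMolecule:
    name, comps = _parse_molecule(text, where, declaration=False)
    seen: dict[str, int] = {}
    out = PatternMolecule(name=name)
    for cname, states, bond in comps:
        seen[cname] = seen.get(cname, 0) + 1
        state = states[0] if states else None
        if state == "?":  # "~?" wildcard: no state constraint
            state = None
        out.components.append(
            PatternComponent(name=cname, occurrence=seen[cname], state=state, bond=bond)
        )
    return out


def _parse_complex(text: str, where: str) -> list[PatternMolecule]:
    return [_parse_pattern_molecule(tok, where) for tok in text.split(".")]


_PLUS_SPLIT = re.compile(r"(?<!!)\+")  # a '+' that is not the '!+' wildcard


def _parse_side(text: str, where: str) -> list[list[PatternMolecule]]:
    text = text.strip()
    if text in ("0", ""):
        return []
    groups = [g.strip() for g in _PLUS_SPLIT.split(text)]
    if any(g == "" for g in groups):
        raise BnglParseError(f"{where}: empty reactant/product term")
    return [_parse_complex(g, where) for g in groups if g != "0"]


def _check_bonds(side: list[list[PatternMolecule]], where: str, side_name: str) -> None:
    counts: dict[str, int] = {}
    for cx in side:
        for mol in cx:
            for pc in mol.components:
                if pc.bond not in (BOND_NONE, BOND_WILD_BOUND, BOND_WILD_ANY):
                    counts[pc.bond] = counts.get(pc.bond, 0) + 1
    for tag, n in sorted(counts.items()):
        if n != 2:
            raise BnglParseError(
                f"{where}: bond tag !{tag} appears {n} time(s) on the {side_name} side "
                f"(must appear exactly twice)"
            )


# ---------------------------------------------------------------------------
# file-level parsing


def _logical_lines(text: str):
    """Yield (line_number, content) with comments stripped and continuations joined."""
    pending = ""
    pending_no = 0
    for no, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].rstrip()
        if pending:
            line = pending + " " + line.lstrip()
            no = pending_no
            pending = ""
        if line.endswith("\\"):
            pending = line[:-1].rstrip()
            pending_no = no
            continue
        if line.strip():
            yield no, line.strip()
    if pending.strip():
        yield pending_no, pending.strip()


_INDEX_RE = re.compile(r"^\d+\s+")
_LABEL_RE = re.compile(r"^([A-Za-z_][A-Za-z0-9_]*)\s*:\s*")


def _strip_index(line: str) -> str:
    return _INDEX_RE.sub("", line)


def _parse_rule_line(line: str, lineno: int) -> Rule:
    where = f"line {lineno}"
    body = _strip_index(line)
    label = None
    lm = _LABEL_RE.match(body)
    # a label is only a label if an arrow follows somewhere after it
    if lm and ("->" in body[lm.end():]):
        label = lm.group(1)
        body = body[lm.end():]
    if "<->" in body:
        reversible = True
        lhs, rhs = body.split("<->", 1)
    elif "->" in body:
        reversible = False
        lhs, rhs = body.split("->", 1)
    else:
        raise BnglParseError(f"{where}: no reaction arrow in rule {line!r}")
    where = f"rule {label or line.strip()!r} ({where})"

    # the product side ends where the rate expression begins: tokens are
    # pattern terms glued by '+'; everything after is opaque rate text
    tokens = rhs.split()
    if not tokens:
        raise BnglParseError(f"{where}: empty product side and no rate")
    expr = tokens[0]
    i = 1
    while i < len(tokens):
        if expr.endswith("+") and not expr.endswith("!+"):
            expr += tokens[i]
            i += 1
        elif tokens[i] == "+":
            if i + 1 >= len(tokens):
                raise BnglParseError(f"{where}: dangling '+' on product side")
            expr += "+" + tokens[i + 1]
            i += 2
        else:
            break
    rate_text = " ".join(tokens[i:]).strip()

    reactants = _parse_side(lhs, where)
    products = _parse_side(expr, where)
    _check_bonds(reactants, where, "reactant")
    _check_bonds(products, where, "product")

    rates = [r.strip() for r in rate_text.split(",") if r.strip()] if rate_text else []
    if reversible and len(rates) != 2:
        raise BnglParseError(
            f"{where}: reversible rule needs two rate expressions, got {len(rates)}"
        )
    return Rule(
        label=label,
        reactants=reactants,
        products=products,
        reversible=reversible,
        rate_expressions=rates,
        is_synthesis=not reactants,
        is_degradation=not products,
    )


def _auto_declare(model: Model, usages: list[PatternMolecule], declared: set[str]) -> None:
    """Declare undeclared molecules from their maximal observed signature and
    extend declarations with states (and components) first seen in patterns.

    Warnings are raised only when a pattern disagrees with an explicit
    declaration; molecules absent from the ``molecule types`` block are
    auto-declared silently (many distributed models omit the block).
    """
    for pm in usages:
        mt = model.molecule_type(pm.name)
        if mt is None:
            mt = MoleculeType(name=pm.name)
            model.molecule_types.append(mt)
        for pc in pm.components:
            decl = mt.component(pc.name, pc.occurrence)
            if decl is None:
                if pm.name in declared:
                    warnings.warn(
                        f"component {pc.name}#{pc.occurrence} of {pm.name} not declared; "
                        f"added to the declaration",
                        BnglWarning,
                        stacklevel=2,
                    )
                decl = ComponentDecl(name=pc.name, occurrence=pc.occurrence)
                mt.components.append(decl)
            if pc.state is not None and pc.state not in decl.states:
                if pm.name in declared:
                    warnings.warn(
                        f"state {pm.name}.{pc.name}~{pc.state} not in declaration; appended",
                        BnglWarning,
                        stacklevel=2,
                    )
                decl.states.append(pc.state)


def parse_bngl(text: str, name: str, source_path: str = "") -> Model:
    """Parse BNGL source into a :class:`Model`.

    Handles ``begin X`` / ``end X`` blocks (``begin model`` optional), ``#``
    comments, and ``\\`` line continuations.  Parameters and functions are
    tolerated and skipped; unknown blocks produce a :class:`BnglWarning`.
    Reversible rules (``<->``) are kept as a single :class:`Rule`.
    """
    model = Model(name=name, source_path=source_path)
    block: str | None = None
    pattern_usages: list[PatternMolecule] = []
    declared: set[str] = set()

    for lineno, line in _logical_lines(text):
        low = re.sub(r"\s+", " ", line.lower())
        if low.startswith("begin "):
            blockname = low[len("begin "):].strip()
            if blockname == "model":
                continue
            canonical = _BLOCK_ALIASES.get(blockname)
            if canonical is None:
                if blockname not in _TOLERATED_BLOCKS:
                    warnings.warn(
                        f"line {lineno}: unknown block {blockname!r} skipped",
                        BnglWarning,
                        stacklevel=2,
                    )
                block = "<skip>"
            else:
                block = canonical
            continue
        if low.startswith("end "):
            block = None
            continue
        if block in (None, "<skip>", "parameters", "functions"):
            continue  # actions and opaque blocks

        if block == "molecule types":
            mname, comps = _parse_molecule(_strip_index(line), f"line {lineno}", declaration=True)
            if model.molecule_type(mname) is not None:
                raise BnglParseError(f"line {lineno}: molecule type {mname!r} declared twice")
            mt = MoleculeType(name=mname)
            seen: dict[str, int] = {}
            for cname, states, _bond in comps:
                seen[cname] = seen.get(cname, 0) + 1
                mt.components.append(ComponentDecl(cname, seen[cname], list(states)))
            model.molecule_types.append(mt)
            declared.add(mname)
        elif block == "seed species":
            tok = _strip_index(line).split()
            if tok:
                model.seed_species.append(tok[0])
                try:
                    pattern_usages.extend(_parse_complex(tok[0], f"line {lineno}"))
                except BnglParseError:
                    warnings.warn(
                        f"line {lineno}: seed species pattern not parseable; carried verbatim",
                        BnglWarning,
                        stacklevel=2,
                    )
        elif block == "observables":
            tok = _strip_index(line).split()
            if tok and tok[0] in ("Molecules", "Species", "molecules", "species"):
                tok = tok[1:]
            if len(tok) >= 2:
                model.observables.append((tok[0], " ".join(tok[1:])))
            elif tok:
                model.observables.append((tok[0], ""))
        elif block == "reaction rules":
            rule = _parse_rule_line(line, lineno)
            model.rules.append(rule)
            pattern_usages.extend(rule.molecules("reactants"))
            pattern_usages.extend(rule.molecules("products"))

    _auto_declare(model, pattern_usages, declared)

    # a molecule with no declared components gets one implicit whole-molecule
    # component, so every molecule has at least one component
    for mt in model.molecule_types:
        if not mt.components:
            mt.components.append(ComponentDecl(name=mt.name, occurrence=1))
    return model


# ---------------------------------------------------------------------------
# layout position files


def read_layout_file(text: str, name: str = "") -> StoredLayout:
    """Read a layout position file (native dialect or bare triples).

    Unknown identifiers are retained verbatim; resolution against a model
    happens at stabilization time.
    """
    layout = StoredLayout(name=name)
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.startswith("#cmapkit-layout"):
                layout.version = line.split()[-1] if len(line.split()) > 1 else "v1"
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise LayoutFileError(f"line {lineno}: expected 'identifier x y', got {raw!r}")
        ident, xs, ys = parts
        try:
            x, y = float(xs), float(ys)
        except ValueError:
            raise LayoutFileError(f"line {lineno}: non-numeric coordinate in {raw!r}") from None
        if not (math.isfinite(x) and math.isfinite(y)):
            raise LayoutFileError(f"line {lineno}: non-finite coordinate in {raw!r}")
        layout.positions[ident.strip()] = (x, y)
    return layout


def write_layout_file(layout: StoredLayout) -> str:
    """Serialize a :class:`StoredLayout` to the native dialect.

    Entries are sorted by identifier so output is bit-stable; coordinates use
    ``repr`` so a read/write round trip preserves them exactly.
    """
    lines = [LAYOUT_HEADER]
    for ident in sorted(layout.positions):
        x, y = layout.positions[ident]
        lines.append(f"{ident}\t{x!r}\t{y!r}")
    return "\n".join(lines) + "\n"
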