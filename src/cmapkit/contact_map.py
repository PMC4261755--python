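"""Contact-map construction and canonical element identities.

A contact map compresses a rule-based model into an undirected graph:
molecule nodes contain component (binding-site) nodes and their state nodes;
an edge records a possible binding interaction between two components,
optionally qualified by the state the bond requires.  Every structure is
represented exactly once no matter how many rules mention it, so the map is
an abstraction of the generative model, not of the implied reaction network.

Every element (node or edge) has a canonical string identifier, the unit of
all cross-model comparison::

    molecule      M
    component     M.c#k          (k = 1-based occurrence among same-named
                                  components of the molecule)
    state         M.c#k~s
    edge          {M.c#k[~s]|N.d#j[~t]}   endpoints sorted lexicographically
    unstructured  M.@syn  /  M.@deg       synthesis / degradation markers

Identifier equality is the sole matching mechanism across models (no synonym
resolution), so the grammar is a stable public interface used in layout
files, CLI arguments, and comparison reports.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

from cmapkit.bngl_io import BOND_NONE, BOND_WILD_ANY, BOND_WILD_BOUND, Model

__all__ = [
    "Endpoint",
    "Edge",
    "ComponentNode",
    "MoleculeNode",
    "ContactMap",
    "CmapStats",
    "ElementIdError",
    "molecule_id",
    "component_id",
    "state_id",
    "endpoint_id",
    "edge_id",
    "unstructured_id",
    "parse_element_id",
    "build_contact_map",
    "element_ids",
    "edge_ids",
    "matrix_row_ids",
    "cmap_stats",
]

logger = logging.getLogger("cmapkit")

# (molecule, component, occurrence, state-or-None)
Endpoint = tuple[str, str, int, str | None]


class ElementIdError(ValueError):
    """Raised when a string does not match the element-identifier grammar."""


def molecule_id(molecule: str) -> str:
    return molecule


def component_id(molecule: str, component: str, occurrence: int) -> str:
    return f"{molecule}.{component}#{occurrence}"


def state_id(molecule: str, component: str, occurrence: int, state: str) -> str:
    return f"{molecule}.{component}#{occurrence}~{state}"


def endpoint_id(ep: Endpoint) -> str:
    m, c, k, s = ep
    base = component_id(m, c, k)
    return base if s is None else f"{base}~{s}"


def edge_id(a: Endpoint, b: Endpoint) -> str:
    lo, hi = sorted((endpoint_id(a), endpoint_id(b)))
    return "{" + lo + "|" + hi + "}"


def unstructured_id(molecule: str, kind: str) -> str:
    if kind not in ("syn", "deg"):
        raise ValueError(f"unstructured kind must be 'syn' or 'deg', got {kind!r}")
    return f"{molecule}.@{kind}"


_NAME = r"[A-Za-z_][A-Za-z0-9_]*"
_STATE = r"[A-Za-z0-9_]+"
_EP = rf"{_NAME}\.{_NAME}#[0-9]+(?:~{_STATE})?"
_MOLECULE_RE = re.compile(rf"^{_NAME}$")
_COMPONENT_RE = re.compile(rf"^({_NAME})\.({_NAME})#([0-9]+)$")
_STATE_RE = re.compile(rf"^({_NAME})\.({_NAME})#([0-9]+)~({_STATE})$")
_EDGE_RE = re.compile(rf"^\{{({_EP})\|({_EP})\}}$")
_UNSTRUCTURED_RE = re.compile(rf"^({_NAME})\.@(syn|deg)$")
_EP_RE = re.compile(rf"^({_NAME})\.({_NAME})#([0-9]+)(?:~({_STATE}))?$")


def _parse_endpoint(text: str) -> Endpoint:
    m = _EP_RE.match(text)
    if not m:
        raise ElementIdError(f"bad edge endpoint {text!r}")
    mol, comp, occ, state = m.groups()
    return (mol, comp, int(occ), state)


def parse_element_id(text: str):
    """Parse a canonical identifier → ``(kind, payload)``.

    kinds: ``molecule`` (name), ``component`` ((m, c, k)), ``state``
    ((m, c, k, s)), ``edge`` ((endpoint, endpoint)), ``unstructured``
    ((m, 'syn'|'deg')).  Raises :class:`ElementIdError` with a grammar
    reminder on malformed input.
    """
    m = _UNSTRUCTURED_RE.match(text)
    if m:
        return ("unstructured", (m.group(1), m.group(2)))
    m = _EDGE_RE.match(text)
    if m:
        return ("edge", (_parse_endpoint(m.group(1)), _parse_endpoint(m.group(2))))
    m = _STATE_RE.match(text)
    if m:
        mol, comp, occ, state = m.groups()
        return ("state", (mol, comp, int(occ), state))
    m = _COMPONENT_RE.match(text)
    if m:
        mol, comp, occ = m.groups()
        return ("component", (mol, comp, int(occ)))
    if _MOLECULE_RE.match(text):
        return ("molecule", text)
    raise ElementIdError(
        f"{text!r} is not a valid element identifier; expected one of "
        "'M', 'M.c#k', 'M.c#k~s', '{M.c#k[~s]|N.d#j[~t]}', 'M.@syn', 'M.@deg'"
    )


# ---------------------------------------------------------------------------
# graph types


@dataclass
class Edge:
    """An undirected binding interaction between two (possibly state-qualified)
    component endpoints; self-edges encode homodimerization."""

    endpoints: tuple[Endpoint, Endpoint]
    contributing_rules: set[str] = field(default_factory=set)

    @property
    def id(self) -> str:
        return edge_id(*self.endpoints)


@dataclass
class ComponentNode:
    name: str
    occurrence: int
    state_nodes: list[str] = field(default_factory=list)
    modifiable: bool = False  # some rule changes its state
    binds: bool = False  # participates in >=1 bond (incl. wildcard bonds)


@dataclass
class MoleculeNode:
    name: str
    component_nodes: list[ComponentNode] = field(default_factory=list)


@dataclass
class ContactMap:
    name: str
    molecule_nodes: list[MoleculeNode] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)  # sorted by id, unique
    unstructured_nodes: set[tuple[str, str]] = field(default_factory=set)  # (kind, molecule)

    def molecule(self, name: str) -> MoleculeNode | None:
        for mn in self.molecule_nodes:
            if mn.name == name:
                return mn
        return None

    def component(self, molecule: str, name: str, occurrence: int) -> ComponentNode | None:
        mn = self.molecule(molecule)
        if mn is None:
            return None
        for cn in mn.component_nodes:
            if cn.name == name and cn.occurrence == occurrence:
                return cn
        return None


@dataclass
class CmapStats:
    n_molecules: int
    n_components: int
    n_states: int
    n_modifiable: int
    n_edges: int
    n_unstructured: int
    n_visual_nodes: int  # molecules + components + states + unstructured
    n_matrix_rows: int  # states + stateless components (metric convention)


# ---------------------------------------------------------------------------
# construction


def _rule_tag(index: int, label: str | None) -> str:
    return label if label else f"R{index + 1}"


def build_contact_map(model: Model) -> ContactMap:
    """Build the contact map of a parsed model.

    One molecule node per molecule type, one component node per declared
    (name, occurrence), state nodes from the declarations (the parser has
    already folded in states first seen in rules).  An edge is added for
    every bond realized on either side of any rule; the endpoint carries a
    state qualifier only when the rule writes an explicit state on the bonded
    component on that side.  A component is flagged modifiable when some
    rule's explicit-state multiset for it differs between the two sides (the
    molecule must appear on both sides).  Rules with an empty side contribute
    synthesis/degradation markers attached to the molecules on the other side.
    """
    cmap = ContactMap(name=model.name)
    for mt in model.molecule_types:
        cmap.molecule_nodes.append(
            MoleculeNode(
                name=mt.name,
                component_nodes=[
                    ComponentNode(name=c.name, occurrence=c.occurrence, state_nodes=list(c.states))
                    for c in mt.components
                ],
            )
        )

    edges: dict[str, Edge] = {}
    for ridx, rule in enumerate(model.rules):
        tag = _rule_tag(ridx, rule.label)
        for side in ("reactants", "products"):
            bonds: dict[str, list[Endpoint]] = {}
            for pm in rule.molecules(side):
                for pc in pm.components:
                    node = cmap.component(pm.name, pc.name, pc.occurrence)
                    if pc.bond == BOND_NONE:
                        continue
                    if pc.bond in (BOND_WILD_BOUND, BOND_WILD_ANY):
                        if node is not None:
                            node.binds = True
                        logger.warning(
                            "%s: wildcard bond on %s.%s#%d contributes no edge",
                            tag, pm.name, pc.name, pc.occurrence,
                        )
                        continue
                    bonds.setdefault(pc.bond, []).append(
                        (pm.name, pc.name, pc.occurrence, pc.state)
                    )
            for eps in bonds.values():
                if len(eps) != 2:  # parser guarantees; defensive
                    continue
                eid = edge_id(eps[0], eps[1])
                edge = edges.get(eid)
                if edge is None:
                    a, b = sorted(eps, key=endpoint_id)
                    edge = Edge(endpoints=(a, b))
                    edges[eid] = edge
                edge.contributing_rules.add(tag)

        # modifiability: explicit-state multisets per (mol, comp, occ) on the
        # two sides differ, for molecules present on both sides
        def _state_multisets(side: str) -> dict[tuple[str, str, int], Counter]:
            out: dict[tuple[str, str, int], Counter] = {}
            for pm in rule.molecules(side):
                for pc in pm.components:
                    if pc.state is not None:
                        out.setdefault((pm.name, pc.name, pc.occurrence), Counter())[pc.state] += 1
            return out

        lhs_mols = {pm.name for pm in rule.molecules("reactants")}
        rhs_mols = {pm.name for pm in rule.molecules("products")}
        both = lhs_mols & rhs_mols
        lhs_states = _state_multisets("reactants")
        rhs_states = _state_multisets("products")
        for key in set(lhs_states) | set(rhs_states):
            if key[0] not in both:
                continue
            if lhs_states.get(key, Counter()) != rhs_states.get(key, Counter()):
                node = cmap.component(*key)
                if node is not None:
                    node.modifiable = True

        # synthesis / degradation markers; a reversible rule with an empty
        # side implies both directions
        if rule.is_synthesis:
            for pm in rule.molecules("products"):
                cmap.unstructured_nodes.add(("syn", pm.name))
                if rule.reversible:
                    cmap.unstructured_nodes.add(("deg", pm.name))
        if rule.is_degradation:
            for pm in rule.molecules("reactants"):
                cmap.unstructured_nodes.add(("deg", pm.name))
                if rule.reversible:
                    cmap.unstructured_nodes.add(("syn", pm.name))

    for edge in edges.values():
        for mol, comp, occ, _state in edge.endpoints:
            node = cmap.component(mol, comp, occ)
            if node is not None:
                node.binds = True
    cmap.edges = [edges[eid] for eid in sorted(edges)]
    return cmap


# ---------------------------------------------------------------------------
# identities and statistics


def edge_ids(cmap: ContactMap) -> set[str]:
    """Identifiers of the binding-interaction edges."""
    return {e.id for e in cmap.edges}


def element_ids(cmap: ContactMap) -> set[str]:
    """Canonical identifiers of every element: molecules, components, states,
    unstructured markers, and edges."""
    ids: set[str] = set()
    for mn in cmap.molecule_nodes:
        ids.add(molecule_id(mn.name))
        for cn in mn.component_nodes:
            ids.add(component_id(mn.name, cn.name, cn.occurrence))
            for s in cn.state_nodes:
                ids.add(state_id(mn.name, cn.name, cn.occurrence, s))
    for kind, mol in cmap.unstructured_nodes:
        ids.add(unstructured_id(mol, kind))
    ids |= edge_ids(cmap)
    return ids


def matrix_row_ids(cmap: ContactMap) -> list[str]:
    """Adjacency-matrix rows: every state node, plus every component node
    that has no states; sorted for determinism.  These rows are the "nodes"
    of the similarity metric (molecules contribute only via components)."""
    rows: list[str] = []
    for mn in cmap.molecule_nodes:
        for cn in mn.component_nodes:
            if cn.state_nodes:
                rows.extend(
                    state_id(mn.name, cn.name, cn.occurrence, s) for s in cn.state_nodes
                )
            else:
                rows.append(component_id(mn.name, cn.name, cn.occurrence))
    return sorted(rows)


def cmap_stats(cmap: ContactMap) -> CmapStats:
    """Structural counts of a contact map (no reaction-network quantities)."""
    n_molecules = len(cmap.molecule_nodes)
    n_components = sum(len(mn.component_nodes) for mn in cmap.molecule_nodes)
    n_states = sum(
        len(cn.state_nodes) for mn in cmap.molecule_nodes for cn in mn.component_nodes
    )
    n_modifiable = sum(
        1 for mn in cmap.molecule_nodes for cn in mn.component_nodes if cn.modifiable
    )
    n_unstructured = len(cmap.unstructured_nodes)
    return CmapStats(
        n_molecules=n_molecules,
        n_components=n_components,
        n_states=n_states,
        n_modifiable=n_modifiable,
        n_edges=len(cmap.edges),
        n_unstructured=n_unstructured,
        n_visual_nodes=n_molecules + n_components + n_states + n_unstructured,
        n_matrix_rows=len(matrix_row_ids(cmap)),
    )
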