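"""Deterministic force-directed contact-map layout with pinned positions.

The layout is two-level: molecule boxes are placed by a Fruchterman–Reingold
pass over the molecule-adjacency graph (two molecules are adjacent when a
binding edge joins their components; synthesis/degradation markers attach to
their molecule), then components are placed on a grid inside each box with
state nodes stacked beside their component.  All randomness is fixed by an
integer seed, so a given (contact map, seed, pinned set) always produces the
identical layout — the property that makes layouts shareable and testable.

Pinning: any molecule or component named in a stored layout keeps its input
coordinates exactly.  Stabilizing a family against one reference layout
therefore puts every shared element at the same coordinates in every panel,
so that visual differences between panels reflect model differences only.

Coordinates are abstract units, y-down, origin wherever the force pass puts
the family (SVG export rescales to fit).
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from cmapkit.bngl_io import StoredLayout
from cmapkit.contact_map import (
    ContactMap,
    ElementIdError,
    component_id,
    parse_element_id,
    state_id,
    unstructured_id,
)

__all__ = [
    "MoleculeBox",
    "Layout",
    "force_layout",
    "stabilize_layouts",
    "COMP_W",
    "COMP_H",
    "STATE_W",
    "STATE_H",
]

logger = logging.getLogger("cmapkit")

# glyph sizes in abstract units
COMP_W, COMP_H = 30.0, 14.0
STATE_W, STATE_H = 24.0, 10.0
_PAD = 8.0
_LABEL_BAND = 14.0  # room for the molecule name at the top of its box


@dataclass
class MoleculeBox:
    center: tuple[float, float]
    half_extent: tuple[float, float]  # (half width, half height)
    pinned: bool = False


@dataclass
class Layout:
    """Positions for one contact map; all coordinates are glyph centers."""

    name: str
    molecules: dict[str, MoleculeBox] = field(default_factory=dict)
    components: dict[str, tuple[float, float]] = field(default_factory=dict)  # component id
    states: dict[str, tuple[float, float]] = field(default_factory=dict)  # state id
    unstructured: dict[str, tuple[float, float]] = field(default_factory=dict)
    pinned_ids: set[str] = field(default_factory=set)

    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) over all molecule boxes and markers."""
        xs: list[float] = []
        ys: list[float] = []
        for box in self.molecules.values():
            xs += [box.center[0] - box.half_extent[0], box.center[0] + box.half_extent[0]]
            ys += [box.center[1] - box.half_extent[1], box.center[1] + box.half_extent[1]]
        for x, y in self.unstructured.values():
            xs += [x - 12, x + 12]
            ys += [y - 12, y + 12]
        if not xs:
            return (0.0, 0.0, 0.0, 0.0)
        return (min(xs), min(ys), max(xs), max(ys))


def _resolve_pins(
    cmap: ContactMap, pinned: StoredLayout | None
) -> tuple[dict[str, tuple[float, float]], dict[str, tuple[float, float]]]:
    """Split a stored layout into molecule pins and component pins that exist
    in this contact map; everything else is ignored with a warning."""
    mol_pins: dict[str, tuple[float, float]] = {}
    comp_pins: dict[str, tuple[float, float]] = {}
    if pinned is None:
        return mol_pins, comp_pins
    for ident, xy in pinned.positions.items():
        try:
            kind, payload = parse_element_id(ident)
        except ElementIdError:
            logger.warning("layout %s: unparseable pinned id %r ignored", cmap.name, ident)
            continue
        if kind == "molecule":
            if cmap.molecule(payload) is not None:
                mol_pins[payload] = xy
            else:
                logger.debug("layout %s: pinned molecule %r not in model", cmap.name, ident)
        elif kind == "component":
            if cmap.component(*payload) is not None:
                comp_pins[ident] = xy
            else:
                logger.debug("layout %s: pinned component %r not in model", cmap.name, ident)
        else:
            logger.warning(
                "layout %s: pinned id %r is not a molecule or component; ignored",
                cmap.name, ident,
            )
    return mol_pins, comp_pins


def _molecule_graph(cmap: ContactMap) -> nx.Graph:
    g = nx.Graph()
    for mn in cmap.molecule_nodes:
        g.add_node(mn.name)
    for edge in cmap.edges:
        (m1, _c1, _k1, _s1), (m2, _c2, _k2, _s2) = edge.endpoints
        if m1 != m2:
            g.add_edge(m1, m2)
    for kind, mol in sorted(cmap.unstructured_nodes):
        node = unstructured_id(mol, kind)
        g.add_node(node)
        if cmap.molecule(mol) is not None:
            g.add_edge(node, mol)
    return g


def _box_geometry(mn, comp_pins, center):
    """Place the components of one molecule; returns (components, states,
    half_extent) with the default grid centered on ``center``."""
    n = len(mn.component_nodes)
    cols = max(1, math.ceil(math.sqrt(n)))
    rows = math.ceil(n / cols)
    max_states = max((len(c.state_nodes) for c in mn.component_nodes), default=0)
    cell_w = COMP_W + _PAD + (STATE_W + 4.0) * max_states
    cell_h = COMP_H + _PAD
    grid_w, grid_h = cols * cell_w, rows * cell_h
    cx, cy = center

    comps: dict[str, tuple[float, float]] = {}
    states: dict[str, tuple[float, float]] = {}
    for i, cn in enumerate(mn.component_nodes):
        cid = component_id(mn.name, cn.name, cn.occurrence)
        if cid in comp_pins:
            x, y = comp_pins[cid]
        else:
            col, row = i % cols, i // cols
            x = cx - grid_w / 2 + col * cell_w + COMP_W / 2 + _PAD / 2
            y = cy + _LABEL_BAND / 2 - grid_h / 2 + row * cell_h + COMP_H / 2 + _PAD / 2
        comps[cid] = (x, y)
        for si, s in enumerate(cn.state_nodes):
            states[state_id(mn.name, cn.name, cn.occurrence, s)] = (
                x + COMP_W / 2 + 2.0 + (si + 0.5) * (STATE_W + 4.0),
                y + (COMP_H - STATE_H) / 2,
            )

    # symmetric half-extent about the (possibly pinned) center so every glyph,
    # including pinned components and their states, stays inside the box
    half_w = grid_w / 2 + _PAD / 2
    half_h = grid_h / 2 + _LABEL_BAND / 2 + _PAD / 2
    for (x, y) in comps.values():
        half_w = max(half_w, abs(x - cx) + COMP_W / 2 + _PAD / 2)
        half_h = max(half_h, abs(y - cy) + COMP_H / 2 + _PAD / 2)
    for (x, y) in states.values():
        half_w = max(half_w, abs(x - cx) + STATE_W / 2 + _PAD / 2)
        half_h = max(half_h, abs(y - cy) + STATE_H / 2 + _PAD / 2)
    return comps, states, (half_w, half_h)


def force_layout(cmap: ContactMap, seed: int = 0, pinned: StoredLayout | None = None) -> Layout:
    """Lay out one contact map; same (cmap, seed, pinned) → identical result.

    Pinned molecules and components keep their stored coordinates exactly;
    everything else is placed by a seeded spring pass (molecules) and a
    deterministic grid (components/states).
    """
    mol_pins, comp_pins = _resolve_pins(cmap, pinned)
    g = _molecule_graph(cmap)
    nodes = sorted(g.nodes)

    # spacing scaled to the largest box so boxes do not overlap grossly
    spacing = 3.0 * max(
        [COMP_W + _PAD]
        + [
            math.sqrt(len(mn.component_nodes)) * (COMP_W + _PAD + (STATE_W + 4.0))
            for mn in cmap.molecule_nodes
        ]
    ) if cmap.molecule_nodes else 100.0

    pos: dict[str, tuple[float, float]] = {}
    if nodes:
        fixed = [n for n in nodes if n in mol_pins]
        if len(fixed) == len(nodes):
            pos = {n: tuple(mol_pins[n]) for n in nodes}
        elif fixed:
            rng = np.random.default_rng(seed & 0x7FFFFFFF)
            init = {n: np.asarray(mol_pins[n], dtype=float) for n in fixed}
            anchor = np.mean(list(init.values()), axis=0)
            for n in nodes:
                if n not in init:
                    init[n] = anchor + rng.uniform(-spacing, spacing, size=2)
            raw = nx.spring_layout(
                g, pos=init, fixed=fixed, seed=seed & 0x7FFFFFFF, k=spacing, iterations=300
            )
            pos = {n: (float(p[0]), float(p[1])) for n, p in raw.items()}
            for n in fixed:  # bit-exact pass-through
                pos[n] = tuple(mol_pins[n])
        elif len(nodes) == 1:
            pos = {nodes[0]: (0.0, 0.0)}
        else:
            raw = nx.spring_layout(g, seed=seed & 0x7FFFFFFF, iterations=300)
            pos = {
                n: (float(p[0]) * spacing * len(nodes) / 2.0,
                    float(p[1]) * spacing * len(nodes) / 2.0)
                for n, p in raw.items()
            }

    layout = Layout(name=cmap.name)
    layout.pinned_ids = set(mol_pins) | set(comp_pins)
    for mn in cmap.molecule_nodes:
        center = pos[mn.name]
        comps, states, half = _box_geometry(mn, comp_pins, center)
        layout.molecules[mn.name] = MoleculeBox(
            center=center, half_extent=half, pinned=mn.name in mol_pins
        )
        layout.components.update(comps)
        layout.states.update(states)
    for kind, mol in sorted(cmap.unstructured_nodes):
        layout.unstructured[unstructured_id(mol, kind)] = pos[unstructured_id(mol, kind)]
    return layout


def _model_seed(name: str, seed: int) -> int:
    return (zlib.crc32(name.encode("utf-8")) ^ seed) & 0x7FFFFFFF


def stabilize_layouts(
    family: list[ContactMap], reference: StoredLayout, seed: int = 0
) -> list[Layout]:
    """Apply one stored layout across a whole family.

    Every element named in the reference and present in a model is pinned to
    the reference coordinates; the rest of each model is laid out by
    :func:`force_layout` with a per-model seed derived from the model name.
    Shared pinned elements therefore occupy identical positions in every
    panel, which is what makes the small multiples visually comparable.
    """
    return [
        force_layout(cmap, seed=_model_seed(cmap.name, seed), pinned=reference)
        for cmap in family
    ]


def layout_to_stored(layout: Layout, name: str | None = None) -> StoredLayout:
    """Snapshot molecule and component coordinates as a shareable layout."""
    stored = StoredLayout(name=name if name is not None else layout.name)
    for mol, box in layout.molecules.items():
        stored.positions[mol] = box.center
    stored.positions.update(layout.components)
    return stored
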