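"""Graph-format export and grayscale small-multiple SVG rendering.

Contact maps serialize to GraphML, DOT, and a JSON dialect (the JSON dialect
round-trips back to a :class:`~cmapkit.contact_map.ContactMap`).  Rendering
draws one panel per model at a common scale, row-wise in family order, in
grayscale so that the colored similarity/difference overlays stand out.  A
highlight overlay is a single filled, padded hull per connected group of
highlighted elements — a light-weight stand-in for contour-style "bubble
set" regions with the same testable guarantee: every highlighted glyph lies
geometrically inside its overlay region.  Panels taking part in a pairwise
comparison get a tinted background even when their highlight set is empty
(the subgraph-comparison case, where one side simply has nothing unique).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import ConvexHull, QhullError

from cmapkit.contact_map import (
    ComponentNode,
    ContactMap,
    Edge,
    MoleculeNode,
    component_id,
    edge_id,
    element_ids,
    molecule_id,
    state_id,
    unstructured_id,
)
from cmapkit.layout import COMP_H, COMP_W, STATE_H, STATE_W, Layout
from cmapkit.similarity import FamilyOrdering

__all__ = [
    "HighlightSet",
    "export_graph",
    "contact_map_from_json",
    "render_panels",
    "SUPPORTED_FORMATS",
]

logger = logging.getLogger("cmapkit")

SUPPORTED_FORMATS = ("graphml", "dot", "json")

# overlay palette: similarity green / difference red-orange, 40% opacity;
# backgrounds of panels under comparison are lightly tinted
STYLE_COLORS = {"similarity": "#2e8b57", "difference": "#d2491e"}
BACKGROUND_TINTS = {"similarity": "#edf7ef", "difference": "#fdf1ea"}


@dataclass
class HighlightSet:
    """Element ids to overlay on one panel.

    ``background`` marks the panel as a comparison member even when
    ``elements`` is empty.
    """

    elements: set[str] = field(default_factory=set)
    style: str = "similarity"  # "similarity" | "difference"
    background: bool = True


# ---------------------------------------------------------------------------
# export


def _iter_nodes(cmap: ContactMap):
    """Yield (id, attrs) for every visual node, molecules first, sorted."""
    for mn in sorted(cmap.molecule_nodes, key=lambda m: m.name):
        yield molecule_id(mn.name), {"kind": "molecule", "molecule": mn.name}
        for cn in mn.component_nodes:
            cid = component_id(mn.name, cn.name, cn.occurrence)
            yield cid, {
                "kind": "component",
                "molecule": mn.name,
                "component": cn.name,
                "occurrence": cn.occurrence,
                "modifiable": cn.modifiable,
                "binds": cn.binds,
                "parent": molecule_id(mn.name),
            }
            for s in cn.state_nodes:
                yield state_id(mn.name, cn.name, cn.occurrence, s), {
                    "kind": "state",
                    "molecule": mn.name,
                    "component": cn.name,
                    "occurrence": cn.occurrence,
                    "state": s,
                    "parent": cid,
                }
    for kind, mol in sorted(cmap.unstructured_nodes):
        yield unstructured_id(mol, kind), {
            "kind": "unstructured",
            "unstructured_kind": "synthesis" if kind == "syn" else "degradation",
            "molecule": mol,
        }


def _edge_records(cmap: ContactMap):
    for edge in sorted(cmap.edges, key=lambda e: e.id):
        (m1, c1, k1, s1), (m2, c2, k2, s2) = edge.endpoints
        yield (
            component_id(m1, c1, k1),
            component_id(m2, c2, k2),
            {
                "id": edge.id,
                "state_a": s1 or "",
                "state_b": s2 or "",
                "rules": ",".join(sorted(edge.contributing_rules)),
            },
        )


def export_graph(cmap: ContactMap, format: str = "json") -> str:
    """Serialize a contact map to ``graphml``, ``dot``, or ``json`` text.

    Output ordering is deterministic.  Molecule containment is encoded as a
    ``parent`` attribute (GraphML/JSON) or cluster subgraphs (DOT).
    """
    if format not in SUPPORTED_FORMATS:
        raise ValueError(
            f"unknown format {format!r}; supported formats: {', '.join(SUPPORTED_FORMATS)}"
        )
    if format == "json":
        doc = {
            "format": "cmapkit-contact-map",
            "version": 1,
            "name": cmap.name,
            "molecules": [
                {
                    "name": mn.name,
                    "components": [
                        {
                            "name": cn.name,
                            "occurrence": cn.occurrence,
                            "states": list(cn.state_nodes),
                            "modifiable": cn.modifiable,
                            "binds": cn.binds,
                        }
                        for cn in mn.component_nodes
                    ],
                }
                for mn in cmap.molecule_nodes
            ],
            "edges": [
                {
                    "endpoints": [list(ep) for ep in edge.endpoints],
                    "rules": sorted(edge.contributing_rules),
                }
                for edge in sorted(cmap.edges, key=lambda e: e.id)
            ],
            "unstructured": [
                {"kind": kind, "molecule": mol} for kind, mol in sorted(cmap.unstructured_nodes)
            ],
        }
        return json.dumps(doc, indent=1) + "\n"

    if format == "graphml":
        g = nx.Graph(name=cmap.name)
        for nid, attrs in _iter_nodes(cmap):
            g.add_node(nid, **attrs)
        for u, v, attrs in _edge_records(cmap):
            g.add_edge(u, v, **attrs)
        return "\n".join(nx.generate_graphml(g, named_key_ids=True)) + "\n"

    # DOT: molecule containment as cluster subgraphs
    def q(s: str) -> str:
        return '"' + s.replace('"', '\\"') + '"'

    lines = [f"graph {q(cmap.name or 'contact_map')} {{"]
    for mn in sorted(cmap.molecule_nodes, key=lambda m: m.name):
        lines.append(f"  subgraph {q('cluster_' + mn.name)} {{")
        lines.append(f"    label={q(mn.name)};")
        for cn in mn.component_nodes:
            cid = component_id(mn.name, cn.name, cn.occurrence)
            shade = "gray75" if cn.modifiable else "gray90"
            lines.append(
                f"    {q(cid)} [kind=component, modifiable={str(cn.modifiable).lower()}, "
                f"style=filled, fillcolor={shade}];"
            )
            for s in cn.state_nodes:
                sid = state_id(mn.name, cn.name, cn.occurrence, s)
                lines.append(f"    {q(sid)} [kind=state, shape=box];")
                lines.append(f"    {q(cid)} -- {q(sid)} [style=dotted];")
        lines.append("  }")
    for kind, mol in sorted(cmap.unstructured_nodes):
        nid = unstructured_id(mol, kind)
        lines.append(f"  {q(nid)} [kind=unstructured, shape=diamond];")
        mn = cmap.molecule(mol)
        if mn is not None and mn.component_nodes:  # anchor the marker to its molecule's cluster
            c0 = mn.component_nodes[0]
            anchor = component_id(mol, c0.name, c0.occurrence)
            lines.append(f"  {q(nid)} -- {q(anchor)} [style=dashed, kind=unstructured_link];")
    for u, v, attrs in _edge_records(cmap):
        label = ""
        if attrs["state_a"] or attrs["state_b"]:
            label = f', label={q((attrs["state_a"] or "-") + "|" + (attrs["state_b"] or "-"))}'
        lines.append(f"  {q(u)} -- {q(v)} [kind=bond{label}];")
    lines.append("}")
    return "\n".join(lines) + "\n"


def contact_map_from_json(text: str) -> ContactMap:
    """Rebuild a contact map from the JSON dialect (export round trip)."""
    doc = json.loads(text)
    if doc.get("format") != "cmapkit-contact-map":
        raise ValueError("not a cmapkit contact-map JSON document")
    cmap = ContactMap(name=doc.get("name", ""))
    for m in doc.get("molecules", []):
        cmap.molecule_nodes.append(
            MoleculeNode(
                name=m["name"],
                component_nodes=[
                    ComponentNode(
                        name=c["name"],
                        occurrence=c["occurrence"],
                        state_nodes=list(c.get("states", [])),
                        modifiable=c.get("modifiable", False),
                        binds=c.get("binds", False),
                    )
                    for c in m.get("components", [])
                ],
            )
        )
    for e in doc.get("edges", []):
        eps = tuple(
            (ep[0], ep[1], int(ep[2]), ep[3] if ep[3] is not None else None)
            for ep in e["endpoints"]
        )
        cmap.edges.append(Edge(endpoints=eps, contributing_rules=set(e.get("rules", []))))
    cmap.edges.sort(key=lambda e: e.id)
    for u in doc.get("unstructured", []):
        cmap.unstructured_nodes.add((u["kind"], u["molecule"]))
    return cmap


# ---------------------------------------------------------------------------
# SVG rendering


def _f(x: float) -> str:
    return f"{x:.2f}"


def _esc(s: str) -> str:
    return s.replace("&", "&amp;").replace("<", "&lt;").replace(">", "&gt;").replace('"', "&quot;")


def _glyph_boxes(cmap: ContactMap, layout: Layout) -> dict[str, tuple[float, float, float, float]]:
    """Element id → (x, y, w, h) glyph rectangle in layout coordinates.
    Edges map to the bounding box of their endpoint segment."""
    boxes: dict[str, tuple[float, float, float, float]] = {}
    for mol, box in layout.molecules.items():
        boxes[mol] = (
            box.center[0] - box.half_extent[0],
            box.center[1] - box.half_extent[1],
            2 * box.half_extent[0],
            2 * box.half_extent[1],
        )
    for cid, (x, y) in layout.components.items():
        boxes[cid] = (x - COMP_W / 2, y - COMP_H / 2, COMP_W, COMP_H)
    for sid, (x, y) in layout.states.items():
        boxes[sid] = (x - STATE_W / 2, y - STATE_H / 2, STATE_W, STATE_H)
    for uid, (x, y) in layout.unstructured.items():
        boxes[uid] = (x - 10, y - 10, 20, 20)
    for edge in cmap.edges:
        (m1, c1, k1, _s1), (m2, c2, k2, _s2) = edge.endpoints
        p1 = layout.components.get(component_id(m1, c1, k1))
        p2 = layout.components.get(component_id(m2, c2, k2))
        if p1 and p2:
            x0, x1 = min(p1[0], p2[0]), max(p1[0], p2[0])
            y0, y1 = min(p1[1], p2[1]), max(p1[1], p2[1])
            boxes[edge.id] = (x0, y0, x1 - x0, y1 - y0)
    return boxes


def _owner_molecule(eid: str) -> str | None:
    """Molecule owning a component/state/unstructured id, None for edges."""
    if eid.startswith("{"):
        return None
    return eid.split(".", 1)[0] if "." in eid else eid


def _highlight_groups(ids: set[str]) -> list[set[str]]:
    """Connected groups of highlighted elements: elements of one molecule
    group together; a highlighted edge bridges its endpoint molecules."""
    g = nx.Graph()
    for eid in ids:
        g.add_node(eid)
        mol = _owner_molecule(eid)
        if mol is not None:
            g.add_node(("anchor", mol))
            g.add_edge(eid, ("anchor", mol))
        else:  # edge id {A.c#k[~s]|B.d#j[~t]}
            for ep in eid[1:-1].split("|"):
                g.add_node(("anchor", ep.split(".", 1)[0]))
                g.add_edge(eid, ("anchor", ep.split(".", 1)[0]))
    groups = []
    for comp in nx.connected_components(g):
        members = {n for n in comp if isinstance(n, str)}
        if members:
            groups.append(members)
    return sorted(groups, key=lambda s: min(s))


def _padded_hull(points: np.ndarray, pad: float = 10.0) -> np.ndarray:
    """Convex hull of ``points`` scaled uniformly about its centroid so that
    every input point stays strictly inside; degenerate inputs fall back to a
    padded bounding rectangle."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    hull_pts = None
    if len(pts) >= 3:
        try:
            hull = ConvexHull(pts)
            hull_pts = pts[hull.vertices]
        except QhullError:
            hull_pts = None
    if hull_pts is None:
        x0, y0 = pts.min(axis=0) - pad
        x1, y1 = pts.max(axis=0) + pad
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    centroid = hull_pts.mean(axis=0)
    radii = np.linalg.norm(hull_pts - centroid, axis=1)
    r_min = radii.min()
    if r_min < 1e-6:
        x0, y0 = pts.min(axis=0) - pad
        x1, y1 = pts.max(axis=0) + pad
        return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
    factor = 1.0 + pad / r_min
    return centroid + (hull_pts - centroid) * factor


def render_panels(
    family: list[ContactMap],
    layouts: list[Layout],
    ordering: FamilyOrdering | None = None,
    highlights: dict[str, HighlightSet] | None = None,
    panel_size: tuple[float, float] = (420.0, 320.0),
) -> str:
    """Render the family as one SVG of same-scale panels, row-wise in family
    order, grayscale base plus highlight overlays.  Deterministic output."""
    if len(layouts) != len(family):
        raise ValueError("need one layout per contact map")
    highlights = highlights or {}
    order = ordering.order if ordering is not None else list(range(len(family)))

    # common scale across all panels from the union of layout bounds
    pw, ph = panel_size
    margin = 16.0
    bounds = [lay.bounds() for lay in layouts]
    wmax = max((b[2] - b[0] for b in bounds), default=1.0) or 1.0
    hmax = max((b[3] - b[1] for b in bounds), default=1.0) or 1.0
    gmin_x = min((b[0] for b in bounds), default=0.0)
    gmin_y = min((b[1] for b in bounds), default=0.0)
    scale = min((pw - 2 * margin) / wmax, (ph - 2 * margin) / hmax, 1.0)

    n = len(order)
    ncols = max(1, int(np.ceil(np.sqrt(n))))
    nrows = int(np.ceil(n / ncols)) if n else 1
    width, height = ncols * pw, nrows * ph

    out: list[str] = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{_f(width)}" height="{_f(height)}" '
        f'viewBox="0 0 {_f(width)} {_f(height)}" font-family="sans-serif">'
    ]

    for slot, idx in enumerate(order):
        cmap, lay = family[idx], layouts[idx]
        px = (slot % ncols) * pw
        py = (slot // ncols) * ph
        hs = highlights.get(cmap.name)

        def t(p: tuple[float, float]) -> tuple[float, float]:
            return (
                px + margin + (p[0] - gmin_x) * scale,
                py + margin + (p[1] - gmin_y) * scale,
            )

        out.append(f'<g class="panel" data-model="{_esc(cmap.name)}">')
        bg = "#ffffff"
        if hs is not None and (hs.background or hs.elements):
            bg = BACKGROUND_TINTS.get(hs.style, "#f2f2f2")
        out.append(
            f'<rect class="panel-bg" x="{_f(px)}" y="{_f(py)}" width="{_f(pw)}" '
            f'height="{_f(ph)}" fill="{bg}" stroke="#999999" stroke-width="1"/>'
        )
        out.append(
            f'<text x="{_f(px + 6)}" y="{_f(py + 13)}" font-size="11" '
            f'fill="#333333">{_esc(cmap.name)}</text>'
        )

        # molecule boxes
        for mol in sorted(lay.molecules):
            box = lay.molecules[mol]
            x, y = t((box.center[0] - box.half_extent[0], box.center[1] - box.half_extent[1]))
            w, h = 2 * box.half_extent[0] * scale, 2 * box.half_extent[1] * scale
            out.append(
                f'<rect class="glyph molecule" data-eid="{_esc(mol)}" x="{_f(x)}" y="{_f(y)}" '
                f'width="{_f(w)}" height="{_f(h)}" rx="6" fill="#ebebeb" stroke="#8c8c8c"/>'
            )
            out.append(
                f'<text x="{_f(x + 4)}" y="{_f(y + 11)}" font-size="9" '
                f'fill="#444444">{_esc(mol)}</text>'
            )

        # unstructured markers and their dashed link to the molecule
        for uid in sorted(lay.unstructured):
            ux, uy = t(lay.unstructured[uid])
            mol = uid.split(".", 1)[0]
            if mol in lay.molecules:
                mx, my = t(lay.molecules[mol].center)
                out.append(
                    f'<line x1="{_f(ux)}" y1="{_f(uy)}" x2="{_f(mx)}" y2="{_f(my)}" '
                    f'stroke="#aaaaaa" stroke-dasharray="3,3"/>'
                )
            r = 10 * scale
            out.append(
                f'<circle class="glyph unstructured" data-eid="{_esc(uid)}" cx="{_f(ux)}" '
                f'cy="{_f(uy)}" r="{_f(max(r, 3.0))}" fill="#f5f5f5" stroke="#8c8c8c"/>'
            )
            out.append(
                f'<text x="{_f(ux - 8)}" y="{_f(uy + 3)}" font-size="8" fill="#555555">'
                f'{"syn" if uid.endswith("@syn") else "deg"}</text>'
            )

        # bond edges (drawn above boxes, below component glyphs)
        for edge in sorted(cmap.edges, key=lambda e: e.id):
            (m1, c1, k1, _s1), (m2, c2, k2, _s2) = edge.endpoints
            p1 = lay.components.get(component_id(m1, c1, k1))
            p2 = lay.components.get(component_id(m2, c2, k2))
            if p1 is None or p2 is None:
                continue
            x1, y1 = t(p1)
            x2, y2 = t(p2)
            if (m1, c1, k1) == (m2, c2, k2):  # homodimer self-loop
                out.append(
                    f'<path class="glyph edge" data-eid="{_esc(edge.id)}" '
                    f'd="M {_f(x1)} {_f(y1)} c -18 -24, 18 -24, 0 0" '
                    f'fill="none" stroke="#5a5a5a" stroke-width="1.2"/>'
                )
            else:
                out.append(
                    f'<line class="glyph edge" data-eid="{_esc(edge.id)}" x1="{_f(x1)}" '
                    f'y1="{_f(y1)}" x2="{_f(x2)}" y2="{_f(y2)}" stroke="#5a5a5a" '
                    f'stroke-width="1.2"/>'
                )

        # components and states
        for cid in sorted(lay.components):
            x, y = t(lay.components[cid])
            mol, rest = cid.split(".", 1)
            node = None
            mn = cmap.molecule(mol)
            if mn is not None:
                cname, occ = rest.split("#")
                node = cmap.component(mol, cname, int(occ))
            fill = "#b8b8b8" if (node is not None and node.modifiable) else "#dcdcdc"
            out.append(
                f'<rect class="glyph component" data-eid="{_esc(cid)}" '
                f'x="{_f(x - COMP_W / 2 * scale)}" y="{_f(y - COMP_H / 2 * scale)}" '
                f'width="{_f(COMP_W * scale)}" height="{_f(COMP_H * scale)}" '
                f'fill="{fill}" stroke="#6f6f6f"/>'
            )
            out.append(
                f'<text x="{_f(x - COMP_W / 2 * scale + 2)}" y="{_f(y + 3)}" font-size="8" '
                f'fill="#222222">{_esc(rest)}</text>'
            )
        for sid in sorted(lay.states):
            x, y = t(lay.states[sid])
            out.append(
                f'<rect class="glyph state" data-eid="{_esc(sid)}" '
                f'x="{_f(x - STATE_W / 2 * scale)}" y="{_f(y - STATE_H / 2 * scale)}" '
                f'width="{_f(STATE_W * scale)}" height="{_f(STATE_H * scale)}" '
                f'fill="#f0f0f0" stroke="#9a9a9a"/>'
            )
            out.append(
                f'<text x="{_f(x - STATE_W / 2 * scale + 2)}" y="{_f(y + 3)}" font-size="7" '
                f'fill="#333333">~{_esc(sid.rsplit("~", 1)[1])}</text>'
            )

        # highlight overlay: one padded hull per connected highlighted group
        if hs is not None and hs.elements:
            present = element_ids(cmap)
            boxes = _glyph_boxes(cmap, lay)
            usable: set[str] = set()
            for eid in sorted(hs.elements):
                if eid not in present:
                    logger.warning(
                        "render %s: highlight id %r not in model; skipped", cmap.name, eid
                    )
                elif eid in boxes:
                    usable.add(eid)
            color = STYLE_COLORS.get(hs.style, "#2e8b57")
            for gi, group in enumerate(_highlight_groups(usable)):
                pts = []
                for eid in sorted(group):
                    bx, by, bw, bh = boxes[eid]
                    for cx, cy in ((bx, by), (bx + bw, by), (bx + bw, by + bh), (bx, by + bh)):
                        pts.append(t((cx, cy)))
                hull = _padded_hull(np.array(pts), pad=8.0)
                path = " ".join(f"{_f(x)},{_f(y)}" for x, y in hull)
                out.append(
                    f'<polygon class="overlay" data-style="{hs.style}" data-group="{gi}" '
                    f'points="{path}" fill="{color}" fill-opacity="0.4" stroke="{color}" '
                    f'stroke-opacity="0.6"/>'
                )
        out.append("</g>")

    out.append("</svg>")
    return "\n".join(out) + "\n"
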