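# cmapkit

Structural comparison of rule-based biochemical models through their contact
maps: a scriptable library and command-line tool for researchers who maintain
or survey *families* of BioNetGen-language (BNGL) models — branching versions
of one signaling model, or independently published models of the same pathway
— and need to see at a glance what the models share and where they differ.

## The idea

A rule-based model specifies cell-signaling biochemistry as reaction rules
over molecular patterns.  Even a modest rule set implies a combinatorially
large reaction network (hundreds of species, thousands of reactions), so
comparing models at the network level is hopeless.  The **contact map** is a
compact structural abstraction: one node per molecule type, containing one
node per binding site (*component*, with a 1-based occurrence index for
repeated same-named sites) and per internal *state*; an undirected edge for
every possible binding interaction named by any rule, optionally qualified by
the state the bond requires; and unstructured markers for synthesis and
degradation.  Every structure appears exactly once no matter how many rules
mention it: a 24-rule receptor model compresses to 5 molecules, 6 edges, and
3 state-modifiable sites.

Every element gets a canonical string identifier (`M`, `M.c#k`, `M.c#k~s`,
`{M.c#k[~s]|N.d#j[~t]}`, `M.@syn`, `M.@deg`); identifier equality is the sole
matching mechanism across models.  On top of this, cmapkit implements:

* **A graph-similarity metric.**  The metric's nodes are the rows of an
  adjacency-matrix abstraction (every state, plus every stateless component);
  its edges are the binding edges.  For models *G*, *H* it computes the
  shared-node count *n*, shared-edge count *e*, and the fractions
  *f_n*, *f_e* of the *smaller* graph's nodes/edges present in the larger, and
  combines them as

      S(G, H) = n · f_n + e · f_e

  so both large common cores and subgraph containment score highly: a
  subgraph scores *f_n* = *f_e* = 100 % against any supergraph, regardless of
  the size difference.

* **Family sorting.**  The *most complete* model (greatest rows + edges) is
  the reference; the rest are ordered by descending score against it, giving
  the row-wise small-multiples order.

* **Pairwise and family-wide comparison.**  Shared-element and
  difference-element sets over all element kinds, and single-element search
  across a family ("which members still contain this site?").

* **Layout stabilization.**  Deterministic force-directed layout with exact
  pass-through of pinned coordinates from a stored layout file, so shared
  elements occupy identical positions in every panel and visual differences
  reflect model differences only.

* **Export and rendering.**  GraphML / DOT / JSON export and grayscale SVG
  small multiples with green (similarity) or red-orange (difference) padded
  hull overlays; a panel whose difference set is empty (a pure subgraph)
  keeps a tinted background to show it takes part in the comparison.

* **A synthetic family generator** (`cmapkit.synthetic_fixtures`) that plants
  a common core plus known per-model edits and returns the full ground truth,
  so the whole pipeline is testable without external data.

Bundled under `cmapkit.examples` are synthetic reconstructions of two classic
signaling families (an EGF-receptor model and a four-member FcεRI family)
used throughout the tests and docs.

## Worked example

Put the bundled FcεRI-style family in a directory and ask for structure,
order, and differences:

```
$ cmapkit stats models/
model	n_molecules	n_components	n_states	n_modifiable	n_edges	n_unstructured	n_visual_nodes	n_matrix_rows
synthetic_fceri_base	4	9	6	3	4	0	19	12
synthetic_fceri_fyn	5	10	6	3	5	0	21	13
synthetic_fceri_fyn_trimer	5	11	6	3	5	0	22	14
synthetic_fceri_xlink	4	9	6	3	5	0	19	12

$ cmapkit sort models/
0	synthetic_fceri_fyn_trimer
1	synthetic_fceri_fyn
2	synthetic_fceri_base
3	synthetic_fceri_xlink
```

Each member's contact map has 4–5 edges; the trimer variant is the most
complete (14 rows + 5 edges) and leads the ordering, followed by the members
in decreasing similarity to it.  Now compare the two most similar members:

```
$ cmapkit compare models/ synthetic_fceri_fyn_trimer synthetic_fceri_fyn --mode differences
#cmapkit-report v1
mode	differences
models	synthetic_fceri_fyn_trimer	synthetic_fceri_fyn
only:synthetic_fceri_fyn_trimer	component	Lig.l#3
```

The two models differ by exactly one element — the third arm site of the
ligand (`Lig.l#3`).  The smaller model's difference set is empty because it
is a complete subgraph of the trimer variant; in a rendered comparison
(`cmapkit render models/ --highlight report.txt --out panels.svg`) its panel
is background-tinted with no overlay region.  `cmapkit layout --seed N` and a
`--reference` layout file pin shared elements to common coordinates across
all panels; `cmapkit generate --spec family.yaml` emits a synthetic family.

The same operations are available as library functions
(`parse_bngl`, `build_contact_map`, `similarity_matrices`, `sort_family`,
`compare_differences`, `stabilize_layouts`, `render_panels`, ...).

## Layout position files

```
#cmapkit-layout v1
Rec	120.0	80.0
Rec.b#1	131.5	92.25
```

Tab- (or whitespace-) separated `identifier x y` triples over molecule and
component identifiers; unknown identifiers are kept and resolved against each
model at stabilization time.  `docs/methods.md` documents the model,
conventions, and design choices in detail.
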