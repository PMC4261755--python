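# Methods

This note documents the procedures cmapkit implements, the conventions and
parameters behind them, and the design choices made where the design was
genuinely open.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The BNGL subset

The parser targets the structural content a contact map needs and nothing
more.  Supported: `begin X … end X` blocks for parameters, molecule types,
(seed) species, observables, functions, and reaction rules (`begin model`
optional); `#` comments; `\` line continuations; rule labels and leading
indices; reversible rules (`<->`, kept as one rule object with two rate
expressions); synthesis/degradation rules with an empty side written as `0`;
bond wildcards `!+` and `!?`; state wildcard `~?`.  Rates, parameters, and
functions are carried or skipped as opaque text and never evaluated.
Out of scope: compartments, energy patterns, local functions in rates, and
`DeleteMolecules` semantics — none of them affect the contact map.

Conventions that make identity well defined:

* **Occurrence indexing.**  Repeated same-named components of a molecule are
  distinguished by a 1-based occurrence index in declaration order; the i-th
  same-named component *written in a pattern* refers to occurrence i.  This
  positional convention matches common BNGL practice and fixes the meaning of
  "the same site" across models.
* **Auto-declaration.**  A molecule used in rules or seed species but absent
  from `molecule types` is declared silently from its maximal observed
  signature (many distributed models omit the block).  A state or component
  that contradicts an *explicit* declaration is appended with a warning.
* **Implicit whole-molecule component.**  A molecule declared with no
  components receives one component named after the molecule itself, so every
  molecule has at least one component (and hence at least one metric row).
* A numbered bond tag must appear exactly twice on one rule side; violations
  are parse errors naming the rule and tag.

## Contact-map construction

One molecule node per type; one component node per declared
(name, occurrence); state nodes from the declaration (already including
states first seen in rules).  An edge is recorded for every bond realized on
*either* side of *any* rule, keyed by its canonical identifier, with the set
of contributing rules attached — several rules may map to one edge, and
re-adding a rule never changes the element set.  Self-edges encode
homodimerization.

* **State-qualified endpoints.**  A bond endpoint carries a state qualifier
  only when the rule writes an explicit state on the bonded component on the
  side where the bond exists (e.g. an SH2 domain binding a site *in its
  phosphorylated state*).  Qualified and unqualified endpoints are distinct
  edge identities.
* **Modifiability.**  A component is flagged modifiable when some rule's
  multiset of explicit states for that (molecule, component, occurrence)
  differs between the two rule sides *and* the molecule appears on both
  sides.  The both-sides restriction keeps pure synthesis (`0 -> A(y~U)`)
  from counting as modification.  This per-rule heuristic is exact whenever
  rules write state changes explicitly — true of the model families this
  package targets — but it does not perform full rule-graph mapping, so a
  state change expressed only through molecule deletion/creation in one rule
  would be missed.
* **Wildcard bonds** (`!+`, `!?`) mark the component as binding but create no
  edge: there is no partner to identify.
* **Unstructured nodes.**  A rule with an empty reactant (product) side adds
  a synthesis (degradation) marker per molecule on the other side; a
  reversible rule with an empty side adds both.

Two node-count conventions are exposed side by side in `cmap_stats`, since
either may be meant by a "node count" for these graphs: *visual nodes*
(molecules + components + states + unstructured markers, the glyphs drawn)
and *matrix rows* (the metric's nodes, below).

## The similarity metric

The metric works on the adjacency-matrix abstraction built bottom-up: every
state is a row; a component is a row only if it has no states; molecules are
represented through their components and contribute no rows of their own.
For two models, four factors are computed by identifier equality (synonyms
are deliberately not matched — identifier equality is the contract):

* shared-node count `n` = |rows(G) ∩ rows(H)|,
* shared-edge count `e` = |edges(G) ∩ edges(H)|,
* node fraction `f_n` = n / min(|rows(G)|, |rows(H)|),
* edge fraction `f_e` = e / min(|edges(G)|, |edges(H)|),

combined as `S = n·f_n + e·f_e`.  Fractions are stored in [0, 1] (printed as
percentages in reports), which makes the self-score law exact:
`S(A, A) = |rows(A)| + |edges(A)|`.  When the smaller graph has no rows (or
edges) the corresponding fraction is defined as 0; the paired count is also
0, so the score is unchanged and no division is undefined.  Edges incident to
synthesis/degradation markers are not binding interactions and are excluded
from the edge totals by default; `include_unstructured=True` counts the
markers as edge items for users who want turnover reflected in the score.

Family ordering: the reference is the most complete member — argmax of
rows + edges, ties broken by model name ascending (all tie-breaks in the
package are lexicographic, for deterministic golden files) — and the
remaining members are sorted by descending score against it, names breaking
ties.

One subtlety relating the metric to element-set comparison: a component
identifier can be a metric row in one model (stateless there) yet not in the
other (stateful there).  The metric's shared-node count therefore equals
|shared elements ∩ rows(G) ∩ rows(H)|, not |shared ∩ rows(G)| alone; the test
suite pins this form of the consistency law.

## Comparison semantics

Shared set = intersection of canonical identifiers over all element kinds;
difference sets = the two set differences.  A component is shared even when
its state lists differ (the differing states then appear as differences); an
edge is shared only if both endpoints, including qualifiers, match.  If one
model is a complete subgraph of the other, its difference set is empty — the
rendered panel shows no overlay region and is marked as a comparison member
by its background tint instead.  The family-wide `find` operation returns a
boolean membership vector; an identifier present nowhere is a valid all-false
answer, while a grammatically invalid identifier is an error.

## Layout

Layouts are two-level.  Molecule boxes are placed by a seeded
Fruchterman–Reingold spring pass (networkx, 300 iterations, spacing scaled to
the largest box) over the molecule-adjacency graph — molecules are adjacent
when a binding edge joins their components; synthesis/degradation markers
attach to their molecule.  Components sit on a √n grid inside their box with
state nodes stacked beside their component; glyph sizes are fixed abstract
units (components 30×14, states 24×10, y-down).  Box extents are symmetric
around the molecule center and grown to contain every component and state
glyph, including pinned ones, so containment holds unconditionally.

Pinning is exact: coordinates named in a stored layout pass through
bit-identically (fixed nodes are never moved by the spring pass, and the
no-global-rescale rule applies whenever pins are present).  Stabilizing a
family against one reference layout pins every element the reference and the
model have in common and lays out the rest with a per-model seed derived as
`crc32(model name) XOR user seed`, so panels are stable across runs without
coupling between models.  A single unpinned molecule sits at the origin by
convention.  Reference entries that are not molecule or component
identifiers are warned about and ignored; entries naming elements absent
from a given model are expected (the reference usually comes from the most
complete member) and skipped silently.

Determinism — identical (contact map, seed, pins) giving identical layouts —
is the testable contract; no claim is made about crossing minimality.

## Rendering

One SVG, one panel per model, row-wise in family order, all panels at one
common scale (computed from the union of layout bounds) so stabilized
elements align across panels.  The base rendering is grayscale; highlight
overlays are drawn per connected group of highlighted elements (elements
group through their owning molecule; a highlighted edge bridges its endpoint
molecules) as a convex hull of the glyph corners, scaled uniformly about its
centroid so every input point stays strictly inside, with a bounding-box
fallback for degenerate (collinear or near-coincident) point sets.  This
padded-hull region is a deliberate simplification of contour-style
"bubble set" overlays: the testable guarantee — every highlighted glyph lies
geometrically inside its overlay region — is the property that matters, and
the test suite checks it from the SVG's own coordinates.  Similarity overlays
are green, difference overlays red-orange, both at 40 % opacity; comparison
panels get a light background tint even when their highlight set is empty.
Coordinates are printed at fixed precision, so identical inputs produce
byte-identical SVG.

## The synthetic generator and what passing tests show

The generator emulates how families arise in practice: a common core (by
default 4 molecules × 2 components, 40 % of components carrying a two-state
cycle, 4 binding edges — the scale of the signaling families above) with a
small per-model edit budget (by default one inserted molecule, component,
state, edge, and synthesis rule, and one deleted component and edge per
non-reference member; model 0 receives insertions only, making it a core
superset).  Edits apply in a fixed order (molecules, components, states,
edges, synthesis; deletions before insertions) so the bookkept ground truth
is unambiguous.  Deletions always remove the highest occurrence of a
same-named site, keeping occurrence indices contiguous, and never empty a
molecule or the family.  Names come from fixed pronounceable-token pools so
identifiers are stable and readable.

The ground truth (element sets, pairwise shared/difference sets, metric
factors and scores, most complete member, intended ordering) is computed by
direct bookkeeping on the generator's internal structures, duplicating the
identifier grammar locally rather than importing the modules under test.
The end-to-end property — parse → contact map → metric/comparison reproduces
the bookkeeping exactly across hundreds of seeded families — is the
package's central correctness argument.

Limits of that argument: generated models use unqualified edges, single-state
flip rules, and no wildcard bonds, so state-qualified edge identity,
wildcards, auto-declaration, and modifiability corner cases are covered by
the hand-written example models and unit tests instead; and generated BNGL is
regular, so parser robustness to the formatting variety of real distributed
files (continuations, labels, indices, unknown blocks) again rests on the
unit tests.  Passing the suite shows structural extraction and comparison are
correct on this class of models; it says nothing about kinetics, which the
package never interprets.

## Numerical and degenerate-input choices

* Fractions with zero denominators are 0 (see above); empty models are valid
  everywhere (empty id set, all-zero stats, score 0).
* Layout coordinates are finite floats; layout files serialize them with
  `repr`, so read/write round trips are exact, and entries are sorted by
  identifier for bit-stable output.
* All iteration orders that reach an output (exports, reports, SVG, CSV) are
  sorted; every random choice flows from an explicit integer seed.
* Hull padding is 8 px; the uniform-scale factor is `1 + pad/r_min` with a
  bounding-box fallback when the hull degenerates (fewer than three distinct
  points, collinearity, or `r_min` below 1e-6).

## Known limitations

* Models with similar but distinct rule sets can have identical contact maps;
  comparison is structural, not kinetic or rule-level.
* No synonym or ontology matching: `EGFR` and `egfr` are different elements.
  Harmonizing nomenclature is the user's step, as it is in practice.
* The modifiability heuristic is per-rule and multiset-based (see above).
* Stored-layout files use this package's own dialect; no importer for other
  tools' position formats is provided.
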