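"""Seeded generator of BNGL model families with bookkept ground truth.

Model families in practice grow out of a common core: researchers copy a
base model and insert or remove molecules, binding sites, states, and
interaction rules.  The generator emulates exactly that: it builds a random
core model, then derives each family member by applying a per-model edit
budget (deletions first, then insertions, in the fixed category order
molecules → components → states → edges → synthesis).  Model 0 receives only
the insertion half of its budget, so it is always a superset of the core and
the family's natural reference.

Alongside the BNGL texts the generator returns a :class:`GroundTruth` record
— per-model element-identifier sets, per-pair shared/difference sets, the
four similarity factors and combined score, the most complete member, and
the intended family ordering — computed by direct bookkeeping on its own
internal structures, never by calling the parsing/contact-map/similarity
modules it is used to test.

Rates are placeholder constants and are never evaluated; the generator aims
at structural, not kinetic, realism.  Molecule and component names come from
a fixed pronounceable-token list so identifiers stay stable and readable in
golden files.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

__all__ = [
    "EditBudget",
    "FamilySpec",
    "PairTruth",
    "GroundTruth",
    "InfeasibleSpecError",
    "generate_family",
    "family_spec_from_dict",
]


class InfeasibleSpecError(ValueError):
    """The requested family cannot be generated (e.g. more edges than
    component pairs, or deletions below one molecule)."""


# fixed name pools: pronounceable, unambiguous, stable across versions
_MOLECULE_TOKENS = [
    "Abrin", "Belor", "Cytar", "Dovin", "Erlan", "Fodra", "Gamil", "Hexor",
    "Ilvan", "Jorun", "Kelar", "Lomir", "Midra", "Norv", "Oblin", "Pexar",
    "Quorin", "Ruvel", "Soltan", "Tivar", "Ulmor", "Vexin", "Wolan", "Xirel",
    "Yoren", "Zovar",
]
_COMPONENT_TOKENS = [
    "ax", "bel", "cor", "dim", "eln", "fos", "gat", "hul", "irn", "jod",
    "kap", "lum", "mor", "nev", "oss", "pir", "qun", "rev", "sol", "tam",
]
_STATE_TOKENS = ["U", "P", "on", "off", "lo", "hi", "open", "shut"]


@dataclass
class EditBudget:
    """Counts of structural edits applied to one family member."""

    add_molecules: int = 0
    del_molecules: int = 0
    add_components: int = 0
    del_components: int = 0
    add_states: int = 0
    del_states: int = 0
    add_edges: int = 0
    del_edges: int = 0
    add_synthesis: int = 0

    def insertions_only(self) -> "EditBudget":
        return replace(self, del_molecules=0, del_components=0, del_states=0, del_edges=0)

    def validate(self) -> None:
        for name, value in vars(self).items():
            if value < 0:
                raise InfeasibleSpecError(f"edit budget {name} must be non-negative")


@dataclass
class FamilySpec:
    """Study conditions for one synthetic family: a handful of models built
    around a small common core with a few edits each, the scale of the
    signaling-model families the tool is meant for."""

    n_models: int = 4
    n_core_molecules: int = 4
    components_per_molecule: int = 2
    state_fraction: float = 0.4  # chance a core component carries a 2-state cycle
    n_core_edges: int = 4
    edits: EditBudget = field(
        default_factory=lambda: EditBudget(
            add_molecules=1,
            del_molecules=0,
            add_components=1,
            del_components=1,
            add_states=1,
            del_states=0,
            add_edges=1,
            del_edges=1,
            add_synthesis=1,
        )
    )
    seed: int = 0
    family_name: str = "fam"

    def validate(self) -> None:
        if self.n_models < 1:
            raise InfeasibleSpecError("n_models must be >= 1")
        if self.n_core_molecules < 1:
            raise InfeasibleSpecError("need at least one core molecule")
        if self.components_per_molecule < 1:
            raise InfeasibleSpecError("need at least one component per molecule")
        if not (0.0 <= self.state_fraction <= 1.0):
            raise InfeasibleSpecError("state_fraction must be in [0, 1]")
        self.edits.validate()
        if self.n_core_molecules - self.edits.del_molecules < 1:
            raise InfeasibleSpecError("edit budget deletes below one molecule")
        n_comp = self.n_core_molecules * self.components_per_molecule
        if self.n_core_edges > n_comp * (n_comp - 1) // 2:
            raise InfeasibleSpecError("requested core edges exceed available component pairs")
        if self.n_core_molecules > len(_MOLECULE_TOKENS) - self.edits.add_molecules * 2:
            raise InfeasibleSpecError("not enough molecule name tokens for this spec")


def family_spec_from_dict(data: dict) -> FamilySpec:
    """Build a spec from a plain mapping (the CLI's config-file format)."""
    data = dict(data)
    edits = EditBudget(**data.pop("edits", {}))
    return FamilySpec(edits=edits, **data)


# ---------------------------------------------------------------------------
# internal structure bookkeeping (independent of the modules under test)

Comp = tuple[str, int]  # (component name, occurrence)
EdgeT = tuple[tuple[str, str, int], tuple[str, str, int]]  # sorted endpoint pair


@dataclass
class _Struct:
    # molecule -> ordered list of (comp name, occurrence, states)
    molecules: dict[str, list[tuple[str, int, list[str]]]] = field(default_factory=dict)
    edges: set[EdgeT] = field(default_factory=set)
    synthesis: set[str] = field(default_factory=set)

    def copy(self) -> "_Struct":
        return _Struct(
            molecules={m: [(c, k, list(s)) for c, k, s in comps]
                       for m, comps in self.molecules.items()},
            edges=set(self.edges),
            synthesis=set(self.synthesis),
        )

    def component_triples(self) -> list[tuple[str, str, int]]:
        return [(m, c, k) for m in sorted(self.molecules)
                for c, k, _s in self.molecules[m]]

    # --- canonical identifiers, duplicated here on purpose: the ground truth
    # must not depend on the contact_map module it is used to check
    def element_ids(self) -> set[str]:
        ids: set[str] = set()
        for m, comps in self.molecules.items():
            ids.add(m)
            for c, k, states in comps:
                ids.add(f"{m}.{c}#{k}")
                ids.update(f"{m}.{c}#{k}~{s}" for s in states)
        for (m1, c1, k1), (m2, c2, k2) in self.edges:
            a, b = sorted((f"{m1}.{c1}#{k1}", f"{m2}.{c2}#{k2}"))
            ids.add("{" + a + "|" + b + "}")
        ids.update(f"{m}.@syn" for m in self.synthesis)
        return ids

    def matrix_rows(self) -> set[str]:
        rows: set[str] = set()
        for m, comps in self.molecules.items():
            for c, k, states in comps:
                if states:
                    rows.update(f"{m}.{c}#{k}~{s}" for s in states)
                else:
                    rows.add(f"{m}.{c}#{k}")
        return rows

    def edge_ids(self) -> set[str]:
        out = set()
        for (m1, c1, k1), (m2, c2, k2) in self.edges:
            a, b = sorted((f"{m1}.{c1}#{k1}", f"{m2}.{c2}#{k2}"))
            out.add("{" + a + "|" + b + "}")
        return out


def _norm_edge(a: tuple[str, str, int], b: tuple[str, str, int]) -> EdgeT:
    return tuple(sorted((a, b)))  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# ground truth containers


@dataclass
class PairTruth:
    nodes_shared: int
    edges_shared: int
    node_fraction: float
    edge_fraction: float
    score: float
    shared_elements: set[str]
    only_a: set[str]
    only_b: set[str]


@dataclass
class GroundTruth:
    model_names: list[str]
    element_ids: list[set[str]]
    matrix_rows: list[set[str]]
    edge_ids: list[set[str]]
    pairs: dict[tuple[int, int], PairTruth]
    most_complete: int
    ordering: list[int]
    added: list[set[str]]  # planted insertions vs the core, per model
    deleted: list[set[str]]  # planted deletions vs the core, per model


# ---------------------------------------------------------------------------
# generation


def _build_core(spec: FamilySpec, rng: random.Random) -> tuple[_Struct, list[str], list[str]]:
    mol_pool = list(_MOLECULE_TOKENS)
    comp_pool = list(_COMPONENT_TOKENS)
    core = _Struct()
    mol_names = [mol_pool.pop(0) for _ in range(spec.n_core_molecules)]
    for m in mol_names:
        comps = rng.sample(comp_pool, spec.components_per_molecule)
        entries = []
        for c in sorted(comps):
            states: list[str] = []
            if rng.random() < spec.state_fraction:
                states = list(rng.sample(_STATE_TOKENS, 2))
            entries.append((c, 1, states))
        core.molecules[m] = entries
    triples = core.component_triples()
    pairs = [
        (triples[i], triples[j])
        for i in range(len(triples))
        for j in range(i + 1, len(triples))
    ]
    if spec.n_core_edges > len(pairs):
        raise InfeasibleSpecError("requested core edges exceed available component pairs")
    for a, b in rng.sample(pairs, spec.n_core_edges):
        core.edges.add(_norm_edge(a, b))
    return core, mol_pool, comp_pool


def _apply_edits(
    struct: _Struct,
    budget: EditBudget,
    rng: random.Random,
    mol_pool: list[str],
    comp_pool: list[str],
) -> None:
    # deletions first within each category, categories in fixed order
    for _ in range(budget.del_molecules):
        candidates = sorted(struct.molecules)
        if len(candidates) <= 1:
            raise InfeasibleSpecError("cannot delete below one molecule")
        victim = rng.choice(candidates)
        del struct.molecules[victim]
        struct.edges = {e for e in struct.edges if e[0][0] != victim and e[1][0] != victim}
        struct.synthesis.discard(victim)
    for _ in range(budget.add_molecules):
        if not mol_pool:
            raise InfeasibleSpecError("molecule name pool exhausted")
        m = mol_pool.pop(0)
        n_comp = 1 + rng.randint(0, 1)
        comps = sorted(rng.sample(comp_pool, n_comp))
        struct.molecules[m] = [(c, 1, []) for c in comps]

    for _ in range(budget.del_components):
        # only the highest occurrence of a name may go, keeping indices contiguous
        candidates = []
        for m in sorted(struct.molecules):
            comps = struct.molecules[m]
            if len(comps) < 2:
                continue
            max_occ: dict[str, int] = {}
            for c, k, _s in comps:
                max_occ[c] = max(max_occ.get(c, 0), k)
            candidates.extend((m, c, k) for c, k in sorted(max_occ.items()))
        if not candidates:
            continue  # nothing deletable without emptying a molecule
        m, c, k = rng.choice(candidates)
        struct.molecules[m] = [e for e in struct.molecules[m] if not (e[0] == c and e[1] == k)]
        struct.edges = {
            e for e in struct.edges if (m, c, k) not in (e[0], e[1])
        }
    for _ in range(budget.add_components):
        m = rng.choice(sorted(struct.molecules))
        comps = struct.molecules[m]
        if rng.random() < 0.5 and comps:
            # duplicate an existing site name -> next occurrence index
            c = rng.choice(sorted({e[0] for e in comps}))
            k = max(e[1] for e in comps if e[0] == c) + 1
        else:
            used = {e[0] for e in comps}
            free = [c for c in comp_pool if c not in used]
            if not free:
                c = rng.choice(sorted(used))
                k = max(e[1] for e in comps if e[0] == c) + 1
            else:
                c, k = rng.choice(free), 1
        struct.molecules[m] = comps + [(c, k, [])]

    for _ in range(budget.del_states):
        candidates = [
            (m, i)
            for m in sorted(struct.molecules)
            for i, (_c, _k, s) in enumerate(struct.molecules[m])
            if s
        ]
        if not candidates:
            continue
        m, i = rng.choice(candidates)
        c, k, states = struct.molecules[m][i]
        struct.molecules[m][i] = (c, k, states[:-1])
    for _ in range(budget.add_states):
        candidates = [
            (m, i) for m in sorted(struct.molecules)
            for i in range(len(struct.molecules[m]))
        ]
        m, i = rng.choice(candidates)
        c, k, states = struct.molecules[m][i]
        free = [s for s in _STATE_TOKENS if s not in states]
        if not free:
            continue
        if states:
            new = [rng.choice(free)]
        else:  # a fresh 2-state cycle so the site is actually modifiable
            new = rng.sample(free, min(2, len(free)))
        struct.molecules[m][i] = (c, k, states + new)

    for _ in range(budget.del_edges):
        if not struct.edges:
            continue
        struct.edges.discard(rng.choice(sorted(struct.edges)))
    for _ in range(budget.add_edges):
        triples = struct.component_triples()
        pool = [
            _norm_edge(triples[i], triples[j])
            for i in range(len(triples))
            for j in range(i + 1, len(triples))
        ]
        free = [e for e in pool if e not in struct.edges]
        if not free:
            raise InfeasibleSpecError("no component pair left for a new edge")
        struct.edges.add(rng.choice(free))

    for _ in range(budget.add_synthesis):
        free = [m for m in sorted(struct.molecules) if m not in struct.synthesis]
        if not free:
            continue
        struct.synthesis.add(rng.choice(free))


# ---------------------------------------------------------------------------
# BNGL emission


def _occ_pattern(c: str, k: int, suffix: str) -> str:
    """Positional reference to occurrence ``k`` of component ``c``: the site
    name written k times, ``suffix`` attached to the k-th."""
    return ",".join([c] * (k - 1) + [c + suffix])


def _full_signature(comps: list[tuple[str, int, list[str]]]) -> str:
    return ",".join(c + (f"~{s[0]}" if s else "") for c, _k, s in comps)


def _emit_bngl(struct: _Struct, name: str) -> str:
    lines = [f"# {name} (generated synthetic model)", "begin model", "begin parameters"]
    lines += ["  kon 1.0", "  koff 0.1", "  kmod 1.0", "  ksyn 1.0", "end parameters"]
    lines.append("begin molecule types")
    for m in sorted(struct.molecules):
        decl = ",".join(
            c + "".join(f"~{s}" for s in states) for c, _k, states in struct.molecules[m]
        )
        lines.append(f"  {m}({decl})")
    lines.append("end molecule types")
    lines.append("begin seed species")
    for m in sorted(struct.molecules):
        lines.append(f"  {m}({_full_signature(struct.molecules[m])}) 100")
    lines.append("end seed species")
    lines.append("begin observables")
    for m in sorted(struct.molecules):
        lines.append(f"  Molecules {m}_total {m}()")
    lines.append("end observables")
    lines.append("begin reaction rules")
    for (m1, c1, k1), (m2, c2, k2) in sorted(struct.edges):
        lhs = f"{m1}({_occ_pattern(c1, k1, '')}) + {m2}({_occ_pattern(c2, k2, '')})"
        rhs = f"{m1}({_occ_pattern(c1, k1, '!1')}).{m2}({_occ_pattern(c2, k2, '!1')})"
        lines.append(f"  {lhs} <-> {rhs} kon, koff")
    for m in sorted(struct.molecules):
        for c, k, states in struct.molecules[m]:
            if len(states) >= 2:
                lines.append(
                    f"  {m}({_occ_pattern(c, k, '~' + states[0])}) -> "
                    f"{m}({_occ_pattern(c, k, '~' + states[1])}) kmod"
                )
    for m in sorted(struct.synthesis):
        lines.append(f"  0 -> {m}({_full_signature(struct.molecules[m])}) ksyn")
    lines.append("end reaction rules")
    lines.append("end model")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public entry point


def _pair_truth(a: _Struct, b: _Struct) -> PairTruth:
    rows_a, rows_b = a.matrix_rows(), b.matrix_rows()
    edges_a, edges_b = a.edge_ids(), b.edge_ids()
    nodes_shared = len(rows_a & rows_b)
    edges_shared = len(edges_a & edges_b)
    n_min = min(len(rows_a), len(rows_b))
    e_min = min(len(edges_a), len(edges_b))
    nf = nodes_shared / n_min if n_min else 0.0
    ef = edges_shared / e_min if e_min else 0.0
    ids_a, ids_b = a.element_ids(), b.element_ids()
    return PairTruth(
        nodes_shared=nodes_shared,
        edges_shared=edges_shared,
        node_fraction=nf,
        edge_fraction=ef,
        score=nodes_shared * nf + edges_shared * ef,
        shared_elements=ids_a & ids_b,
        only_a=ids_a - ids_b,
        only_b=ids_b - ids_a,
    )


def generate_family(spec: FamilySpec) -> tuple[list[str], GroundTruth]:
    """Generate a family of BNGL texts plus its bookkept ground truth.

    Deterministic: the same spec (including seed) yields byte-identical
    texts.  Model 0 is a superset of the core (insertions only); models
    1..n-1 receive the full edit budget, deletions before insertions.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    core, mol_pool, comp_pool = _build_core(spec, rng)

    structs: list[_Struct] = []
    names: list[str] = []
    for i in range(spec.n_models):
        struct = core.copy()
        budget = spec.edits.insertions_only() if i == 0 else spec.edits
        # each model draws names from its own copy of the pool so families
        # share inserted-name collisions only through the rng stream
        _apply_edits(struct, budget, rng, list(mol_pool), list(comp_pool))
        structs.append(struct)
        names.append(f"{spec.family_name}_{i:02d}")

    texts = [_emit_bngl(s, n) for s, n in zip(structs, names)]

    core_ids = core.element_ids()
    element_sets = [s.element_ids() for s in structs]
    pairs = {
        (i, j): _pair_truth(structs[i], structs[j])
        for i in range(spec.n_models)
        for j in range(i + 1, spec.n_models)
    }

    sizes = [
        (-(len(s.matrix_rows()) + len(s.edge_ids())), names[i], i)
        for i, s in enumerate(structs)
    ]
    ref = min(sizes)[2]

    def _score(i: int) -> float:
        if i == ref:
            return len(structs[ref].matrix_rows()) + len(structs[ref].edge_ids())
        key = (min(ref, i), max(ref, i))
        return pairs[key].score

    rest = sorted((i for i in range(spec.n_models) if i != ref),
                  key=lambda i: (-_score(i), names[i]))
    truth = GroundTruth(
        model_names=names,
        element_ids=element_sets,
        matrix_rows=[s.matrix_rows() for s in structs],
        edge_ids=[s.edge_ids() for s in structs],
        pairs=pairs,
        most_complete=ref,
        ordering=[ref] + rest,
        added=[ids - core_ids for ids in element_sets],
        deleted=[core_ids - ids for ids in element_sets],
    )
    return texts, truth
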