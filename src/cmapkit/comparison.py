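"""Pairwise shared/difference element sets and family-wide element search.

These are the data behind the similarity and difference overlays: given two
contact maps built under identical conventions, the shared set is the
intersection of their canonical element identifiers over every element kind
(molecules, components, states, edges, unstructured markers) and the
difference sets are the two set differences.  A component element is shared
even when its state lists differ — the differing states then show up as
difference elements — while an edge is shared only when both endpoints,
including any state qualifier, match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from cmapkit.contact_map import ContactMap, element_ids, parse_element_id

__all__ = [
    "ComparisonResult",
    "compare_similarities",
    "compare_differences",
    "find_element",
]


@dataclass
class ComparisonResult:
    mode: str  # "similarities" | "differences" | "find"
    model_names: list[str]
    shared: set[str] = field(default_factory=set)  # similarities mode
    only_a: set[str] = field(default_factory=set)  # differences mode
    only_b: set[str] = field(default_factory=set)
    membership: list[bool] = field(default_factory=list)  # find mode
    query: str | None = None


def compare_similarities(a: ContactMap, b: ContactMap) -> ComparisonResult:
    """Elements present in both models (identifier equality, all kinds)."""
    return ComparisonResult(
        mode="similarities",
        model_names=[a.name, b.name],
        shared=element_ids(a) & element_ids(b),
    )


def compare_differences(a: ContactMap, b: ContactMap) -> ComparisonResult:
    """Elements present in exactly one of the two models.

    When one model is a complete subgraph of the other, its ``only`` set is
    empty — the overlay on that panel is an empty region and the panel is
    marked as a comparison member by its background tint instead.
    """
    ids_a, ids_b = element_ids(a), element_ids(b)
    return ComparisonResult(
        mode="differences",
        model_names=[a.name, b.name],
        only_a=ids_a - ids_b,
        only_b=ids_b - ids_a,
    )


def find_element(family: list[ContactMap], element: str) -> ComparisonResult:
    """Locate one element across a whole family.

    Returns a boolean membership vector aligned with ``family``.  The
    identifier must be syntactically valid (:class:`ElementIdError`
    otherwise); an identifier present nowhere yields all-false.
    """
    parse_element_id(element)  # validates; raises ElementIdError on bad input
    return ComparisonResult(
        mode="find",
        model_names=[c.name for c in family],
        membership=[element in element_ids(c) for c in family],
        query=element,
    )


# ---------------------------------------------------------------------------
# structured-text report (consumed by the render module as highlight sets)

_REPORT_HEADER = "#cmapkit-report v1"


def report_text(result: ComparisonResult) -> str:
    """Serialize a comparison result as a line-oriented, machine-readable
    report: a header, a ``mode`` line, a ``models`` line, then one
    ``<set>\\t<kind>\\t<element id>`` line per element, sorted."""
    lines = [_REPORT_HEADER, f"mode\t{result.mode}", "models\t" + "\t".join(result.model_names)]
    if result.query is not None:
        lines.append(f"query\t{result.query}")

    def emit(setname: str, ids: set[str]) -> None:
        for eid in sorted(ids):
            kind, _ = parse_element_id(eid)
            lines.append(f"{setname}\t{kind}\t{eid}")

    if result.mode == "similarities":
        emit("shared", result.shared)
    elif result.mode == "differences":
        emit(f"only:{result.model_names[0]}", result.only_a)
        emit(f"only:{result.model_names[1]}", result.only_b)
    elif result.mode == "find":
        for name, present in zip(result.model_names, result.membership):
            lines.append(f"member\t{name}\t{'true' if present else 'false'}")
    return "\n".join(lines) + "\n"


def parse_report(text: str) -> ComparisonResult:
    """Inverse of :func:`report_text`."""
    mode = ""
    names: list[str] = []
    result = ComparisonResult(mode="", model_names=[])
    members: dict[str, bool] = {}
    for line in text.splitlines():
        line = line.rstrip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        key = parts[0]
        if key == "mode":
            mode = parts[1]
        elif key == "models":
            names = parts[1:]
        elif key == "query":
            result.query = parts[1]
        elif key == "shared":
            result.shared.add(parts[2])
        elif key.startswith("only:"):
            model = key[len("only:"):]
            if names and model == names[0]:
                result.only_a.add(parts[2])
            else:
                result.only_b.add(parts[2])
        elif key == "member":
            members[parts[1]] = parts[2] == "true"
    result.mode = mode
    result.model_names = names
    if mode == "find":
        result.membership = [members.get(n, False) for n in names]
    return result
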