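"""Bundled example models (all synthetic).

These files are synthetic reconstructions written for this package, in the
style of two classic cell-signaling rule-based model families:

* ``synthetic_egfr`` — EGF receptor signaling (egf, egfr, Grb2, Shc, Sos):
  24 reaction rules compressing to a contact map with 5 molecule nodes, 6
  binding edges, and 3 modifiable components.
* ``synthetic_fceri_*`` — a four-member FceRI (high-affinity IgE receptor)
  family sharing a Lig/Lyn/Rec/Syk core, each member's contact map having 4
  or 5 edges.  ``synthetic_fceri_fyn_trimer`` differs from
  ``synthetic_fceri_fyn`` by exactly one element: the third ligand arm site
  ``Lig.l#3``.

They are test fixtures and documentation material, not curated published
models; kinetic parameters are plausible placeholders and are never used by
this package.
"""

from __future__ import annotations

from importlib import resources

from cmapkit.bngl_io import Model, parse_bngl

__all__ = ["example_names", "example_text", "example_model", "example_family"]


def example_names() -> list[str]:
    root = resources.files(__package__)
    return sorted(p.name[: -len(".bngl")] for p in root.iterdir() if p.name.endswith(".bngl"))


def example_text(name: str) -> str:
    return (resources.files(__package__) / f"{name}.bngl").read_text()


def example_model(name: str) -> Model:
    return parse_bngl(example_text(name), name=name)


def example_family(prefix: str) -> list[Model]:
    """All bundled models whose name starts with ``prefix``, sorted by name."""
    names = [n for n in example_names() if n.startswith(prefix)]
    if not names:
        raise KeyError(f"no bundled example matches prefix {prefix!r}")
    return [example_model(n) for n in names]
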