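"""Named path-model fixtures: starting models, saturated search frameworks,
and fitted models with their published standardized coefficients.

Coefficients printed in the Results body text are stored as ``printed``;
values that appear only in figure graphics are stored as ``placeholder`` with
implementer-chosen simulation defaults (documented in the spec files) and must
never be asserted as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .sem import PathModel, parse_model_spec

__all__ = ["CatalogEntry", "load_entry", "list_entries"]

_PACKAGE_DIR = "seasonfire.catalog_specs"


@dataclass(frozen=True)
class CatalogEntry:
    name: str
    model: PathModel
    role: str  # starting | saturated-framework | fitted-best
    provenance: dict  # edge name -> "printed" | "placeholder"
    optional_edges: tuple

    @property
    def printed_edges(self) -> dict[str, float]:
        """Edge name -> coefficient, restricted to text-printed values."""
        fixed = {e.name: e.value for e in self.model.edges if not e.free}
        return {k: fixed[k] for k, v in self.provenance.items() if v == "printed"}


def list_entries() -> list[str]:
    files = resources.files(_PACKAGE_DIR)
    return sorted(f.name[:-4] for f in files.iterdir() if f.name.endswith(".sem"))


def load_entry(name: str) -> CatalogEntry:
    """Load a catalog model by name; raises KeyError for unknown names."""
    ref = resources.files(_PACKAGE_DIR).joinpath(f"{name}.sem")
    if not ref.is_file():
        raise KeyError(f"unknown catalog entry {name!r}; available: {', '.join(list_entries())}")
    model, meta = parse_model_spec(ref.read_text(), name=name)
    return CatalogEntry(
        name=name,
        model=model,
        role=meta["role"],
        provenance=meta["provenance"],
        optional_edges=tuple(meta["optional_edges"]),
    )
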