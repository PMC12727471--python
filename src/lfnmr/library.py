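"""Bundled metabolite spin-system parameter library.

The library is a JSON asset mapping species names to one or more
:class:`~lfnmr.spinsim.SpinSystem` records (shifts in ppm, scalar
couplings in Hz, relative molar populations). A record may declare a
``parent`` name under which several forms are grouped; the bundled
glucose entry expands to its alpha and beta pyranose anomers with
equilibrium populations 0.36 and 0.64.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from pathlib import Path

from .spinsim import SpinSystem

__all__ = ["load_metabolite_library", "default_library_path"]

_REQUIRED_KEYS = {"name", "spins", "couplings"}


def default_library_path() -> Path:
    """Path of the JSON parameter library shipped with the package."""
    return Path(str(resources.files("lfnmr").joinpath("data/metabolites.json")))


def _parse_system(rec: dict) -> SpinSystem:
    missing = _REQUIRED_KEYS - rec.keys()
    if missing:
        raise ValueError(
            f"metabolite record {rec.get('name', '<unnamed>')!r} is missing "
            f"required field(s): {sorted(missing)}")
    shifts = [s["shift_ppm"] for s in rec["spins"]]
    eq = rec.get("equivalence_groups")
    return SpinSystem(
        name=rec["name"],
        shifts=tuple(float(s) for s in shifts),
        couplings=tuple(tuple(float(x) for x in row) for row in rec["couplings"]),
        population=float(rec.get("population", 1.0)),
        equivalence_groups=(tuple(tuple(g) for g in eq) if eq else None),
        source_id=rec.get("source_id", ""),
    )


@lru_cache(maxsize=8)
def _load_cached(path_str: str) -> dict[str, tuple[SpinSystem, ...]]:
    with open(path_str) as fh:
        doc = json.load(fh)
    if "systems" not in doc:
        raise ValueError(f"{path_str}: missing top-level 'systems' field")
    library: dict[str, list[SpinSystem]] = {}
    for rec in doc["systems"]:
        system = _parse_system(rec)
        library.setdefault(rec["name"], []).append(system)
        parent = rec.get("parent")
        if parent:
            library.setdefault(parent, []).append(system)
    return {k: tuple(v) for k, v in library.items()}


def load_metabolite_library(path: str | Path | None = None
                            ) -> dict[str, tuple[SpinSystem, ...]]:
    """Load and validate a metabolite parameter library.

    Returns a mapping from species name to the tuple of spin systems the
    name resolves to. Validation (symmetric couplings, non-negative
    populations, spin-count caps) happens in the SpinSystem constructor
    and raises ``ValueError`` naming the offending field.
    """
    if path is None:
        path = default_library_path()
    return dict(_load_cached(str(path)))
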