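"""Leaf-morphology species matching for North American shrub birches.

Each candidate species is described by a blade-shape category, a leaf-size
range (length x width, cm, inclusive), a margin category and a teeth-shape
category.  A species is a candidate for a leaf iff its blade shape and teeth
categories match and the measured length and width fall inside the species
ranges; several species may match, or none.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["LeafTraits", "SPECIES_KEYS", "match_species"]

BLADE_SHAPES = (
    "obovate-orbicular",
    "elliptic-obovate-orbicular",
    "ovate-rhombic-ovate",
    "orbiculate-reniform",
)
MARGINS = (
    "dentate-crenate",
    "crenate-dentate",
    "sharply/doubly-serrate",
    "deeply-crenate",
)
TEETH = (
    "obtuse-rounded",
    "acute-obtuse-rounded",
    "long-sharp",
    "rounded",
)


@dataclass
class LeafTraits:
    blade_shape: str
    length_cm: float
    width_cm: float
    margin: str
    teeth: str

    def validate(self) -> None:
        if self.blade_shape not in BLADE_SHAPES:
            raise ValueError(f"unknown blade shape {self.blade_shape!r}")
        if self.margin not in MARGINS:
            raise ValueError(f"unknown margin {self.margin!r}")
        if self.teeth not in TEETH:
            raise ValueError(f"unknown teeth shape {self.teeth!r}")
        if self.length_cm <= 0 or self.width_cm <= 0:
            raise ValueError("leaf dimensions must be positive")


@dataclass(frozen=True)
class _SpeciesKey:
    blade_shape: str
    length_range: tuple[float, float]
    width_range: tuple[float, float]
    margin: str
    teeth: str


#: diagnostic leaf keys; teeth categories overlapping between species are
#: listed for every species they apply to
SPECIES_KEYS: dict[str, _SpeciesKey] = {
    "Betula glandulosa": _SpeciesKey(
        "obovate-orbicular", (0.5, 3.0), (1.0, 2.5),
        "dentate-crenate", "obtuse-rounded"),
    "Betula pumila": _SpeciesKey(
        "elliptic-obovate-orbicular", (2.5, 5.0), (1.0, 5.0),
        "crenate-dentate", "acute-obtuse-rounded"),
    "Betula occidentalis": _SpeciesKey(
        "ovate-rhombic-ovate", (2.0, 5.8), (1.0, 4.5),
        "sharply/doubly-serrate", "long-sharp"),
    "Betula nana ssp. exilis": _SpeciesKey(
        "orbiculate-reniform", (0.5, 1.2), (0.5, 1.6),
        "deeply-crenate", "rounded"),
}

#: teeth categories considered compatible (a rounded apex satisfies both the
#: strictly rounded and the obtuse-to-rounded descriptions)
_TEETH_COMPAT = {
    "obtuse-rounded": {"obtuse-rounded", "rounded"},
    "acute-obtuse-rounded": {"acute-obtuse-rounded", "obtuse-rounded", "rounded"},
    "long-sharp": {"long-sharp"},
    "rounded": {"rounded"},
}


def match_species(traits: LeafTraits) -> set[str]:
    """Candidate species whose blade shape and teeth match and whose size
    ranges (inclusive) contain the measured leaf."""
    traits.validate()
    out = set()
    for name, key in SPECIES_KEYS.items():
        if key.blade_shape != traits.blade_shape:
            continue
        if traits.teeth not in _TEETH_COMPAT[key.teeth]:
            continue
        lo, hi = key.length_range
        wlo, whi = key.width_range
        if lo <= traits.length_cm <= hi and wlo <= traits.width_cm <= whi:
            out.add(name)
    return out
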