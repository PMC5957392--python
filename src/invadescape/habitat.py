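"""Habitat class registry.

Eleven categorical habitat classes cover every raster cell. Codes follow the
fixed composition ordering used throughout the analysis (unsuitable = 0 ...
shrubland = 10); this ordering also fixes the on-disk dialect of the ASCII
rasters and the first eleven entries of the landscape metric vector.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "HabitatClass",
    "CLASSES",
    "CLASS_NAMES",
    "CODE_BY_NAME",
    "N_CLASSES",
    "UNSUITABLE",
    "GRASSLAND",
    "DECIDUOUS",
    "CONIFEROUS",
    "MIXED_FOREST",
    "PASTURE",
    "CROP",
    "ROAD",
    "WETLAND",
    "WATER",
    "SHRUBLAND",
    "BARRIER_CODES",
    "SUITABLE_CODES",
]


@dataclass(frozen=True)
class HabitatClass:
    """One categorical habitat type: an integer code and a canonical name."""

    code: int
    name: str


CLASS_NAMES: tuple[str, ...] = (
    "unsuitable",
    "grassland",
    "deciduous forest",
    "coniferous forest",
    "mixed forest",
    "pasture",
    "crop",
    "road",
    "wetland",
    "water",
    "shrubland",
)

CLASSES: tuple[HabitatClass, ...] = tuple(
    HabitatClass(code, name) for code, name in enumerate(CLASS_NAMES)
)

CODE_BY_NAME: dict[str, int] = {c.name: c.code for c in CLASSES}

N_CLASSES = len(CLASSES)

UNSUITABLE = 0
GRASSLAND = 1
DECIDUOUS = 2
CONIFEROUS = 3
MIXED_FOREST = 4
PASTURE = 5
CROP = 6
ROAD = 7
WETLAND = 8
WATER = 9
SHRUBLAND = 10

# Classes the invader can never occupy: no growth, no establishment.
BARRIER_CODES: frozenset[int] = frozenset({UNSUITABLE, ROAD, WATER})

# Classes with positive expansion rate where plants can establish and grow.
SUITABLE_CODES: frozenset[int] = frozenset(range(N_CLASSES)) - BARRIER_CODES
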