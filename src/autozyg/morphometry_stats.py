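"""Closed-form morphometry utilities: spindle angle, Cavalieri volume, PI.

Small, exactly specified quantities used in the downstream phenotype work:
the mitotic spindle-plane angle (acute angle between the ventricular surface
and the line connecting the two centrosomes, in degrees), Cavalieri volume
estimation from systematically sampled section areas, and the dye-dilution
proliferation index from per-generation flow-cytometry counts,

    PI = sum_i N_Gi / sum_i (N_Gi / 2^i),

i.e. total cells over the back-calculated number of founding cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

Point = tuple[float, float]


@dataclass(frozen=True)
class SpindleMeasurement:
    """Two centrosome positions and two points defining the ventricular surface (um)."""

    centrosome_a: Point
    centrosome_b: Point
    surface_a: Point
    surface_b: Point

    def __post_init__(self) -> None:
        if self.centrosome_a == self.centrosome_b:
            raise ValueError("centrosome points coincide; spindle axis undefined")
        if self.surface_a == self.surface_b:
            raise ValueError("surface points coincide; surface line undefined")


@dataclass(frozen=True)
class GenerationCounts:
    """Cell counts per division generation G0..Gn from dye-dilution gating."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError("generation counts must be non-negative")
        if not self.counts or not any(self.counts):
            raise ValueError("at least one generation count must be nonzero")


def spindle_angle(m: SpindleMeasurement) -> float:
    """Acute angle (degrees, in [0, 90]) between spindle axis and surface line.

    Symmetric in the order of the centrosome (and surface) points and
    invariant under joint translation, rotation and scaling.
    """
    vx = m.centrosome_b[0] - m.centrosome_a[0]
    vy = m.centrosome_b[1] - m.centrosome_a[1]
    sx = m.surface_b[0] - m.surface_a[0]
    sy = m.surface_b[1] - m.surface_a[1]
    dot = abs(vx * sx + vy * sy)
    cross = abs(vx * sy - vy * sx)
    return math.degrees(math.atan2(cross, dot))


def cavalieri_volume(
    section_areas: Sequence[float],
    section_thickness: float,
    sampling_interval: int = 1,
) -> float:
    """Cavalieri volume estimate: sum(areas) x (thickness x sampling interval).

    ``sampling_interval`` is the systematic sampling period (e.g. 10 when
    every tenth section of thickness 10 um is measured, giving 100 um between
    measured sections).  Units follow the inputs (um^2 x um -> um^3).
    """
    if len(section_areas) == 0:
        raise ValueError("need at least one section area")
    if any(a < 0 for a in section_areas):
        raise ValueError("section areas must be non-negative")
    if section_thickness <= 0:
        raise ValueError("section thickness must be positive")
    if sampling_interval < 1:
        raise ValueError("sampling interval must be >= 1")
    return float(sum(section_areas)) * section_thickness * sampling_interval


def proliferation_index(c: GenerationCounts) -> float:
    """Dye-dilution proliferation index, >= 1, equal to 1 iff nothing divided."""
    total = sum(c.counts)
    founders = sum(n / 2**i for i, n in enumerate(c.counts))
    return total / founders
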