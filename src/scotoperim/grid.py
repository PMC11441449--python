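"""Test-grid geometry for fundus-controlled perimetry.

Coordinates are retinal degrees with the origin at the anatomical
fovea / fixation locus.  In right-eye (OD) convention +x points toward
the temporal retina and +y toward the superior retina; left-eye exams
are mirrored into this convention before any hemifield analysis (see
:func:`scotoperim.exam.normalize_eye`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull


class GridKind(str, Enum):
    SCOTOPIC_RADIAL_37 = "scotopic_radial_37"
    MESOPIC_10_2 = "mesopic_10_2"
    CUSTOM = "custom"


#: Default ring radii (degrees) for the 37-point scotopic radial grid:
#: one central locus plus three rings of 12.  The device's exact radii
#: are not published; these are configurable and chosen so the grid
#: footprint (147 deg^2 convex hull) is consistent with healthy
#: volume-to-mean sensitivity ratios.
DEFAULT_SCOTOPIC_RING_RADII = (1.0, 3.0, 7.0)
DEFAULT_POINTS_PER_RING = 12


class InvalidGeometryError(ValueError):
    """Raised for degenerate or ill-ordered grid geometry."""


@dataclass(frozen=True)
class Locus:
    id: int
    x: float
    y: float
    ring_index: int  # 0 = central locus


@dataclass(frozen=True)
class Grid:
    """An ordered set of test loci.

    Construction is deterministic: equal parameters always produce
    identical locus layouts, so serialized grids compare equal across
    runs.
    """

    loci: tuple[Locus, ...]
    kind: GridKind = GridKind.CUSTOM
    ring_radii: tuple[float, ...] = field(default=())
    points_per_ring: int = 0

    def __post_init__(self) -> None:
        ids = [l.id for l in self.loci]
        if len(set(ids)) != len(ids):
            raise InvalidGeometryError("locus ids must be unique")
        for l in self.loci:
            if not (math.isfinite(l.x) and math.isfinite(l.y)):
                raise InvalidGeometryError(f"non-finite coordinate at locus {l.id}")
        if self.kind is GridKind.SCOTOPIC_RADIAL_37:
            n_central = sum(1 for l in self.loci if l.x == 0.0 and l.y == 0.0)
            if len(self.loci) != 37 or n_central != 1:
                raise InvalidGeometryError(
                    "scotopic_radial_37 requires 37 loci with exactly one at the origin"
                )

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of locus coordinates in degrees, in locus order."""
        return np.array([[l.x, l.y] for l in self.loci], dtype=float)

    @property
    def locus_ids(self) -> np.ndarray:
        return np.array([l.id for l in self.loci], dtype=int)

    def central_index(self) -> int | None:
        """Index of the locus at the origin, or ``None`` if absent."""
        for i, l in enumerate(self.loci):
            if l.x == 0.0 and l.y == 0.0:
                return i
        return None

    def hull_area(self) -> float:
        """Area of the convex hull of the loci, in deg^2."""
        return float(ConvexHull(self.xy).volume)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind.value,
            "ring_radii": list(self.ring_radii),
            "points_per_ring": self.points_per_ring,
            "loci": [[l.id, l.x, l.y, l.ring_index] for l in self.loci],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @staticmethod
    def from_json(path: str | Path) -> "Grid":
        payload = json.loads(Path(path).read_text())
        kind = GridKind(payload["kind"])
        if payload.get("loci"):
            loci = tuple(Locus(int(i), float(x), float(y), int(r))
                         for i, x, y, r in payload["loci"])
            return Grid(loci, kind, tuple(payload.get("ring_radii", ())),
                        int(payload.get("points_per_ring", 0)))
        return build_grid(kind, payload.get("ring_radii"),
                          payload.get("points_per_ring", DEFAULT_POINTS_PER_RING))


def build_grid(
    kind: GridKind | str = GridKind.SCOTOPIC_RADIAL_37,
    ring_radii: Sequence[float] | None = None,
    points_per_ring: int = DEFAULT_POINTS_PER_RING,
) -> Grid:
    """Build a test grid.

    Radial grids place a central locus (id 0) plus ``points_per_ring``
    loci on each ring, at angles 2*pi*k/points_per_ring starting on the
    +x (temporal, OD) axis, counter-clockwise.  The mesopic variant is
    the rectilinear 10-2 pattern (68 loci on a 2-degree lattice offset
    by 1 degree, within 10 degrees of fixation).

    Raises
    ------
    InvalidGeometryError
        If ring radii are not strictly increasing and positive, or
        ``points_per_ring`` < 3.
    """
    kind = GridKind(kind)
    if kind is GridKind.MESOPIC_10_2:
        return _build_10_2()
    if ring_radii is None:
        ring_radii = DEFAULT_SCOTOPIC_RING_RADII
    radii = [float(r) for r in ring_radii]
    if any(r <= 0 for r in radii) or any(b <= a for a, b in zip(radii, radii[1:])):
        raise InvalidGeometryError("ring radii must be positive and strictly increasing")
    if points_per_ring < 3:
        raise InvalidGeometryError("points_per_ring must be >= 3")

    loci = [Locus(0, 0.0, 0.0, 0)]
    next_id = 1
    for ring, r in enumerate(radii, start=1):
        for k in range(points_per_ring):
            theta = 2.0 * math.pi * k / points_per_ring
            x = r * math.cos(theta)
            y = r * math.sin(theta)
            # snap values that are exactly on an axis to avoid -0.0 / 1e-16 residue
            if abs(x) < 1e-12:
                x = 0.0
            if abs(y) < 1e-12:
                y = 0.0
            loci.append(Locus(next_id, x, y, ring))
            next_id += 1
    if kind is GridKind.SCOTOPIC_RADIAL_37 and len(loci) != 37:
        kind = GridKind.CUSTOM
    return Grid(tuple(loci), kind, tuple(radii), points_per_ring)


def _build_10_2() -> Grid:
    """Rectilinear 10-2: 68 loci at odd-degree offsets within 10 deg."""
    loci = []
    next_id = 0
    coords = [-9, -7, -5, -3, -1, 1, 3, 5, 7, 9]
    for y in reversed(coords):
        for x in coords:
            if x * x + y * y < 90:  # keeps 17 loci per quadrant = 68 total
                loci.append(Locus(next_id, float(x), float(y), -1))
                next_id += 1
    return Grid(tuple(loci), GridKind.MESOPIC_10_2, (), 0)
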