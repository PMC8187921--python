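"""Disk-template geometry for unfolded left-atrium (LA) tissues.

The unfolded LA is a disk of standard diameter 150 mm rasterised at
0.3 mm/pixel (500 x 500 grid by default).  The mitral valve maps to the
disk border; the four pulmonary veins (LSPV, LIPV, RSPV, RIPV) and the
left atrial appendage (LAA) are circular openings strictly inside the
disk.  Everything outside the disk or inside an opening is void
(non-conducting, background).

Raster convention: row-major arrays indexed ``[row, col]``; physical
coordinates in mm with x rightward (columns), y downward (rows), origin
at the top-left grid corner; the centre of pixel ``[i, j]`` is at
``((j + 0.5) * pixel_size, (i + 0.5) * pixel_size)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

PV_NAMES = ("LSPV", "LIPV", "RSPV", "RIPV")


class GeometryError(ValueError):
    """Raised when openings overlap each other or leave the disk."""


@dataclass(frozen=True)
class DiskTemplate:
    """Geometry of one unfolded-LA disk.

    All lengths are in mm; ``grid_shape`` is (rows, cols).
    """

    grid_shape: tuple[int, int]
    pixel_size: float
    disk_radius: float
    pv_centres: dict[str, tuple[float, float]]
    pv_radii: dict[str, float]
    laa_centre: tuple[float, float]
    laa_radius: float

    @property
    def centre(self) -> tuple[float, float]:
        ny, nx = self.grid_shape
        return (nx * self.pixel_size / 2.0, ny * self.pixel_size / 2.0)

    # -- masks ---------------------------------------------------------

    def pixel_coords(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) mm coordinates of every pixel centre, each (rows, cols)."""
        ny, nx = self.grid_shape
        x = (np.arange(nx) + 0.5) * self.pixel_size
        y = (np.arange(ny) + 0.5) * self.pixel_size
        return np.meshgrid(x, y)

    def disk_mask(self) -> np.ndarray:
        x, y = self.pixel_coords()
        cx, cy = self.centre
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.disk_radius**2

    def openings(self) -> dict[str, tuple[tuple[float, float], float]]:
        ops = {name: (self.pv_centres[name], self.pv_radii[name]) for name in PV_NAMES}
        ops["LAA"] = (self.laa_centre, self.laa_radius)
        return ops

    def opening_mask(self) -> np.ndarray:
        x, y = self.pixel_coords()
        mask = np.zeros(self.grid_shape, dtype=bool)
        for (ox, oy), r in self.openings().values():
            mask |= (x - ox) ** 2 + (y - oy) ** 2 <= r**2
        return mask

    def tissue_mask(self) -> np.ndarray:
        """True where myocardium can exist (inside disk, outside openings)."""
        return self.disk_mask() & ~self.opening_mask()

    # -- validation ----------------------------------------------------

    def validate(self) -> None:
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.disk_radius <= 0:
            raise GeometryError("disk_radius must be positive")
        ny, nx = self.grid_shape
        cx, cy = self.centre
        if cx < self.disk_radius or cy < self.disk_radius:
            raise GeometryError("grid does not cover the disk")
        items = list(self.openings().items())
        for name, ((ox, oy), r) in items:
            if r <= 0:
                raise GeometryError(f"{name}: non-positive radius")
            d = math.hypot(ox - cx, oy - cy)
            if d + r >= self.disk_radius:
                raise GeometryError(f"{name}: opening not strictly inside the disk")
        for i, (na, ((xa, ya), ra)) in enumerate(items):
            for nb, ((xb, yb), rb) in items[i + 1 :]:
                if math.hypot(xa - xb, ya - yb) <= ra + rb:
                    raise GeometryError(f"openings {na} and {nb} overlap")

    def with_openings(
        self,
        pv_centres: dict[str, tuple[float, float]] | None = None,
        pv_radii: dict[str, float] | None = None,
    ) -> "DiskTemplate":
        """Copy of this template with replaced PV geometry (validated)."""
        t = DiskTemplate(
            grid_shape=self.grid_shape,
            pixel_size=self.pixel_size,
            disk_radius=self.disk_radius,
            pv_centres=dict(pv_centres or self.pv_centres),
            pv_radii=dict(pv_radii or self.pv_radii),
            laa_centre=self.laa_centre,
            laa_radius=self.laa_radius,
        )
        t.validate()
        return t


def _default_layout(centre: tuple[float, float], disk_radius: float):
    """PVs on a ring at 0.45 x disk radius, LAA below-left of centre.

    The unfold-map literature fixes no canonical coordinates for the
    openings, so this layout is a parameterised convention: left pair
    (LSPV/LIPV) left of centre, right pair right of centre, superior
    veins above (smaller y), LAA between the centre and the left
    inferior vein.
    """
    cx, cy = centre
    ring = 0.45 * disk_radius
    o = ring / math.sqrt(2.0)
    pv_centres = {
        "LSPV": (cx - o, cy - o),
        "LIPV": (cx - o, cy + o),
        "RSPV": (cx + o, cy - o),
        "RIPV": (cx + o, cy + o),
    }
    laa_centre = (cx - 0.133 * disk_radius, cy + 0.187 * disk_radius)
    return pv_centres, laa_centre


def make_disk_template(
    disk_diameter: float = 150.0,
    pixel_size: float = 0.3,
    grid_shape: tuple[int, int] | None = None,
    pv_centres: dict[str, tuple[float, float]] | None = None,
    pv_radii: dict[str, float] | float = 6.0,
    laa_centre: tuple[float, float] | None = None,
    laa_radius: float = 9.0,
) -> DiskTemplate:
    """Build a validated :class:`DiskTemplate`.

    Defaults give the standard 150 mm disk at 0.3 mm/pixel on a 500x500
    grid, PV opening radius 6 mm and LAA radius 9 mm.  ``pv_centres`` /
    ``laa_centre`` default to the ring layout of :func:`_default_layout`.

    Raises :class:`GeometryError` for openings that overlap or leave the
    disk.
    """
    if pixel_size <= 0:
        raise GeometryError("pixel_size must be positive")
    disk_radius = disk_diameter / 2.0
    if grid_shape is None:
        n = int(math.ceil(disk_diameter / pixel_size))
        grid_shape = (n, n)
    ny, nx = grid_shape
    centre = (nx * pixel_size / 2.0, ny * pixel_size / 2.0)
    default_pvs, default_laa = _default_layout(centre, disk_radius)
    if pv_centres is None:
        pv_centres = default_pvs
    if laa_centre is None:
        laa_centre = default_laa
    if not isinstance(pv_radii, dict):
        pv_radii = {name: float(pv_radii) for name in PV_NAMES}
    template = DiskTemplate(
        grid_shape=grid_shape,
        pixel_size=float(pixel_size),
        disk_radius=disk_radius,
        pv_centres=dict(pv_centres),
        pv_radii=dict(pv_radii),
        laa_centre=tuple(laa_centre),
        laa_radius=float(laa_radius),
    )
    template.validate()
    return template
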