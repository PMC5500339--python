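"""Digital contrast-and-resolution phantom.

A water cylinder divided into three disks along z, one per contrast
material (iodine, calcium, barium).  Each disk carries: bar patterns at
eight discrete spatial frequencies (half-periods of 1..8 voxels, i.e.
0.71-5.68 lp/mm at the native 88 um voxel size), a grid of spheres
(diameter x concentration fraction) for detectability analysis, and
four calibration vials (iodine, calcium, barium at half the disk
maximum, plus water) that span all disks.

The phantom is voxelized by center-point sampling; band limiting is
supplied downstream by the chain PSF, not by antialiased rendering.
The same specification object also yields the measurement layout
(bar/gap masks, vial masks, sphere centers) used by the evaluation
module, so regions of interest are derived from geometry rather than
detected from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PhantomSpec", "FractionMaps", "PhantomLayout", "build_phantom"]


@dataclass
class PhantomSpec:
    """Geometry and contrast description of the phantom."""

    voxel_size: float = 0.088  # mm
    diameter: float = 34.0  # mm
    disk_materials: tuple = ("iodine", "calcium", "barium")
    max_concentration: dict = field(
        default_factory=lambda: {"iodine": 15.0, "calcium": 75.0, "barium": 15.0}
    )  # mg/ml
    disk_height: float = 9.0  # mm per disk
    # bar patterns: half-period in voxels; 1..8 => 5.68..0.71 lp/mm at 88 um
    linepair_half_periods: tuple = (8, 7, 6, 5, 4, 3, 2, 1)
    n_bars: int = 3  # material bars per group (gaps interleaved)
    bar_length_mm: float = 1.5
    sphere_diameters: tuple = (2.0, 1.5, 1.0, 0.5)  # mm
    sphere_fractions: tuple = (1.0, 0.66, 0.33, 0.20)
    vial_fraction: float = 0.5
    vial_diameter: float = 3.0  # mm
    include_linepairs: bool = True
    include_spheres: bool = True
    include_vials: bool = True

    @property
    def materials(self) -> tuple:
        return tuple(dict.fromkeys(self.disk_materials))

    @property
    def linepair_frequencies(self) -> tuple:
        """Spatial frequencies (lp/mm) of the bar groups."""
        return tuple(1.0 / (2.0 * k * self.voxel_size) for k in self.linepair_half_periods)

    def scaled(self, scale: float) -> "PhantomSpec":
        """Shrink the phantom extent while keeping voxel size and bar
        frequencies (which are voxel-defined) unchanged."""
        if not (0 < scale <= 1):
            raise ValueError("scale must be in (0, 1]")
        return PhantomSpec(
            voxel_size=self.voxel_size,
            diameter=self.diameter * scale,
            disk_materials=self.disk_materials,
            max_concentration=dict(self.max_concentration),
            disk_height=self.disk_height * scale,
            linepair_half_periods=self.linepair_half_periods,
            n_bars=self.n_bars,
            bar_length_mm=max(4 * self.voxel_size, self.bar_length_mm * scale),
            sphere_diameters=tuple(
                d for d in (d0 * scale for d0 in self.sphere_diameters)
                if d >= 4 * self.voxel_size
            )
            or (4 * self.voxel_size,),
            sphere_fractions=self.sphere_fractions,
            vial_fraction=self.vial_fraction,
            vial_diameter=max(4 * self.voxel_size, self.vial_diameter * scale),
            include_linepairs=self.include_linepairs,
            include_spheres=self.include_spheres,
            include_vials=self.include_vials,
        )


@dataclass
class FractionMaps:
    """Per-material fraction volumes frac(m, z, y, x) in [0, 1]."""

    fractions: np.ndarray  # (n_materials, nz, ny, nx)
    materials: tuple
    voxel_size: float
    max_concentration: dict

    @property
    def water_fraction(self) -> np.ndarray:
        """Background water as the complement of the contrast solutes.

        Contrast materials are dissolved/suspended in water, so water is
        displaced only marginally; the phantom treats the solvent as
        full water inside the cylinder (fractions describe solute
        concentration relative to the per-material maximum).
        """
        return self.support.astype(float)

    @property
    def support(self) -> np.ndarray:
        return self._support

    _support: np.ndarray = None

    def concentration(self, material: str) -> np.ndarray:
        """Concentration map in mg/ml."""
        idx = self.materials.index(material)
        return self.fractions[idx] * self.max_concentration[material]


@dataclass
class _BarGroup:
    disk: int
    half_period_vox: int
    frequency: float  # lp/mm
    bar_slices: list  # list of (z, y, x) index-slice triples, material bars
    gap_slices: list  # interleaved water gaps


@dataclass
class _Vial:
    material: str
    center_xy: tuple
    radius_mm: float
    fraction: float


@dataclass
class _Sphere:
    disk: int
    material: str
    center: tuple  # (z, y, x) voxel float coords
    diameter_mm: float
    fraction: float


@dataclass
class PhantomLayout:
    """Measurement geometry derived from a :class:`PhantomSpec`."""

    spec: PhantomSpec
    shape: tuple  # (nz, ny, nx)
    disk_z: list  # (z0, z1) per disk
    bar_groups: list = field(default_factory=list)
    vials: list = field(default_factory=list)
    spheres: list = field(default_factory=list)

    def vial_mask(self, vial: _Vial, margin_vox: float = 1.0) -> np.ndarray:
        """Boolean mask of one vial, eroded radially by ``margin_vox``."""
        nz, ny, nx = self.shape
        dv = self.spec.voxel_size
        yy, xx = _center_grid(ny, nx, dv)
        r = np.hypot(yy - vial.center_xy[1], xx - vial.center_xy[0])
        disk2d = r <= (vial.radius_mm - margin_vox * dv)
        mask = np.zeros(self.shape, dtype=bool)
        for z0, z1 in self.disk_z:
            zm = max(1, (z1 - z0) // 6)
            mask[z0 + zm : z1 - zm] |= disk2d[None, :, :]
        return mask

    def vial_mask_2d(self, vial: _Vial, margin_vox: float = 1.0) -> np.ndarray:
        """In-plane boolean mask of one vial (for single-slice fixtures)."""
        ny, nx = self.shape[1:]
        dv = self.spec.voxel_size
        yy, xx = _center_grid(ny, nx, dv)
        r = np.hypot(yy - vial.center_xy[1], xx - vial.center_xy[0])
        return r <= (vial.radius_mm - margin_vox * dv)

    def sphere_roi(self, sphere: _Sphere, side_vox: int) -> tuple:
        """Cubic ROI (slices) of side ``side_vox`` centered on a sphere."""
        out = []
        for c, n in zip(sphere.center, self.shape):
            lo = int(round(c)) - side_vox // 2
            lo = min(max(lo, 0), n - side_vox)
            out.append(slice(lo, lo + side_vox))
        return tuple(out)


def _center_grid(ny, nx, dv):
    y = (np.arange(ny) + 0.5 - ny / 2.0) * dv
    x = (np.arange(nx) + 0.5 - nx / 2.0) * dv
    return np.meshgrid(y, x, indexing="ij")


def _layout(spec: PhantomSpec) -> PhantomLayout:
    dv = spec.voxel_size
    n_xy = int(np.ceil(spec.diameter / dv)) + 8
    n_xy += n_xy % 2
    nz_disk = max(8, int(round(spec.disk_height / dv)))
    n_disks = len(spec.disk_materials)
    nz = nz_disk * n_disks
    layout = PhantomLayout(
        spec=spec,
        shape=(nz, n_xy, n_xy),
        disk_z=[(d * nz_disk, (d + 1) * nz_disk) for d in range(n_disks)],
    )
    radius = spec.diameter / 2.0

    # --- bar groups: packed into rows in the upper half of each disk,
    #     each row limited to the chord width of the cylinder there ---
    if spec.include_linepairs:
        if min(spec.linepair_half_periods) < 1:
            raise ValueError("finest bar half-period is below one voxel")
        bar_len = max(2, int(round(spec.bar_length_mm / dv)))
        y_limit = int(n_xy / 2 - max(1, 0.08 * radius / dv))

        def _chord_avail(y_idx: int) -> int:
            # widest |y| within the row band sits at its top edge
            y_mm = abs((y_idx + 0.5 - n_xy / 2.0) * dv)
            if y_mm >= radius:
                return 0
            return int(2 * 0.92 * np.sqrt(radius**2 - y_mm**2) / dv)

        rows: list[tuple[int, list[int]]] = []  # (y index, half-periods)
        y = int(n_xy / 2 - 0.92 * radius / dv)
        current: list[int] = []
        width = 0
        for k in sorted(spec.linepair_half_periods, reverse=True):
            gwidth = (2 * spec.n_bars - 1) * k + 4
            while True:
                avail = _chord_avail(y)
                if width + gwidth <= avail:
                    current.append(k)
                    width += gwidth
                    break
                if current:
                    rows.append((y, current))
                    y += bar_len + 3
                    current, width = [], 0
                else:
                    y += 1  # a single group is wider than this chord
                if y + bar_len > y_limit:
                    raise ValueError("phantom too small for the requested bar groups")
        if current:
            rows.append((y, current))
        if rows and rows[-1][0] + bar_len > y_limit:
            raise ValueError("phantom too small for the requested bar groups")
        for d in range(n_disks):
            z0, z1 = layout.disk_z[d]
            zc = (z0 + z1) // 2
            zs = slice(max(z0 + 1, zc - nz_disk // 3), min(z1 - 1, zc + nz_disk // 3))
            for y_row, row in rows:
                total_w = sum((2 * spec.n_bars - 1) * k + 4 for k in row)
                x = int(n_xy / 2 - total_w // 2)
                for k in row:
                    bars, gaps = [], []
                    for b in range(2 * spec.n_bars - 1):
                        xs = slice(x + b * k, x + (b + 1) * k)
                        tgt = bars if b % 2 == 0 else gaps
                        tgt.append((zs, slice(y_row, y_row + bar_len), xs))
                    layout.bar_groups.append(
                        _BarGroup(
                            disk=d,
                            half_period_vox=k,
                            frequency=1.0 / (2.0 * k * dv),
                            bar_slices=bars,
                            gap_slices=gaps,
                        )
                    )
                    x += (2 * spec.n_bars - 1) * k + 4

    # --- spheres: grid (diameter rows x fraction columns), central band ---
    if spec.include_spheres:
        n_f = len(spec.sphere_fractions)
        xs = np.linspace(-0.58, 0.58, n_f) * radius
        y0 = 0.08 * radius
        y = y0
        for d in range(n_disks):
            z0, z1 = layout.disk_z[d]
            zc = (z0 + z1) / 2.0
            y = y0
            for diam in spec.sphere_diameters:
                y += 0.55 * diam
                for fx, frac in zip(xs, spec.sphere_fractions):
                    cyv = y / dv + n_xy / 2.0 - 0.5
                    cxv = fx / dv + n_xy / 2.0 - 0.5
                    layout.spheres.append(
                        _Sphere(
                            disk=d,
                            material=spec.disk_materials[d],
                            center=(zc - 0.5, cyv, cxv),
                            diameter_mm=diam,
                            fraction=frac,
                        )
                    )
                y += 0.55 * diam + 2 * dv

    # --- vials: four cylinders in the lower band, spanning all disks ---
    if spec.include_vials:
        vial_r = spec.vial_diameter / 2.0
        vial_mats = list(dict.fromkeys(spec.disk_materials))[:3] + ["water"]
        xs = np.linspace(-0.51, 0.51, len(vial_mats)) * radius
        yv = 0.70 * radius
        for m, x in zip(vial_mats, xs):
            layout.vials.append(
                _Vial(
                    material=m,
                    center_xy=(float(x), float(yv)),
                    radius_mm=vial_r,
                    fraction=0.0 if m == "water" else spec.vial_fraction,
                )
            )
    return layout


def build_phantom(spec: PhantomSpec) -> tuple[FractionMaps, PhantomLayout]:
    """Voxelize the phantom by center-point sampling.

    Returns the per-material fraction maps together with the layout
    object describing where every measurement feature sits.
    """
    layout = _layout(spec)
    nz, ny, nx = layout.shape
    dv = spec.voxel_size
    mats = spec.materials
    frac = np.zeros((len(mats), nz, ny, nx))
    yy, xx = _center_grid(ny, nx, dv)
    rr = np.hypot(yy, xx)
    support2d = rr <= spec.diameter / 2.0
    midx = {m: i for i, m in enumerate(mats)}

    for d, mat in enumerate(spec.disk_materials):
        z0, z1 = layout.disk_z[d]
        i = midx[mat]
        for g in layout.bar_groups:
            if g.disk == d:
                for zs, ys, xs in g.bar_slices:
                    frac[i][zs, ys, xs] = 1.0
        zc = np.arange(nz)
        for s in layout.spheres:
            if s.disk != d:
                continue
            r_vox = s.diameter_mm / 2.0 / dv
            z_rel = (zc - s.center[0])[:, None, None]
            y_rel = (np.arange(ny) - s.center[1])[None, :, None]
            x_rel = (np.arange(nx) - s.center[2])[None, None, :]
            inside = z_rel**2 + y_rel**2 + x_rel**2 <= r_vox**2
            inside[:z0] = False
            inside[z1:] = False
            frac[i][inside] = np.maximum(frac[i][inside], s.fraction)

    for v in layout.vials:
        r2d = np.hypot(yy - v.center_xy[1], xx - v.center_xy[0])
        cyl = r2d <= v.radius_mm
        for i in range(len(mats)):
            frac[i][:, cyl] = 0.0
        if v.material != "water":
            frac[midx[v.material]][:, cyl] = v.fraction

    frac *= support2d[None, None, :, :]
    maps = FractionMaps(
        fractions=frac,
        materials=mats,
        voxel_size=dv,
        max_concentration=dict(spec.max_concentration),
    )
    maps._support = np.broadcast_to(support2d, (nz, ny, nx)).copy()
    return maps, layout
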