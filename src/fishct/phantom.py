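"""Ground-truthed synthetic fish volumes.

The phantom emulates the gross anatomy a microCT musculoskeletal analysis
cares about: a soft-tissue body (elliptical cross sections under a smooth
anteroposterior height profile), a vertebral column of separated mineralized
centra each carrying a neural (dorsal) and haemal (ventral) arch, two
air-filled swim-bladder chambers separated by a thin septum, and scattered
adipose pockets.  Every measured quantity downstream has an analytic ground
truth computed from the specification alone, so the whole pipeline is
testable without any external scan.

Geometry conventions (see :mod:`fishct.volume_io`): axis 0 is
anteroposterior with index 0 anterior, axis 1 is dorsoventral with index 0
dorsal, axis 2 is left-right.  All physical quantities are micrometres
unless noted; voxel centres sit at ``(i + 0.5) * voxel_size``.

Arch construction: each arch is a pair of straight bands ("legs") in the
transverse plane, rising from attachment points on the centrum surface at
polar angle ``arch_attach_angle`` to a midline apex, with apex angle
``neural_arch_angle_true`` between the legs and perpendicular band width
``arch_thickness``.  Bands are extruded over ``arch_ap_extent`` along AP.
Because the bands are axis-aligned integer-row constructs, their exact voxel
counts are computable by closed-form row arithmetic before any grid is
allocated, which is what the truth table uses.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .compartments import Compartment, Element, MEASURE_UNITS
from .errors import InvalidSpecError
from .volume_io import AttenuationVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "CohortSpec",
    "CohortFish",
    "generate_phantom",
    "generate_cohort",
    "analytic_truth",
    "apply_effects",
    "cohort_truth_table",
    "EFFECT_QUANTITIES",
]


def _ellipse_profile(t: float) -> float:
    u = 2.0 * t - 1.0
    return math.sqrt(max(0.0, 1.0 - u * u))


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of one synthetic fish.

    Defaults describe a small adult zebrafish-like body at the 21 um voxel
    size used for in vivo scanning: standard length 12.6 mm, maximal height
    2.55 mm (fineness ratio ~4.9), 24 vertebrae with 378 um centra at a
    462 um pitch, and vertebral tissue mineral density 900 mg HA/cm^3.
    Intensities are native attenuation units ordered
    air < adipose < soft tissue < bone.
    """

    # body
    standard_length: float = 12600.0
    max_height: float = 2550.0
    width_fraction: float = 0.62
    body_height_profile: Callable[[float], float] | None = None

    # vertebral column
    n_vertebrae: int = 24
    centrum_radius: float = 160.0
    centrum_length: float = 378.0
    intervertebral_gap: float = 84.0
    column_start_frac: float = 0.08
    column_dv_offset_frac: float = 0.18  # column sits dorsal of the midline

    # arches
    arch_thickness: float = 84.0
    neural_arch_angle_true: float = 30.0  # degrees, apex angle
    haemal_arch_angle_true: float = 30.0
    arch_attach_angle: float = 50.0  # degrees from the dorsal pole of the centrum
    arch_ap_extent: float = 168.0

    # mineral density and calibration (intensity = (TMD - intercept) / slope)
    bone_density: float | Sequence[float] = 900.0  # mg HA/cm^3
    tmd_slope: float = 1.0
    tmd_intercept: float = 0.0

    # intensities (native units)
    air_intensity: float = 0.0
    adipose_intensity: float = 60.0
    soft_tissue_intensity: float = 120.0

    # swim bladder
    sb_anterior_length: float = 2200.0
    sb_posterior_length: float = 2900.0
    sb_gap: float = 63.0
    sb_boundary_frac: float = 0.45  # AP position of the chamber gap centre, fraction of SL
    sb_radius: float = 340.0
    sb_dv_offset_frac: float = 0.19  # chambers sit ventral of the midline

    # adipose pockets
    adipose_pocket_fraction: float = 0.015
    pocket_radius_range: tuple[float, float] = (120.0, 280.0)

    # imaging
    voxel_size: float = 21.0
    noise_sd: float = 8.0
    pad_voxels: int = 3
    seed: int = 0

    def __post_init__(self):
        lengths = {
            "standard_length": self.standard_length,
            "max_height": self.max_height,
            "centrum_radius": self.centrum_radius,
            "centrum_length": self.centrum_length,
            "arch_thickness": self.arch_thickness,
            "arch_ap_extent": self.arch_ap_extent,
            "sb_anterior_length": self.sb_anterior_length,
            "sb_posterior_length": self.sb_posterior_length,
            "sb_radius": self.sb_radius,
            "voxel_size": self.voxel_size,
        }
        for name, value in lengths.items():
            if not value > 0:
                raise InvalidSpecError(f"{name} must be > 0, got {value}")
        if self.intervertebral_gap < 0 or self.sb_gap < 0:
            raise InvalidSpecError("gaps must be >= 0")
        if int(self.n_vertebrae) < 1:
            raise InvalidSpecError(f"n_vertebrae must be >= 1, got {self.n_vertebrae}")
        self.n_vertebrae = int(self.n_vertebrae)
        dens = np.atleast_1d(np.asarray(self.bone_density, dtype=float))
        if dens.size == 1:
            dens = np.full(self.n_vertebrae, dens[0])
        if dens.size != self.n_vertebrae:
            raise InvalidSpecError(
                f"bone_density must be scalar or length {self.n_vertebrae}, got {dens.size}"
            )
        self._density = dens
        if self.tmd_slope <= 0:
            raise InvalidSpecError("tmd_slope must be > 0")
        bone_int = self.bone_intensity(float(dens.min()))
        order = (self.air_intensity, self.adipose_intensity, self.soft_tissue_intensity, bone_int)
        if not (order[0] < order[1] < order[2] < order[3]):
            raise InvalidSpecError(
                f"intensities must satisfy air < adipose < soft < bone, got {order}"
            )
        if not 0 <= self.adipose_pocket_fraction < 1:
            raise InvalidSpecError("adipose_pocket_fraction must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        if self.column_length > self.standard_length:
            raise InvalidSpecError(
                f"vertebral column ({self.column_length} um) exceeds standard length"
            )
        if self.column_start_frac * self.standard_length + self.column_length > self.standard_length:
            raise InvalidSpecError("vertebral column does not fit behind the head")

    # -- derived geometry -------------------------------------------------
    def profile(self, t: float) -> float:
        fn = self.body_height_profile or _ellipse_profile
        return float(fn(t))

    def bone_intensity(self, density: float) -> float:
        """Inverse of the TMD calibration: attenuation producing ``density``."""
        return (density - self.tmd_intercept) / self.tmd_slope

    @property
    def density_per_vertebra(self) -> np.ndarray:
        return self._density

    @property
    def column_length(self) -> float:
        n = self.n_vertebrae
        return n * self.centrum_length + (n - 1) * self.intervertebral_gap

    @property
    def pad_um(self) -> float:
        return self.pad_voxels * self.voxel_size

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        vx = self.voxel_size
        nap = math.ceil((self.standard_length + 2 * self.pad_um) / vx)
        ndv = math.ceil((self.max_height + 2 * self.pad_um) / vx)
        nlr = math.ceil((self.width_fraction * self.max_height + 2 * self.pad_um) / vx)
        return nap, ndv, nlr

    @property
    def body_centre(self) -> tuple[float, float]:
        """(y0, z0): DV/LR coordinates of the body midline, um."""
        _, ndv, nlr = self.grid_shape
        return ndv * self.voxel_size / 2.0, nlr * self.voxel_size / 2.0

    @property
    def column_axis_dv(self) -> float:
        y0, _ = self.body_centre
        return y0 - self.column_dv_offset_frac * self.max_height

    def vertebra_ap_start(self, i: int) -> float:
        pitch = self.centrum_length + self.intervertebral_gap
        return self.pad_um + self.column_start_frac * self.standard_length + i * pitch

    @property
    def sb_boundary_x(self) -> float:
        return self.pad_um + self.sb_boundary_frac * self.standard_length

    def replace(self, **overrides) -> "PhantomSpec":
        return dataclasses.replace(self, **overrides)


# ---------------------------------------------------------------------------
# grid arithmetic helpers (shared by voxelizer and closed-form truth)
# ---------------------------------------------------------------------------

def _grid_range(lo: float, hi: float, step: float) -> range:
    """Indices i whose centre (i + 0.5) * step lies in the half-open [lo, hi)."""
    i0 = math.ceil(lo / step - 0.5)
    i1 = math.ceil(hi / step - 0.5)
    return range(max(i0, 0), max(i1, i0))


def _closed_count(lo: float, hi: float, step: float) -> tuple[int, int]:
    """First index and count of centres (k + 0.5) * step in the closed [lo, hi]."""
    k0 = math.ceil(lo / step - 0.5)
    k1 = math.floor(hi / step - 0.5)
    return k0, max(0, k1 - k0 + 1)


@dataclasses.dataclass(frozen=True)
class _ArchGeometry:
    """Transverse-plane geometry of one arch (neural or haemal)."""

    y_apex: float      # DV coordinate of the apex
    y_base: float      # DV coordinate of the attachment row
    sign: int          # -1 neural (dorsal), +1 haemal (ventral)
    slope: float       # |dz/dy| of the leg midline = tan(half apex angle)
    band_width: float  # z extent of a leg at fixed y (perpendicular width / cos)
    z_attach: float    # |z| of attachment point


def _arch_geometry(spec: PhantomSpec, side: str) -> _ArchGeometry:
    theta = math.radians(
        spec.neural_arch_angle_true if side == "neural" else spec.haemal_arch_angle_true
    )
    psi = math.radians(spec.arch_attach_angle)
    if not 0 < theta < math.pi:
        raise InvalidSpecError("arch apex angle must be in (0, 180) degrees")
    r = spec.centrum_radius
    z_b = r * math.sin(psi)
    y_off = r * math.cos(psi)
    half = theta / 2.0
    h_eff = z_b / math.tan(half)
    y_col = spec.column_axis_dv
    if side == "neural":
        y_base = y_col - y_off
        y_apex = y_base - h_eff
        sign = -1
    else:
        y_base = y_col + y_off
        y_apex = y_base + h_eff
        sign = +1
    return _ArchGeometry(
        y_apex=y_apex,
        y_base=y_base,
        sign=sign,
        slope=math.tan(half),
        band_width=spec.arch_thickness / math.cos(half),
        z_attach=z_b,
    )


def _arch_row_span(geom: _ArchGeometry, vx: float) -> range:
    """DV grid rows of the arch, half-open from apex toward base."""
    if geom.sign < 0:
        return _grid_range(geom.y_apex, geom.y_base, vx)
    return _grid_range(geom.y_base, geom.y_apex, vx)


def _arch_cells_in_row(geom: _ArchGeometry, y: float, z0: float, vx: float,
                       nlr: int) -> list[float]:
    """z-coordinates (grid centres) of arch cells in DV row at coordinate y.

    The two mirrored legs are unioned; cells are returned regardless of the
    centrum, which the caller subtracts.
    """
    u = abs(y - geom.y_apex)  # distance from apex along DV
    c = geom.slope * u        # |z| of the leg midline relative to the body axis
    w2 = geom.band_width / 2.0
    zs: set[int] = set()
    intervals = [(c - w2, c + w2)]
    if c - w2 < -(c) + w2:  # legs overlap across the midline near the apex
        intervals = [(-c - w2, c + w2)]
    else:
        intervals.append((-c - w2, -c + w2))
    for lo, hi in intervals:
        k0, cnt = _closed_count(z0 + lo, z0 + hi, vx)
        for k in range(k0, k0 + cnt):
            if 0 <= k < nlr:
                zs.add(k)
    return [(k + 0.5) * vx for k in sorted(zs)]


def _arch_truth_counts(spec: PhantomSpec, side: str) -> tuple[int, int]:
    """(voxel count, DV row count) of one arch, by closed-form row arithmetic.

    Cells falling inside the centrum disc are excluded (they belong to the
    centrum).  The count is per single vertebra; by construction it is the
    same for every vertebra because the in-plane geometry does not depend on
    the AP position and the AP extent covers an exact number of slices only
    when ``arch_ap_extent`` is a voxel multiple (the per-vertebra slice count
    is computed per vertebra by the caller).
    """
    geom = _arch_geometry(spec, side)
    vx = spec.voxel_size
    _, z0 = spec.body_centre
    y_col = spec.column_axis_dv
    r2 = spec.centrum_radius ** 2
    _, _, nlr = spec.grid_shape
    rows = _arch_row_span(geom, vx)
    n_cells = 0
    for j in rows:
        y = (j + 0.5) * vx
        for z in _arch_cells_in_row(geom, y, z0, vx, nlr):
            if (y - y_col) ** 2 + (z - z0) ** 2 <= r2:
                continue  # inside the centrum
            n_cells += 1
    return n_cells, len(rows)


def _arch_ap_slices(spec: PhantomSpec, i: int) -> range:
    xc = spec.vertebra_ap_start(i) + spec.centrum_length / 2.0
    return _grid_range(xc - spec.arch_ap_extent / 2.0, xc + spec.arch_ap_extent / 2.0,
                       spec.voxel_size)


# ---------------------------------------------------------------------------
# truth
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PhantomTruth:
    """Analytic ground truth for one phantom.

    Grid-derived fields (compartment counts, regional lean volumes, label
    grids) are ``None`` when the truth was computed without voxelization.
    """

    vertebrae: pd.DataFrame          # index 1..n, phenome measure columns
    standard_length: float           # um
    height: float                    # um
    fineness: float
    boundary_slice: int              # AP slice index of the chamber gap centre
    chamber_lengths: tuple[float, float]  # (anterior, posterior), um
    voxel_size: float
    units: dict = dataclasses.field(default_factory=lambda: dict(MEASURE_UNITS))

    compartment_counts: dict | None = None       # Compartment -> voxel count
    regional_lean_mm3: tuple | None = None       # (trunk, anterior, posterior)
    body_ap_slices: tuple | None = None          # (first, last) body slice index
    vertebra_labels: np.ndarray | None = None    # int16, 0 = not bone
    element_labels: np.ndarray | None = None     # uint8, Element codes


def analytic_truth(spec: PhantomSpec) -> PhantomTruth:
    """Ground truth computable from the spec alone (no voxel grid)."""
    vx = spec.voxel_size
    n = spec.n_vertebrae
    dens = spec.density_per_vertebra
    neur_cells, neur_rows = _arch_truth_counts(spec, "neural")
    haem_cells, haem_rows = _arch_truth_counts(spec, "haemal")
    vv = vx ** 3 * 1e-9  # mm^3 per voxel

    geom_neur = _arch_geometry(spec, "neural")
    neur_le = abs(geom_neur.y_base - geom_neur.y_apex)
    rows = []
    for i in range(n):
        n_arch_slices = len(_arch_ap_slices(spec, i))
        rows.append({
            "Cent.Vol": math.pi * spec.centrum_radius ** 2 * spec.centrum_length * 1e-9,
            "Cent.Th": 2 * spec.centrum_radius / 1000.0,
            "Cent.TMD": dens[i],
            "Neur.Vol": neur_cells * n_arch_slices * vv,
            "Neur.Th": spec.arch_thickness / 1000.0,
            "Neur.TMD": dens[i],
            "Haem.Vol": haem_cells * n_arch_slices * vv,
            "Haem.Th": spec.arch_thickness / 1000.0,
            "Haem.TMD": dens[i],
            "Cent.Le": spec.centrum_length / 1000.0,
            "Neur.Le": neur_le / 1000.0,
            "Neur.Angle": spec.neural_arch_angle_true,
        })
    table = pd.DataFrame(rows, index=pd.RangeIndex(1, n + 1, name="vertebra"))
    return PhantomTruth(
        vertebrae=table,
        standard_length=spec.standard_length,
        height=spec.max_height,
        fineness=spec.standard_length / spec.max_height,
        boundary_slice=int(spec.sb_boundary_x / vx),
        chamber_lengths=(spec.sb_anterior_length, spec.sb_posterior_length),
        voxel_size=vx,
    )


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------

def generate_phantom(
    spec: PhantomSpec,
) -> tuple[AttenuationVolume, np.ndarray, PhantomTruth]:
    """Voxelize a phantom.

    Returns the attenuation volume (int32 native units), the ground-truth
    compartment label grid (uint8, :class:`~fishct.compartments.Compartment`
    codes) and the filled :class:`PhantomTruth`.  Identical specs (including
    seed) produce bit-identical output.
    """
    vx = spec.voxel_size
    nap, ndv, nlr = spec.grid_shape
    y0, z0 = spec.body_centre
    y_col = spec.column_axis_dv
    rng = np.random.default_rng(spec.seed)

    ycoord = (np.arange(ndv) + 0.5) * vx
    zcoord = (np.arange(nlr) + 0.5) * vx
    yy = ycoord[:, None]
    zz = zcoord[None, :]

    labels = np.zeros((nap, ndv, nlr), dtype=np.uint8)  # BACKGROUND
    xcoord = (np.arange(nap) + 0.5) * vx

    # soft-tissue body
    t = (xcoord - spec.pad_um) / spec.standard_length
    for i in range(nap):
        if not 0.0 <= t[i] < 1.0:
            continue
        h = spec.max_height * spec.profile(t[i])
        w = spec.width_fraction * h
        if h <= 0 or w <= 0:
            continue
        m = ((yy - y0) / (h / 2)) ** 2 + ((zz - z0) / (w / 2)) ** 2 <= 1.0
        labels[i][m] = Compartment.LEAN

    # vertebral column
    disc = (yy - y_col) ** 2 + (zz - z0) ** 2 <= spec.centrum_radius ** 2
    arch2d = {}
    for side, code in (("neural", Element.NEURAL_ARCH), ("haemal", Element.HAEMAL_ARCH)):
        geom = _arch_geometry(spec, side)
        band = np.zeros((ndv, nlr), dtype=bool)
        for j in _arch_row_span(geom, vx):
            for z in _arch_cells_in_row(geom, (j + 0.5) * vx, z0, vx, nlr):
                band[j, int(z / vx - 0.5)] = True
        arch2d[code] = band & ~disc

    vert_labels = np.zeros((nap, ndv, nlr), dtype=np.int16)
    elem_labels = np.zeros((nap, ndv, nlr), dtype=np.uint8)
    for i in range(spec.n_vertebrae):
        x_lo = spec.vertebra_ap_start(i)
        cent_slices = _grid_range(x_lo, x_lo + spec.centrum_length, vx)
        a0, a1 = cent_slices.start, cent_slices.stop
        labels[a0:a1, disc] = Compartment.BONE
        vert_labels[a0:a1, disc] = i + 1
        elem_labels[a0:a1, disc] = Element.CENTRUM
        arch_slices = _arch_ap_slices(spec, i)
        b0, b1 = arch_slices.start, arch_slices.stop
        for code, band in arch2d.items():
            labels[b0:b1, band] = Compartment.BONE
            vert_labels[b0:b1, band] = i + 1
            elem_labels[b0:b1, band] = code

    # swim-bladder chambers (internal air; compartment class = presumptive adipose)
    air_mask = np.zeros_like(labels, dtype=bool)
    y_sb = y0 + spec.sb_dv_offset_frac * spec.max_height
    xb = spec.sb_boundary_x
    chambers = (
        (xb - spec.sb_gap / 2.0 - spec.sb_anterior_length, spec.sb_anterior_length),
        (xb + spec.sb_gap / 2.0, spec.sb_posterior_length),
    )
    for x_start, length in chambers:
        for i in _grid_range(x_start, x_start + length, vx):
            dx = (xcoord[i] - (x_start + length / 2.0)) / (length / 2.0)
            rad2 = spec.sb_radius ** 2 * (1.0 - dx * dx)
            if rad2 <= 0:
                continue
            m = (yy - y_sb) ** 2 + (zz - z0) ** 2 <= rad2
            if np.any(labels[i][m] != Compartment.LEAN):
                raise InvalidSpecError(
                    "swim-bladder chamber breaches the body or the skeleton; "
                    "adjust chamber size/position"
                )
            labels[i][m] = Compartment.ADIPOSE
            air_mask[i][m] = True

    # adipose pockets carved into remaining soft tissue
    if spec.adipose_pocket_fraction > 0:
        body_voxels = int(np.count_nonzero(labels))
        r_lo, r_hi = spec.pocket_radius_range
        mean_vol = 4.0 / 3.0 * math.pi * ((r_lo + r_hi) / 2.0) ** 3 / vx ** 3
        target = spec.adipose_pocket_fraction * body_voxels
        n_pockets = max(1, int(round(target / mean_vol)))
        placed = attempts = 0
        while placed < n_pockets and attempts < 50 * n_pockets:
            attempts += 1
            ci = rng.integers(0, nap)
            cj = rng.integers(0, ndv)
            ck = rng.integers(0, nlr)
            radius = rng.uniform(r_lo, r_hi)
            if labels[ci, cj, ck] != Compartment.LEAN:
                continue
            clearance = radius + 2 * vx  # pockets are internal: keep a soft shell
            ir = int(clearance / vx) + 1
            sl = (slice(max(ci - ir, 0), ci + ir + 1),
                  slice(max(cj - ir, 0), cj + ir + 1),
                  slice(max(ck - ir, 0), ck + ir + 1))
            xi = xcoord[sl[0]][:, None, None] - xcoord[ci]
            yi = ycoord[sl[1]][None, :, None] - ycoord[cj]
            zi = zcoord[sl[2]][None, None, :] - zcoord[ck]
            d2 = xi ** 2 + yi ** 2 + zi ** 2
            region = labels[sl]
            if np.any(region[d2 <= clearance ** 2] != Compartment.LEAN):
                continue
            region[d2 <= radius ** 2] = Compartment.ADIPOSE
            placed += 1

    # intensities
    img = np.full(labels.shape, spec.air_intensity, dtype=np.float64)
    img[labels == Compartment.LEAN] = spec.soft_tissue_intensity
    img[(labels == Compartment.ADIPOSE) & ~air_mask] = spec.adipose_intensity
    img[air_mask] = spec.air_intensity
    dens = spec.density_per_vertebra
    for i in range(spec.n_vertebrae):
        img[vert_labels == i + 1] = spec.bone_intensity(float(dens[i]))
    if spec.noise_sd > 0:
        # signed, unclipped: reconstructed attenuation noise is symmetric and
        # raw scanner exports are signed integers.  Clipping at zero would
        # bias the air class mean upward and destabilize the lower threshold.
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.rint(img).astype(np.int32)

    truth = analytic_truth(spec)
    counts = np.bincount(labels.ravel(), minlength=4)
    truth.compartment_counts = {Compartment(c): int(counts[c]) for c in range(4)}
    body = labels != Compartment.BACKGROUND
    body_slices = np.flatnonzero(body.any(axis=(1, 2)))
    truth.body_ap_slices = (int(body_slices[0]), int(body_slices[-1]))
    leanish = (labels == Compartment.LEAN) | (labels == Compartment.ADIPOSE)
    per_slice = leanish.sum(axis=(1, 2)).astype(float)
    vv = spec.voxel_size ** 3 * 1e-9
    b = truth.boundary_slice
    anterior = float(per_slice[body_slices[0]:b].sum()) * vv
    posterior = float(per_slice[b:body_slices[-1] + 1].sum()) * vv
    truth.regional_lean_mm3 = (anterior + posterior, anterior, posterior)
    truth.vertebra_labels = vert_labels
    truth.element_labels = elem_labels

    volume = AttenuationVolume(
        data=img,
        voxel_size=(vx, vx, vx),
        provenance={"source": "fishct.phantom", "seed": spec.seed},
    )
    return volume, labels, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def _scale_all_lengths(spec_kwargs: dict, f: float) -> None:
    for name in (
        "standard_length", "max_height", "centrum_radius", "centrum_length",
        "intervertebral_gap", "arch_thickness", "arch_ap_extent",
        "sb_anterior_length", "sb_posterior_length", "sb_gap", "sb_radius",
    ):
        spec_kwargs[name] = spec_kwargs[name] * f
    lo, hi = spec_kwargs["pocket_radius_range"]
    spec_kwargs["pocket_radius_range"] = (lo * f, hi * f)


def _soft_body_volume(spec: PhantomSpec) -> float:
    """Analytic body volume (um^3) under the height profile."""
    ts = np.linspace(0.0, 1.0, 513)
    prof2 = np.array([spec.profile(t) ** 2 for t in ts])
    integral = float(np.trapezoid(prof2, ts))
    return (math.pi / 4.0) * spec.width_fraction * spec.max_height ** 2 \
        * spec.standard_length * integral


def _inclusion_volume(spec: PhantomSpec) -> float:
    """Analytic volume (um^3) of bone plus swim-bladder air inside the body."""
    bone = spec.n_vertebrae * math.pi * spec.centrum_radius ** 2 * spec.centrum_length
    chambers = sum(
        4.0 / 3.0 * math.pi * (length / 2.0) * spec.sb_radius ** 2
        for length in (spec.sb_anterior_length, spec.sb_posterior_length)
    )
    return bone + chambers


def _apply_lean_volume(spec_kwargs: dict, base: PhantomSpec, f: float) -> None:
    # scale the body width so that (body - inclusions) scales by f; width
    # rather than height, because the dorsoventral positions of the column,
    # arches and swim bladder must keep their clearances
    vb = _soft_body_volume(base)
    vi = _inclusion_volume(base)
    scale = (f * (vb - vi) + vi) / vb
    if scale <= 0:
        raise InvalidSpecError(f"lean_volume effect {f} leaves no soft tissue")
    spec_kwargs["width_fraction"] = base.width_fraction * scale


EFFECT_QUANTITIES = ("standard_length", "centrum_length", "tmd", "lean_volume")


def apply_effects(spec: PhantomSpec, effects: Mapping[str, float]) -> PhantomSpec:
    """Return a spec with multiplicative effects applied to named quantities.

    ``standard_length`` is an isotropic body-size effect (all lengths scale);
    ``centrum_length`` and ``tmd`` are local effects; ``lean_volume`` adjusts
    the body cross section so soft-tissue volume scales by the given factor.
    Unknown quantity names raise ``KeyError``.
    """
    unknown = set(effects) - set(EFFECT_QUANTITIES)
    if unknown:
        raise KeyError(f"unknown effect quantities: {sorted(unknown)}")
    kwargs = dataclasses.asdict(spec)
    kwargs["bone_density"] = np.array(spec.density_per_vertebra)
    kwargs.pop("body_height_profile", None)
    if "standard_length" in effects:
        _scale_all_lengths(kwargs, float(effects["standard_length"]))
    if "centrum_length" in effects:
        kwargs["centrum_length"] = kwargs["centrum_length"] * float(effects["centrum_length"])
    if "tmd" in effects:
        kwargs["bone_density"] = kwargs["bone_density"] * float(effects["tmd"])
    base_for_lean = PhantomSpec(**{**kwargs, "body_height_profile": spec.body_height_profile})
    if "lean_volume" in effects:
        _apply_lean_volume(kwargs, base_for_lean, float(effects["lean_volume"]))
    return PhantomSpec(**{**kwargs, "body_height_profile": spec.body_height_profile})


@dataclasses.dataclass
class CohortSpec:
    """A control spec plus per-group multiplicative effects.

    ``groups`` maps group name to an effects mapping (empty for controls).
    Between-fish variation multiplies each varied quantity by a mean-one
    lognormal factor with log-scale ``scale_sd``.
    """

    control: PhantomSpec
    groups: Mapping[str, Mapping[str, float]]
    n_per_group: int | Mapping[str, int] = 8
    scale_sd: float = 0.05
    vary: tuple[str, ...] = EFFECT_QUANTITIES
    seed: int = 0

    def __post_init__(self):
        if self.scale_sd < 0:
            raise InvalidSpecError("scale_sd must be >= 0")
        for g, eff in self.groups.items():
            unknown = set(eff) - set(EFFECT_QUANTITIES)
            if unknown:
                raise KeyError(f"group {g!r}: unknown effect quantities {sorted(unknown)}")
        for g in self.groups:
            if self.group_n(g) < 1:
                raise InvalidSpecError(f"group {g!r} must have n >= 1")
        bad = set(self.vary) - set(EFFECT_QUANTITIES)
        if bad:
            raise KeyError(f"unknown varied quantities: {sorted(bad)}")

    def group_n(self, group: str) -> int:
        if isinstance(self.n_per_group, Mapping):
            return int(self.n_per_group[group])
        return int(self.n_per_group)


@dataclasses.dataclass
class CohortFish:
    fish_id: str
    group: str
    spec: PhantomSpec
    truth: PhantomTruth
    volume: AttenuationVolume | None = None
    labels: np.ndarray | None = None


def generate_cohort(cspec: CohortSpec, voxelize: bool = True) -> list[CohortFish]:
    """Generate a cohort of phantoms with group effects and per-fish variation.

    Per-fish randomness (variation factors and voxel noise) derives
    deterministically from the master seed.  With ``voxelize=False`` only the
    analytic truth is computed (fast path for statistical simulations).
    """
    master = np.random.SeedSequence(cspec.seed)
    fishes: list[CohortFish] = []
    group_names = list(cspec.groups)
    children = master.spawn(sum(cspec.group_n(g) for g in group_names))
    idx = 0
    for group in group_names:
        effects = dict(cspec.groups[group])
        for j in range(cspec.group_n(group)):
            child = children[idx]
            idx += 1
            rng = np.random.default_rng(child)
            factors = {}
            for q in cspec.vary:
                base = float(effects.get(q, 1.0))
                if cspec.scale_sd > 0:
                    base *= math.exp(rng.normal(-cspec.scale_sd ** 2 / 2.0, cspec.scale_sd))
                factors[q] = base
            for q, f in effects.items():
                factors.setdefault(q, float(f))
            fish_seed = int(child.generate_state(1)[0] % (2 ** 31))
            spec_f = apply_effects(cspec.control, factors).replace(seed=fish_seed)
            if voxelize:
                volume, labels, truth = generate_phantom(spec_f)
            else:
                volume, labels, truth = None, None, analytic_truth(spec_f)
            fishes.append(CohortFish(
                fish_id=f"{group}_{j:02d}", group=group, spec=spec_f,
                truth=truth, volume=volume, labels=labels,
            ))
    return fishes


def cohort_truth_table(cspec: CohortSpec) -> pd.DataFrame:
    """Long-format truth table for a cohort, without voxelization.

    Columns: ``fish``, ``group``, ``standard_length`` (um), ``vertebra`` and
    the twelve phenome measures.
    """
    frames = []
    for fish in generate_cohort(cspec, voxelize=False):
        tab = fish.truth.vertebrae.reset_index()
        tab.insert(0, "fish", fish.fish_id)
        tab.insert(1, "group", fish.group)
        tab.insert(2, "standard_length", fish.truth.standard_length)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
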