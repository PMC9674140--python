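"""Soft-tissue morphometrics from a tissue segmentation.

Derives the whole-body measures used for lean-mass phenotyping: per-slice
cross-sectional area (CSA) profiles along the anteroposterior axis, the
anterior/posterior swim-bladder boundary and the regional lean volumes it
separates, swim-bladder chamber lengths, standard length, dorsoventral
height and the fineness ratio (standard length / height, a body-shape
correlate of swimming performance).

Presumptive adipose is folded into lean throughout, since the intensity
criterion cannot reliably separate adipose from lean tissue; the "lean"
profile is therefore the whole soft-tissue cross section.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .compartments import Compartment
from .errors import BoundaryUndetectableError, EmptyBodyError, FishCTError
from .segmentation import TissueSegmentation

__all__ = [
    "LeanProfile",
    "BodyMeasures",
    "csa_profile",
    "lean_profile",
    "detect_swimbladder_boundary",
    "regional_lean_volumes",
    "chamber_lengths",
    "body_size",
    "body_measures",
]

_COMPARTMENT_SETS = {
    "lean": (Compartment.LEAN, Compartment.ADIPOSE),  # adipose folds into lean
    "bone": (Compartment.BONE,),
    "adipose": (Compartment.ADIPOSE,),
}


@dataclasses.dataclass
class LeanProfile:
    """Per-AP-slice cross-sectional areas (mm^2)."""

    positions_um: np.ndarray      # slice-centre AP positions
    lean_mm2: np.ndarray
    bone_mm2: np.ndarray
    adipose_mm2: np.ndarray
    slice_thickness_um: float
    boundary_slice: int | None = None
    boundary_mode: str = "none"   # {"none", "auto", "override"}

    def __len__(self):
        return self.lean_mm2.size


@dataclasses.dataclass
class BodyMeasures:
    """Whole-body soft-tissue measures of one fish."""

    standard_length_um: float
    dorsoventral_height_um: float
    fineness_ratio: float
    trunk_lean_mm3: float | None = None
    anterior_trunk_lean_mm3: float | None = None
    posterior_trunk_lean_mm3: float | None = None
    anterior_chamber_um: float | None = None
    posterior_chamber_um: float | None = None
    boundary_slice: int | None = None

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def csa_profile(seg: TissueSegmentation, compartment: str = "lean") -> np.ndarray:
    """Cross-sectional area (mm^2) of a compartment per AP slice.

    ``compartment`` is one of ``lean`` (which includes presumptive adipose),
    ``bone`` or ``adipose``.
    """
    try:
        members = _COMPARTMENT_SETS[compartment]
    except KeyError:
        raise KeyError(
            f"unknown compartment {compartment!r}; expected one of {sorted(_COMPARTMENT_SETS)}"
        ) from None
    area_mm2 = seg.voxel_size[1] * seg.voxel_size[2] * 1e-6
    counts = np.zeros(seg.labels.shape[0], dtype=np.int64)
    for m in members:
        counts += (seg.labels == m).sum(axis=(1, 2))
    return counts * area_mm2


def _air_cavities(
    seg: TissueSegmentation,
    volume_data: np.ndarray,
    air_threshold: float | None = None,
    min_voxels: int = 50,
) -> list[dict]:
    """Internal air cavities: in-mask voxels well below the adipose class.

    The default criterion is intensity below half the lower threshold, which
    sits under the adipose class for any ordered intensity model.  Returns
    cavities sorted anterior to posterior.
    """
    if air_threshold is None:
        air_threshold = 0.5 * seg.thresholds.lower
    air = seg.body_mask & (volume_data < air_threshold)
    lab, n = ndimage.label(air, structure=np.ones((3, 3, 3), dtype=bool))
    cavities = []
    for obj_idx, sl in enumerate(ndimage.find_objects(lab)):
        if sl is None:
            continue
        comp = lab[sl] == obj_idx + 1
        size = int(comp.sum())
        if size < min_voxels:
            continue
        ap0, ap1 = sl[0].start, sl[0].stop - 1
        centroid_ap = float(np.argwhere(comp)[:, 0].mean() + ap0)
        cavities.append({
            "ap_min": ap0, "ap_max": ap1, "voxels": size, "centroid_ap": centroid_ap,
        })
    cavities.sort(key=lambda c: c["centroid_ap"])
    return cavities


def _two_chambers(seg, volume_data, **kw) -> tuple[dict, dict]:
    cavities = _air_cavities(seg, volume_data, **kw)
    if len(cavities) < 2:
        raise BoundaryUndetectableError(
            f"found {len(cavities)} internal air cavities; need the two "
            "swim-bladder chambers (an explicit boundary index can be supplied)"
        )
    largest = sorted(cavities, key=lambda c: c["voxels"], reverse=True)[:2]
    ant, post = sorted(largest, key=lambda c: c["centroid_ap"])
    return ant, post


def detect_swimbladder_boundary(
    seg: TissueSegmentation,
    volume_data: np.ndarray,
    override: int | None = None,
    air_threshold: float | None = None,
    min_voxels: int = 50,
) -> int:
    """AP slice index of the anterior/posterior swim-bladder boundary.

    The boundary is the slice of maximal lean CSA in the gap between the two
    largest internal air cavities — the "local spike" between the chambers.
    An explicit ``override`` index is returned unchanged (after range
    checking).
    """
    n = seg.labels.shape[0]
    if override is not None:
        override = int(override)
        if not 0 <= override < n:
            raise IndexError(f"boundary override {override} outside stack of {n}")
        return override
    ant, post = _two_chambers(seg, volume_data, air_threshold=air_threshold,
                              min_voxels=min_voxels)
    g0, g1 = ant["ap_max"] + 1, post["ap_min"]  # gap slices [g0, g1)
    if g1 <= g0:  # chambers overlap in AP: take the midpoint between centroids
        return int(round((ant["centroid_ap"] + post["centroid_ap"]) / 2.0))
    lean = csa_profile(seg, "lean")
    return g0 + int(np.argmax(lean[g0:g1]))


def lean_profile(
    seg: TissueSegmentation,
    volume_data: np.ndarray | None = None,
    boundary: int | None = None,
) -> LeanProfile:
    """Full AP profile (lean/bone/adipose CSA) with the detected boundary.

    ``boundary`` overrides detection; detection requires ``volume_data`` (the
    raw intensities, used to find the air cavities).
    """
    vx = seg.voxel_size[0]
    n = seg.labels.shape[0]
    mode = "none"
    b = None
    if boundary is not None:
        b = detect_swimbladder_boundary(seg, volume_data, override=boundary)
        mode = "override"
    elif volume_data is not None:
        b = detect_swimbladder_boundary(seg, volume_data)
        mode = "auto"
    return LeanProfile(
        positions_um=(np.arange(n) + 0.5) * vx,
        lean_mm2=csa_profile(seg, "lean"),
        bone_mm2=csa_profile(seg, "bone"),
        adipose_mm2=csa_profile(seg, "adipose"),
        slice_thickness_um=vx,
        boundary_slice=b,
        boundary_mode=mode,
    )


def regional_lean_volumes(
    profile: LeanProfile,
    boundary: int | None = None,
    trunk_range: tuple[int, int] | None = None,
) -> tuple[float, float, float]:
    """(trunk, anterior-trunk, posterior-trunk) lean volumes in mm^3.

    Anterior integrates lean CSA over ``[trunk start, boundary)``, posterior
    over ``[boundary, trunk end]``; the trunk is their sum.  The default
    trunk range is the full extent of nonzero lean CSA (the protocol's trunk
    anterior cut is a configuration landmark, not a detected one).
    """
    if boundary is None:
        boundary = profile.boundary_slice
    if boundary is None:
        raise FishCTError("no boundary available: detect one or pass it explicitly")
    lean = profile.lean_mm2
    if trunk_range is None:
        nz = np.flatnonzero(lean > 0)
        if nz.size == 0:
            raise EmptyBodyError("profile has no lean tissue")
        trunk_range = (int(nz[0]), int(nz[-1]))
    t0, t1 = trunk_range
    if not t0 <= boundary <= t1:
        raise FishCTError(
            f"boundary slice {boundary} outside trunk range [{t0}, {t1}]"
        )
    dz_mm = profile.slice_thickness_um / 1000.0
    anterior = float(lean[t0:boundary].sum()) * dz_mm
    posterior = float(lean[boundary:t1 + 1].sum()) * dz_mm
    return anterior + posterior, anterior, posterior


def chamber_lengths(
    seg: TissueSegmentation,
    volume_data: np.ndarray,
    air_threshold: float | None = None,
    min_voxels: int = 50,
) -> tuple[float, float]:
    """(anterior, posterior) swim-bladder chamber AP lengths in um."""
    ant, post = _two_chambers(seg, volume_data, air_threshold=air_threshold,
                              min_voxels=min_voxels)
    vx = seg.voxel_size[0]
    return (
        (ant["ap_max"] - ant["ap_min"] + 1) * vx,
        (post["ap_max"] - post["ap_min"] + 1) * vx,
    )


def body_size(seg: TissueSegmentation) -> BodyMeasures:
    """Standard length, dorsoventral height and fineness ratio.

    Standard length is approximated by the AP extent of the body mask (soft
    fin rays barely attenuate, so the mask typically ends at the caudal
    peduncle); height is the maximal per-slice DV extent of the mask.
    """
    mask = seg.body_mask
    ap_any = mask.any(axis=(1, 2))
    if not ap_any.any():
        raise EmptyBodyError("body mask is empty")
    ap_idx = np.flatnonzero(ap_any)
    sl_um = (ap_idx[-1] - ap_idx[0] + 1) * seg.voxel_size[0]
    dv_any = mask.any(axis=2)  # (AP, DV)
    heights = np.zeros(mask.shape[0], dtype=np.int64)
    for i in np.flatnonzero(dv_any.any(axis=1)):
        rows = np.flatnonzero(dv_any[i])
        heights[i] = rows[-1] - rows[0] + 1
    height_um = float(heights.max()) * seg.voxel_size[1]
    return BodyMeasures(
        standard_length_um=float(sl_um),
        dorsoventral_height_um=height_um,
        fineness_ratio=float(sl_um) / height_um,
    )


def body_measures(
    seg: TissueSegmentation,
    volume_data: np.ndarray,
    boundary: int | None = None,
    trunk_range: tuple[int, int] | None = None,
) -> BodyMeasures:
    """All soft-tissue measures of one fish in one record."""
    measures = body_size(seg)
    profile = lean_profile(seg, volume_data, boundary=boundary)
    trunk, anterior, posterior = regional_lean_volumes(profile, trunk_range=trunk_range)
    ant_len, post_len = chamber_lengths(seg, volume_data)
    measures.trunk_lean_mm3 = trunk
    measures.anterior_trunk_lean_mm3 = anterior
    measures.posterior_trunk_lean_mm3 = posterior
    measures.anterior_chamber_um = ant_len
    measures.posterior_chamber_um = post_len
    measures.boundary_slice = profile.boundary_slice
    return measures
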