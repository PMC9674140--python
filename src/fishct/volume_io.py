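"""Volume and table I/O.

The in-memory representation of a scan is :class:`AttenuationVolume`: a 3-D
grid of raw attenuation values plus its voxel size in micrometres.  The axis
convention is fixed throughout the package:

* axis 0 — anteroposterior (AP), index 0 = anterior (snout)
* axis 1 — dorsoventral (DV), index 0 = dorsal
* axis 2 — left-right (LR)

Readers permute data into this frame according to a user-declared orientation
mapping (the orientation of third-party scans is not assumed).  Intensities
are kept in native units; no rescaling to Hounsfield units is performed,
because all downstream thresholds are computed on the raw histogram.

Supported formats: NIfTI (voxel size in the header zooms, stored in mm),
multi-page TIFF (voxel size in a JSON sidecar), and DICOM series if the
optional ``pydicom`` dependency is installed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, MetadataError

__all__ = [
    "AttenuationVolume",
    "MeasureTable",
    "read_volume",
    "write_volume",
    "write_results",
    "read_measure_table",
    "check_slice_spacing",
]

AXES = ("AP", "DV", "LR")


@dataclasses.dataclass
class AttenuationVolume:
    """A 3-D attenuation grid with voxel-size metadata.

    Parameters
    ----------
    data:
        3-D array ordered (AP, DV, LR).
    voxel_size:
        Voxel edge length per axis in micrometres.
    axes:
        Axis-convention tag; always ``("AP", "DV", "LR")`` after reading.
    provenance:
        Free-form origin record (source path, format, ...).
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    axes: tuple[str, str, str] = AXES
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise FormatError("volume must be a non-empty 3-D array")
        if np.isscalar(self.voxel_size):
            self.voxel_size = (float(self.voxel_size),) * 3
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise MetadataError(f"voxel size must be three positive values, got {self.voxel_size}")
        if tuple(self.axes) != AXES:
            raise MetadataError(f"axis tag must be {AXES}; permute on read")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size)) * 1e-9

    @property
    def slice_thickness_um(self) -> float:
        """AP extent of one slice (axis-0 voxel size), micrometres."""
        return self.voxel_size[0]


@dataclasses.dataclass
class MeasureTable:
    """Per-fish measurements with units and group labels.

    ``data`` is indexed by unique fish identifiers; ``units`` records the unit
    of every measurement column.  The group label lives in ``data[group_col]``
    and standard length (um) in ``data[sl_col]`` when present.
    """

    data: pd.DataFrame
    units: dict[str, str]
    group_col: str = "group"
    sl_col: str = "standard_length"

    def __post_init__(self):
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicated fish identifiers: {dupes}")
        for col in self.data.columns:
            if col == self.group_col:
                continue
            if col not in self.units:
                raise ValueError(f"no unit recorded for column {col!r}")

    @property
    def measure_columns(self) -> list[str]:
        return [c for c in self.data.columns if c != self.group_col]


def _orientation_to_transform(orientation: Sequence[str]) -> tuple[list[int], list[int]]:
    """Parse a declared source-axis orientation like ``("DV", "-AP", "LR")``.

    Returns (permutation, flip axes) mapping source order to (AP, DV, LR).
    """
    labels = [str(o).strip() for o in orientation]
    if len(labels) != 3:
        raise MetadataError(f"orientation must name three axes, got {orientation!r}")
    flips: list[int] = []
    names = []
    for i, lab in enumerate(labels):
        if lab.startswith("-"):
            flips.append(i)
            lab = lab[1:]
        names.append(lab.upper())
    if sorted(names) != sorted(AXES):
        raise MetadataError(f"orientation must be a permutation of {AXES}, got {orientation!r}")
    perm = [names.index(ax) for ax in AXES]
    return perm, flips


def _apply_orientation(data: np.ndarray, voxel_size, orientation) -> tuple[np.ndarray, tuple]:
    if orientation is None:
        return data, tuple(voxel_size)
    perm, flips = _orientation_to_transform(orientation)
    for ax in flips:
        data = np.flip(data, axis=ax)
    data = np.transpose(data, perm)
    vs = tuple(voxel_size[p] for p in perm)
    return data, vs


def check_slice_spacing(positions: Sequence[float], rtol: float = 0.01) -> float:
    """Validate uniform slice spacing of a stack; return the spacing.

    Raises :class:`FormatError` on gaps or irregular spacing (e.g. a missing
    slice in a DICOM series).
    """
    pos = np.sort(np.asarray(positions, dtype=float))
    if pos.size < 2:
        raise FormatError("need at least two slices to establish spacing")
    steps = np.diff(pos)
    spacing = float(np.median(steps))
    if spacing <= 0:
        raise FormatError("duplicate slice positions in series")
    if np.any(np.abs(steps - spacing) > rtol * spacing):
        raise FormatError(
            f"inconsistent slice spacing (median {spacing:g}, range "
            f"{steps.min():g}..{steps.max():g}); a slice may be missing"
        )
    return spacing


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_volume(volume: AttenuationVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI (.nii/.nii.gz) or multi-page TIFF (.tif/.tiff).

    NIfTI stores the voxel size in the header zooms (converted to mm); TIFF
    gets a JSON sidecar ``<name>.json`` holding voxel size and axis order.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.diag([v / 1000.0 for v in volume.voxel_size] + [1.0])
        img = nib.Nifti1Image(np.asarray(volume.data), affine)
        img.header.set_zooms([v / 1000.0 for v in volume.voxel_size])
        img.header["descrip"] = b"fishct axes=AP,DV,LR"
        nib.save(img, str(path))
    elif suffixes.endswith((".tif", ".tiff")):
        import tifffile

        tifffile.imwrite(str(path), np.asarray(volume.data))
        meta = {"voxel_size_um": list(volume.voxel_size), "axes": list(volume.axes)}
        _sidecar_path(path).write_text(json.dumps(meta))
    else:
        raise FormatError(f"unsupported volume format for {path.name!r}")
    return path


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple]:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    if any(z <= 0 for z in zooms):
        raise MetadataError(f"non-positive voxel size in NIfTI header of {path}")
    return data, tuple(z * 1000.0 for z in zooms)  # mm -> um


def _read_tiff(path: Path) -> tuple[np.ndarray, tuple | None]:
    import tifffile

    data = tifffile.imread(str(path))
    if data.ndim != 3:
        raise FormatError(f"expected a multi-page TIFF stack, got ndim={data.ndim}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        return data, tuple(float(v) for v in meta["voxel_size_um"])
    return data, None


def _read_dicom_series(path: Path) -> tuple[np.ndarray, tuple]:
    try:
        import pydicom
    except ImportError as exc:  # pragma: no cover - optional backend
        raise MetadataError(
            "reading DICOM series requires the optional 'pydicom' dependency; "
            "install pydicom or convert the series to NIfTI/TIFF"
        ) from exc
    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in (".dcm", ".ima", ""))
    if not files:
        raise FormatError(f"no DICOM files found under {path}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    positions = [float(getattr(s, "ImagePositionPatient", [0, 0, i])[2]) for i, s in enumerate(slices)]
    order = np.argsort(positions)
    spacing = check_slice_spacing(positions)  # mm
    first = slices[order[0]]
    try:
        row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    except AttributeError as exc:
        raise MetadataError("DICOM series lacks PixelSpacing") from exc
    data = np.stack([slices[i].pixel_array for i in order], axis=0)
    return data, (spacing * 1000.0, row_sp * 1000.0, col_sp * 1000.0)


def read_volume(
    path: str | Path,
    format: str | None = None,
    voxel_size: float | Sequence[float] | None = None,
    orientation: Sequence[str] | None = None,
) -> AttenuationVolume:
    """Read a scan volume into the (AP, DV, LR) frame.

    Parameters
    ----------
    path:
        File (NIfTI, TIFF) or directory (DICOM series).
    format:
        One of ``{"nifti", "tiff", "dicom-series"}``; inferred from the path
        when omitted.
    voxel_size:
        Override in micrometres (scalar or per-axis).  Required for formats
        that carry no voxel-size metadata (e.g. TIFF without sidecar).
    orientation:
        Axis labels of the *file's* axes in storage order, e.g.
        ``("DV", "-AP", "LR")``.  Data are flipped/permuted into (AP, DV, LR).
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            format = "nifti"
        elif name.endswith((".tif", ".tiff")):
            format = "tiff"
        elif path.is_dir():
            format = "dicom-series"
        else:
            raise FormatError(f"cannot infer format of {path.name!r}")

    if format == "nifti":
        data, vs = _read_nifti(path)
    elif format == "tiff":
        data, vs = _read_tiff(path)
    elif format == "dicom-series":
        data, vs = _read_dicom_series(path)
    else:
        raise FormatError(f"unknown volume format {format!r}")

    if voxel_size is not None:
        vs = (voxel_size,) * 3 if np.isscalar(voxel_size) else tuple(voxel_size)
    if vs is None:
        raise MetadataError(
            f"{path.name}: no voxel-size metadata found and no override given"
        )
    data, vs = _apply_orientation(data, vs, orientation)
    return AttenuationVolume(
        data=data,
        voxel_size=vs,
        provenance={"source": str(path), "format": format},
    )


# ---------------------------------------------------------------------------
# tabular output
# ---------------------------------------------------------------------------

def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def write_results(
    tables: Mapping[str, pd.DataFrame | MeasureTable],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write result tables as CSV (header + units row) plus a JSON summary.

    The summary records the exact configuration, its hash, the seed and the
    software version so a run can be reproduced from its outputs.
    """
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, table in tables.items():
        if isinstance(table, MeasureTable):
            df, units = table.data, table.units
        else:
            df, units = table, {}
        path = out_dir / f"{name}.csv"
        units_row = pd.DataFrame(
            [[units.get(str(c), "") for c in df.columns]], columns=df.columns, index=["#units"]
        )
        pd.concat([units_row, df]).to_csv(path, index_label="id")
        written[name] = path
    config = dict(config or {})
    summary = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "tables": sorted(tables),
    }
    spath = out_dir / "summary.json"
    spath.write_text(json.dumps(summary, indent=2, default=str))
    written["summary"] = spath
    return written


def read_measure_table(path: str | Path, group_col: str = "group") -> MeasureTable:
    """Read a CSV written by :func:`write_results` back into a MeasureTable."""
    raw = pd.read_csv(path, index_col=0)
    if len(raw) and raw.index[0] == "#units":
        units_row = raw.iloc[0]
        df = raw.iloc[1:].copy()
        units = {c: str(units_row[c]) for c in df.columns if str(units_row[c]) not in ("", "nan")}
    else:
        df, units = raw, {}
    for c in df.columns:
        if c != group_col:
            try:
                df[c] = pd.to_numeric(df[c])
            except (ValueError, TypeError):
                pass
            units.setdefault(c, "")
    return MeasureTable(data=df, units=units, group_col=group_col)
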