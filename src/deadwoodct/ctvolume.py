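"""CT volume data model, I/O and shared preprocessing.

A CT scan of a log is a 3-D grid of attenuation values in Hounsfield Units
(HU): the scale is anchored at water = 0 HU and air = -1000 HU and is linear
in attenuation relative to water. Axis 0 of every array is the longitudinal
stem axis (slice index z), axes 1 and 2 are the in-plane row/column.

Two preprocessing steps are shared by the tunnel and the decay pipelines:

* removal of the scanner bed (patient table), a horizontal high-opacity band
  below the log that is constant across slices, replaced by surrounding air;
* offset correction and normalization by a factor of 2500 HU, mapping air to
  0 and 1500 HU (250% of water attenuation) to 1.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

AIR_HU = -1000.0
WATER_HU = 0.0


class FormatError(ValueError):
    """Input file(s) violate the expected on-disk layout or geometry."""


class ParameterError(ValueError):
    """A numeric parameter is outside its valid domain."""


@dataclass
class CTVolume:
    """A 3-D CT volume in Hounsfield Units.

    Parameters
    ----------
    voxels
        3-D array indexed (slice z, row y, col x), values in HU.
    pixel_spacing
        In-plane (y, x) voxel size in mm.
    slice_thickness
        Longitudinal voxel size in mm.
    meta
        Free-form string metadata (scanner, kVp, batch id, ...).
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    meta: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D (z, y, x) array")
        py, px = self.pixel_spacing
        if py <= 0 or px <= 0 or self.slice_thickness <= 0:
            raise ValueError("voxel spacing must be positive")
        self.pixel_spacing = (float(py), float(px))
        self.slice_thickness = float(self.slice_thickness)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        py, px = self.pixel_spacing
        return py * px * self.slice_thickness


@dataclass(frozen=True)
class NormalizationParams:
    """Offset-and-scale mapping from HU to the unit interval.

    ``offset_hu`` is added so that air (-1000 HU) maps to 0; ``factor_hu``
    divides the result. With the defaults, normalized 1.0 corresponds to
    1500 HU, i.e. 250% of water attenuation.
    """

    offset_hu: float = 1000.0
    factor_hu: float = 2500.0

    def __post_init__(self) -> None:
        if self.factor_hu <= 0:
            raise ParameterError("factor_hu must be > 0")


@dataclass
class NormalizedVolume:
    """A CT volume mapped into [0, 1] (clipped) with its mapping recorded."""

    values: np.ndarray
    params: NormalizationParams
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    meta: dict[str, str] = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        py, px = self.pixel_spacing
        return py * px * self.slice_thickness

    def to_hu(self) -> np.ndarray:
        """Invert the normalization (exact inside the unclipped range)."""
        return self.values * self.params.factor_hu - self.params.offset_hu


def normalize(vol: CTVolume, params: NormalizationParams | None = None) -> NormalizedVolume:
    """Offset-correct and scale HU into [0, 1], clipping out-of-range values.

    ``value = clip((HU + offset_hu) / factor_hu, 0, 1)``. With defaults,
    air -> 0.0, water -> 0.4 and 1500 HU -> 1.0.
    """
    params = params or NormalizationParams()
    scaled = (vol.voxels.astype(np.float32) + params.offset_hu) / params.factor_hu
    return NormalizedVolume(
        values=np.clip(scaled, 0.0, 1.0),
        params=params,
        pixel_spacing=vol.pixel_spacing,
        slice_thickness=vol.slice_thickness,
        meta=dict(vol.meta),
    )


def relative_attenuation_percent(
    norm_value: float | np.ndarray, params: NormalizationParams | None = None
) -> float | np.ndarray:
    """Convert a normalized value to attenuation as percent of water.

    Water sits at 0 HU = 100%; air at -1000 HU = 0%. With default
    parameters, normalized 1.0 corresponds to 250% of water attenuation.
    """
    params = params or NormalizationParams()
    arr = np.asarray(norm_value, dtype=float)
    if np.any(arr < 0) or np.any(arr > 1):
        raise ParameterError("norm_value must lie in [0, 1]")
    hu = arr * params.factor_hu - params.offset_hu
    percent = 100.0 * (1.0 + hu / 1000.0)
    return float(percent) if np.isscalar(norm_value) else percent


def remove_table(
    vol: CTVolume,
    air_hu: float = AIR_HU,
    opacity_hu: float = 200.0,
    min_row_coverage: float = 0.3,
) -> CTVolume:
    """Blank the scanner bed: everything on and below the table line becomes air.

    The table is identified on the slice-averaged image as the topmost row in
    which a wide horizontal band of pixels exceeds a characteristic opacity
    level (synthetic table surfaces are far denser than wood). Rows from that
    line downward are replaced by the surrounding air level. If no such band
    exists the volume is returned unchanged (absence of a table is normal).

    The operation is idempotent: once blanked, no band exceeds the opacity
    level, so a second call is a no-op.
    """
    mean_img = vol.voxels.mean(axis=0)
    dense = mean_img > opacity_hu
    coverage = dense.mean(axis=1)  # fraction of dense pixels per row
    rows = np.nonzero(coverage >= min_row_coverage)[0]
    out = vol.voxels.copy()
    if rows.size == 0:
        logger.info("remove_table: no table band detected; volume unchanged")
        return CTVolume(out, vol.pixel_spacing, vol.slice_thickness, dict(vol.meta))
    top = int(rows[0])
    out[:, top:, :] = air_hu
    logger.info("remove_table: table line at row %d replaced by air", top)
    meta = dict(vol.meta)
    meta["table_row"] = str(top)
    return CTVolume(out, vol.pixel_spacing, vol.slice_thickness, meta)


# ---------------------------------------------------------------------------
# I/O: DICOM series directory, NIfTI, multi-page TIFF + JSON spacing sidecar
# ---------------------------------------------------------------------------

_FORMATS = ("dicom_dir", "nifti", "tiff_stack")


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def _infer_format(path: Path) -> str:
    if path.is_dir():
        return "dicom_dir"
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".tif", ".tiff")):
        return "tiff_stack"
    raise ParameterError(f"cannot infer volume format from {path!r}")


def read_ct_volume(path: str | Path, format: str | None = None) -> CTVolume:
    """Read a CT volume; values are returned in HU.

    Parameters
    ----------
    path
        DICOM series directory, ``.nii``/``.nii.gz`` file, or multi-page
        TIFF with a ``.json`` spacing sidecar next to it.
    format
        One of ``dicom_dir``, ``nifti``, ``tiff_stack``; inferred from the
        path when omitted.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom_dir":
        return _read_dicom_dir(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "tiff_stack":
        return _read_tiff(path)
    raise ParameterError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def write_ct_volume(vol: CTVolume, path: str | Path, format: str | None = None) -> None:
    """Write a CT volume as DICOM series, NIfTI, or TIFF + spacing sidecar."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "dicom_dir":
        _write_dicom_dir(vol, path)
    elif fmt == "nifti":
        _write_nifti(vol, path)
    elif fmt == "tiff_stack":
        _write_tiff(vol, path)
    else:
        raise ParameterError(f"unknown format {fmt!r}; expected one of {_FORMATS}")


def _read_nifti(path: Path) -> CTVolume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise FormatError(f"expected 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # data axes are stored (z, y, x); zooms follow the data axes
    return CTVolume(
        voxels=data,
        pixel_spacing=(float(zooms[1]), float(zooms[2])),
        slice_thickness=float(zooms[0]),
    )


def _write_nifti(vol: CTVolume, path: Path) -> None:
    import nibabel as nib

    affine = np.diag([vol.slice_thickness, vol.pixel_spacing[0], vol.pixel_spacing[1], 1.0])
    img = nib.Nifti1Image(vol.voxels.astype(np.float32), affine)
    img.header.set_zooms((vol.slice_thickness, *vol.pixel_spacing))
    nib.save(img, str(path))


def _read_tiff(path: Path) -> CTVolume:
    import tifffile

    data = tifffile.imread(str(path)).astype(np.float32)
    if data.ndim == 2:
        data = data[None]
    if data.ndim != 3:
        raise FormatError(f"expected a 2-D/3-D TIFF stack, got shape {data.shape}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing spacing sidecar {sidecar}")
    info = json.loads(sidecar.read_text())
    try:
        py, px = info["pixel_spacing_mm"]
        thickness = info["slice_thickness_mm"]
    except KeyError as err:
        raise FormatError(f"spacing sidecar missing key {err}") from err
    return CTVolume(voxels=data, pixel_spacing=(py, px), slice_thickness=thickness)


def _write_tiff(vol: CTVolume, path: Path) -> None:
    import tifffile

    tifffile.imwrite(str(path), vol.voxels.astype(np.float32), photometric="minisblack")
    _sidecar_path(path).write_text(
        json.dumps(
            {
                "pixel_spacing_mm": list(vol.pixel_spacing),
                "slice_thickness_mm": vol.slice_thickness,
            }
        )
    )


def _read_dicom_dir(path: Path) -> CTVolume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise FormatError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        pos = getattr(ds, "ImagePositionPatient", None)
        if pos is not None:
            return float(pos[2])
        return int(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    shapes = {(int(ds.Rows), int(ds.Columns)) for ds in datasets}
    if len(shapes) != 1:
        raise FormatError(f"inconsistent slice shapes in series: {sorted(shapes)}")
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise FormatError(f"inconsistent pixel spacing in series: {sorted(spacings)}")
    slices = []
    for ds in datasets:
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(ds.pixel_array.astype(np.float32) * slope + intercept)
    ds0 = datasets[0]
    thickness = float(getattr(ds0, "SliceThickness", 1.0))
    py, px = (float(v) for v in ds0.PixelSpacing)
    meta = {}
    for attr in ("Manufacturer", "KVP", "SeriesDescription"):
        if hasattr(ds0, attr):
            meta[attr.lower()] = str(getattr(ds0, attr))
    return CTVolume(
        voxels=np.stack(slices, axis=0),
        pixel_spacing=(py, px),
        slice_thickness=thickness,
        meta=meta,
    )


def _write_dicom_dir(vol: CTVolume, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import CTImageStorage, ExplicitVRLittleEndian, generate_uid

    path.mkdir(parents=True, exist_ok=True)
    series_uid = generate_uid()
    study_uid = generate_uid()
    intercept = -1024.0
    raw = np.rint(vol.voxels - intercept)
    if raw.min() < 0 or raw.max() > np.iinfo(np.uint16).max:
        raise ParameterError("HU range not representable with the fixed DICOM rescale")
    raw = raw.astype(np.uint16)
    for z in range(vol.shape[0]):
        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = CTImageStorage
        meta.MediaStorageSOPInstanceUID = generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(None, {}, file_meta=meta, preamble=b"\0" * 128)
        ds.SOPClassUID = CTImageStorage
        ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
        ds.Modality = "CT"
        ds.SeriesInstanceUID = series_uid
        ds.StudyInstanceUID = study_uid
        ds.InstanceNumber = z + 1
        ds.ImagePositionPatient = [0.0, 0.0, z * vol.slice_thickness]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [vol.pixel_spacing[0], vol.pixel_spacing[1]]
        ds.SliceThickness = vol.slice_thickness
        ds.Rows, ds.Columns = vol.shape[1], vol.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = intercept
        ds.PixelData = raw[z].tobytes()
        ds.save_as(str(path / f"slice_{z:04d}.dcm"), enforce_file_format=True)
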