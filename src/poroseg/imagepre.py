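"""Volumetric image IO, cropping, coarse thresholding and isotropic resampling.

Conventions
-----------
Images are plain scalar grids indexed ``data[i, j, k]`` with per-axis voxel
spacing in millimetres.  The *origin* is the world position (mm) of the centre
of voxel ``(0, 0, 0)``, so world coordinates of voxel ``idx`` are
``origin + spacing * idx`` (voxel-centre convention).  ROI boxes use 0-based,
half-open index bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class VolumetricImage:
    """A 3-D scalar intensity grid with voxel spacing and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray  # (3,) mm, > 0
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        if self.data.ndim != 3:
            raise ValueError("image data must be a 3-D array")
        if not np.all(self.spacing > 0):
            raise ValueError("voxel spacing must be positive on every axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        return bool(np.allclose(self.spacing, self.spacing[0]))

    def world_coordinates(self, index) -> np.ndarray:
        """World position (mm) of a voxel centre; ``index`` may be fractional."""
        return self.origin + self.spacing * np.asarray(index, dtype=float)


@dataclass(frozen=True)
class RoiBox:
    """Half-open index bounds ``lower <= idx < upper`` per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]

    def __post_init__(self) -> None:
        lo, up = np.asarray(self.lower), np.asarray(self.upper)
        if lo.shape != (3,) or up.shape != (3,):
            raise ValueError("RoiBox bounds must have three entries")
        if not np.all(lo < up):
            raise ValueError("RoiBox requires lower < upper on every axis")
        if np.any(lo < 0):
            raise ValueError("RoiBox bounds must be non-negative")

    def intersect(self, other: "RoiBox") -> "RoiBox":
        lo = np.maximum(self.lower, other.lower)
        up = np.minimum(self.upper, other.upper)
        if np.any(lo >= up):
            raise ValueError("ROI intersection is empty")
        return RoiBox(tuple(int(x) for x in lo), tuple(int(x) for x in up))

    @classmethod
    def parse(cls, text: str) -> "RoiBox":
        """Parse ``"x0:x1,y0:y1,z0:z1"``."""
        parts = text.split(",")
        if len(parts) != 3:
            raise ValueError("ROI string must have three comma-separated ranges")
        lo, up = [], []
        for p in parts:
            a, b = p.split(":")
            lo.append(int(a))
            up.append(int(b))
        return cls(tuple(lo), tuple(up))


@dataclass(frozen=True)
class CoarseRange:
    """Inclusive coarse intensity window ``I_min <= I <= I_max``."""

    i_min: float
    i_max: float

    def __post_init__(self) -> None:
        if not self.i_min < self.i_max:
            raise ValueError("coarse range requires I_min < I_max")


@dataclass(frozen=True)
class ContrastReport:
    """First and second moments of object/background intensity, CNR and SNR.

    CNR follows the standard convention (mean difference over background sd).
    SNR is reported as the mean difference over the pooled object/background
    standard deviation ``sqrt((sd_ob**2 + sd_bg**2) / 2)``; the quantity is
    exposed under this documented convention only.
    """

    mean_object: float
    mean_background: float
    sd_object: float
    sd_background: float
    cnr: float
    snr: float
    cnr_defined: bool = True


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def _read_nifti(path: Path) -> VolumetricImage:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    affine = img.affine
    spacing = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    origin = affine[:3, 3]
    return VolumetricImage(data, spacing, origin)


def _write_nifti(img: VolumetricImage, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = np.diag(img.spacing)
    affine[:3, 3] = img.origin
    nib.save(nib.Nifti1Image(img.data, affine), str(path))


def _read_metaimage(path: Path) -> VolumetricImage:
    import SimpleITK as sitk

    itk = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(itk).transpose(2, 1, 0)
    return VolumetricImage(data, np.asarray(itk.GetSpacing()), np.asarray(itk.GetOrigin()))


def _write_metaimage(img: VolumetricImage, path: Path) -> None:
    import SimpleITK as sitk

    itk = sitk.GetImageFromArray(np.ascontiguousarray(img.data.transpose(2, 1, 0)))
    itk.SetSpacing(tuple(float(s) for s in img.spacing))
    itk.SetOrigin(tuple(float(o) for o in img.origin))
    sitk.WriteImage(itk, str(path))


def _read_raw(path: Path) -> VolumetricImage:
    """``.npy`` array with a JSON sidecar ``{spacing, origin}``, or ``.npz``."""
    if path.suffix == ".npz":
        with np.load(path) as z:
            return VolumetricImage(z["data"], z["spacing"],
                                   z["origin"] if "origin" in z else np.zeros(3))
    data = np.load(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FileNotFoundError(
            f"raw array {path} needs a JSON sidecar {sidecar.name} with spacing metadata")
    meta = json.loads(sidecar.read_text())
    if "spacing" not in meta:
        raise ValueError(f"sidecar {sidecar} is missing 'spacing'")
    return VolumetricImage(data, meta["spacing"], meta.get("origin", (0.0, 0.0, 0.0)))


def _write_raw(img: VolumetricImage, path: Path) -> None:
    if path.suffix == ".npz":
        np.savez(path, data=img.data, spacing=img.spacing, origin=img.origin)
        return
    np.save(path, img.data)
    path.with_suffix(".json").write_text(json.dumps(
        {"spacing": list(img.spacing), "origin": list(img.origin)}))


def _read_dicom_series(directory: Path, tol: float = 1e-3) -> VolumetricImage:
    """Read a single-frame DICOM series, rejecting irregular slice spacing."""
    import pydicom

    files = sorted(p for p in Path(directory).iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if not slices:
        raise ValueError(f"no DICOM slices with pixel data found in {directory}")
    slices.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    zpos = np.array([float(ds.ImagePositionPatient[2]) for ds in slices])
    dz = np.diff(zpos)
    if len(dz) == 0:
        raise ValueError("DICOM series has a single slice; cannot infer slice spacing")
    if np.any(dz <= 0):
        raise ValueError("duplicate or unsorted DICOM slice positions")
    if (dz.max() - dz.min()) > tol * dz.mean():
        raise ValueError(
            "inconsistent DICOM slice spacing (missing or irregular slices): "
            f"spacings range {dz.min():g}..{dz.max():g} mm")
    px = [float(v) for v in slices[0].PixelSpacing]
    spacing = np.array([px[1], px[0], float(dz.mean())])  # PixelSpacing is row,col
    # stack to data[i, j, k] = (col, row, slice)
    arr = np.stack([ds.pixel_array.astype(np.float64) for ds in slices], axis=-1)
    data = arr.transpose(1, 0, 2)
    ipp = slices[0].ImagePositionPatient
    origin = np.array([float(ipp[0]), float(ipp[1]), float(ipp[2])])
    return VolumetricImage(data, spacing, origin)


_FORMATS = {"nifti", "metaimage", "dicom", "raw"}


def _sniff_format(path: Path) -> str:
    name = path.name.lower()
    if path.is_dir():
        return "dicom"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mha", ".mhd")):
        return "metaimage"
    if name.endswith((".npy", ".npz")):
        return "raw"
    raise ValueError(f"cannot infer image format from {path}")


def read_volume(path, format_hint: str | None = None) -> VolumetricImage:
    """Read a volumetric image from NIfTI, MetaImage, DICOM series or raw array.

    Parameters
    ----------
    path : str or Path
        File (or DICOM directory) to read.
    format_hint : {"nifti", "metaimage", "dicom", "raw"}, optional
        Overrides extension sniffing.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or _sniff_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {sorted(_FORMATS)}")
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "metaimage":
        return _read_metaimage(path)
    if fmt == "dicom":
        return _read_dicom_series(path)
    return _read_raw(path)


def write_volume(img: VolumetricImage, path, format_hint: str | None = None) -> Path:
    """Write to NIfTI, MetaImage or raw ``.npy``/``.npz`` (by extension)."""
    path = Path(path)
    fmt = format_hint or _sniff_format(path)
    if fmt == "nifti":
        _write_nifti(img, path)
    elif fmt == "metaimage":
        _write_metaimage(img, path)
    elif fmt == "raw":
        _write_raw(img, path)
    else:
        raise ValueError(f"cannot write format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def crop(img: VolumetricImage, roi: RoiBox) -> VolumetricImage:
    """Crop to an ROI; the origin shifts so world coordinates are unchanged."""
    lo, up = np.asarray(roi.lower), np.asarray(roi.upper)
    if np.any(up > img.shape):
        raise ValueError(f"ROI {roi} exceeds image extent {img.shape}")
    sl = tuple(slice(a, b) for a, b in zip(lo, up))
    return VolumetricImage(img.data[sl].copy(), img.spacing.copy(),
                           img.origin + img.spacing * lo)


def resample_isotropic(img: VolumetricImage, target_spacing_mm: float) -> VolumetricImage:
    """Trilinear resample onto an isotropic grid of the given spacing.

    The new grid starts at the same world origin and keeps voxel centres
    within the original extent; sampling clamps to the edge voxels, so no
    background intensity is invented.
    """
    from scipy import ndimage

    t = float(target_spacing_mm)
    if t <= 0:
        raise ValueError("target spacing must be positive")
    extent = (np.array(img.shape) - 1) * img.spacing  # centre-to-centre, mm
    if np.any(t > np.maximum(extent, img.spacing.max())):
        raise ValueError("target spacing is larger than the image extent")
    new_shape = np.floor(extent / t).astype(int) + 1
    coords = np.meshgrid(*[np.arange(n) * t / s for n, s in zip(new_shape, img.spacing)],
                         indexing="ij")
    out = ndimage.map_coordinates(img.data, np.stack(coords), order=1, mode="nearest")
    return VolumetricImage(out, np.full(3, t), img.origin.copy())


def coarse_threshold(img: VolumetricImage, rng: CoarseRange) -> np.ndarray:
    """Boolean candidate mask: ``I_min <= I <= I_max`` (closed interval)."""
    return (img.data >= rng.i_min) & (img.data <= rng.i_max)


def contrast_metrics(img: VolumetricImage, object_mask: np.ndarray,
                     background_mask: np.ndarray) -> ContrastReport:
    """Object/background intensity moments with CNR and (pooled-sd) SNR.

    Standard deviations are population (``ddof=0``) statistics.  A
    zero-variance background makes the CNR undefined; it is reported as NaN
    with ``cnr_defined=False``.
    """
    ob = np.asarray(object_mask, bool)
    bg = np.asarray(background_mask, bool)
    if not ob.any() or not bg.any():
        raise ValueError("object and background masks must be non-empty")
    if np.any(ob & bg):
        raise ValueError("object and background masks must be disjoint")
    vo, vb = img.data[ob], img.data[bg]
    mo, mb = float(vo.mean()), float(vb.mean())
    so, sb = float(vo.std()), float(vb.std())
    pooled = float(np.sqrt(0.5 * (so ** 2 + sb ** 2)))
    if sb == 0.0:
        cnr, defined = float("nan"), False
    else:
        cnr, defined = (mo - mb) / sb, True
    snr = (mo - mb) / pooled if pooled > 0 else float("nan")
    return ContrastReport(mo, mb, so, sb, cnr, snr, defined)
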