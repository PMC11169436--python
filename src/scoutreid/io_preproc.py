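"""Reading, writing and preprocessing of scout CT images.

A scout (localizer) image is a 2D projection acquired before the main CT
scan.  Scanners from different vendors store it at different native pixel
spacings and fields of view, so every image is brought onto a common grid
before feature extraction:

1. resample to 2.0 x 2.0 mm^2 pixel spacing with bicubic interpolation,
2. crop (or zero-pad) the central 384 rows x 256 columns,
3. rescale the bit depth linearly down to 8 bits.

Supported containers are 16-bit grayscale PNG with a JSON metadata sidecar,
an NPZ bundle, and DICOM (PixelSpacing tag required).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image
from skimage.transform import resize
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "ScoutImage",
    "PreprocessConfig",
    "ScoutPreprocessor",
    "read_image",
    "write_image",
    "resample_to_spacing",
    "center_crop_pad",
    "rescale_8bit",
    "preprocess",
]


@dataclass
class ScoutImage:
    """A scout image: pixel grid plus physical spacing and exam metadata.

    Pixels are row-major, indexed ``[row, col]``; ``pixel_spacing`` is
    ``(row_mm, col_mm)``.  Metadata fields are optional because query
    images may arrive with lost or untrusted metadata — that is the
    problem the matcher solves.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    patient_id: str | None = None
    vendor: str | None = None
    table_height: float | None = None
    exam_role: str = "unknown"  # baseline | follow-up | unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got shape {self.pixels.shape}")
        r, c = self.pixel_spacing
        if not (r > 0 and c > 0):
            raise ValueError(f"pixel_spacing must be positive, got {self.pixel_spacing}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def metadata(self) -> dict:
        return {
            "pixel_spacing": list(self.pixel_spacing),
            "patient_id": self.patient_id,
            "vendor": self.vendor,
            "table_height": self.table_height,
            "exam_role": self.exam_role,
        }


@dataclass
class PreprocessConfig:
    """Preprocessing parameters; defaults are the common-grid settings above.

    ``per_image_window``: the 8-bit rescale uses each image's own min/max
    (a fixed global window is not used).
    """

    target_spacing: tuple[float, float] = (2.0, 2.0)
    crop_rows: int = 384
    crop_cols: int = 256
    out_depth: int = 8
    per_image_window: bool = True

    def __post_init__(self) -> None:
        if self.crop_rows <= 0 or self.crop_cols <= 0:
            raise ValueError("crop dimensions must be positive")
        if self.out_depth != 8:
            raise ValueError("only 8-bit output is supported")


# ---------------------------------------------------------------------------
# container I/O


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_image(img: ScoutImage, path: str | Path) -> Path:
    """Write a :class:`ScoutImage` to PNG+JSON sidecar, NPZ, or DICOM."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        arr = img.pixels
        if arr.dtype not in (np.uint8, np.uint16):
            raise ValueError(
                f"PNG container stores uint8/uint16 pixels, got {arr.dtype}; use .npz"
            )
        mode = "I;16" if arr.dtype == np.uint16 else "L"
        Image.fromarray(arr, mode=mode).save(path)
        _sidecar_path(path).write_text(json.dumps(img.metadata(), indent=1))
    elif suffix == ".npz":
        meta = {k: (v if v is not None else "") for k, v in img.metadata().items()}
        np.savez(
            path,
            pixels=img.pixels,
            pixel_spacing=np.asarray(img.pixel_spacing, dtype=float),
            meta=json.dumps(meta),
        )
    elif suffix in (".dcm", ".dicom"):
        _write_dicom(img, path)
    else:
        raise ValueError(f"unsupported container {suffix!r} (use .png, .npz or .dcm)")
    return path


def read_image(path: str | Path) -> ScoutImage:
    """Read a scout image; raises if physical pixel spacing is missing.

    Spacing is never silently assumed: an image without it cannot be
    resampled onto the common grid.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".png":
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"missing metadata sidecar {sidecar.name}: pixel_spacing unknown"
            )
        meta = json.loads(sidecar.read_text())
        if not meta.get("pixel_spacing"):
            raise ValueError(f"sidecar {sidecar.name} lacks field 'pixel_spacing'")
        arr = np.asarray(Image.open(path))
        if arr.dtype == np.int32:  # PIL reads I;16 as int32
            arr = arr.astype(np.uint16)
        return ScoutImage(
            pixels=arr,
            pixel_spacing=tuple(meta["pixel_spacing"]),
            patient_id=meta.get("patient_id"),
            vendor=meta.get("vendor"),
            table_height=meta.get("table_height"),
            exam_role=meta.get("exam_role") or "unknown",
        )
    if suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            meta = json.loads(str(f["meta"]))
            return ScoutImage(
                pixels=f["pixels"],
                pixel_spacing=tuple(f["pixel_spacing"]),
                patient_id=meta.get("patient_id") or None,
                vendor=meta.get("vendor") or None,
                table_height=meta.get("table_height") if meta.get("table_height") != "" else None,
                exam_role=meta.get("exam_role") or "unknown",
            )
    if suffix in (".dcm", ".dicom"):
        return _read_dicom(path)
    raise ValueError(f"unsupported container {suffix!r} (use .png, .npz or .dcm)")


def _read_dicom(path: Path) -> ScoutImage:
    import pydicom

    ds = pydicom.dcmread(path)
    if "PixelSpacing" not in ds:
        raise ValueError(f"DICOM file {path.name} lacks tag PixelSpacing (0028,0030)")
    spacing = tuple(float(v) for v in ds.PixelSpacing)  # (row, col)
    table_height = float(ds.TableHeight) if "TableHeight" in ds else None
    return ScoutImage(
        pixels=ds.pixel_array,
        pixel_spacing=spacing,
        patient_id=str(ds.PatientID) if "PatientID" in ds and ds.PatientID else None,
        vendor=str(ds.Manufacturer) if "Manufacturer" in ds and ds.Manufacturer else None,
        table_height=table_height,
    )


def _write_dicom(img: ScoutImage, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    arr = img.pixels
    if arr.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"DICOM export needs uint8/uint16 pixels, got {arr.dtype}")
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = img.patient_id or ""
    ds.PatientName = img.patient_id or ""
    ds.Manufacturer = img.vendor or ""
    ds.Rows, ds.Columns = arr.shape
    ds.PixelSpacing = [f"{img.pixel_spacing[0]:g}", f"{img.pixel_spacing[1]:g}"]
    if img.table_height is not None:
        ds.TableHeight = f"{img.table_height:g}"
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 8 * arr.itemsize
    ds.BitsStored = 8 * arr.itemsize
    ds.HighBit = 8 * arr.itemsize - 1
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# preprocessing chain


def resample_to_spacing(
    img: ScoutImage, target: tuple[float, float] = (2.0, 2.0)
) -> ScoutImage:
    """Resample onto ``target`` (row_mm, col_mm) spacing, bicubic.

    Output dimensions are ``round(dim_in * spacing_in / spacing_target)``
    per axis, so physical extent is preserved within one target pixel.
    """
    tr, tc = target
    if not (tr > 0 and tc > 0):
        raise ValueError(f"target spacing must be positive, got {target}")
    sr, sc = img.pixel_spacing
    out_shape = (
        int(round(img.pixels.shape[0] * sr / tr)),
        int(round(img.pixels.shape[1] * sc / tc)),
    )
    if out_shape == img.pixels.shape and (sr, sc) == (tr, tc):
        return replace(img, pixel_spacing=(tr, tc))
    out = resize(
        img.pixels.astype(np.float64),
        out_shape,
        order=3,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return replace(img, pixels=out, pixel_spacing=(tr, tc))


def _crop_pad_1d(n_in: int, n_out: int) -> tuple[slice, slice]:
    """Source and destination slices for a centered crop/pad of one axis.

    On odd excess the crop window is biased left/up (floor).
    """
    if n_in >= n_out:
        start = (n_in - n_out) // 2
        return slice(start, start + n_out), slice(0, n_out)
    start = (n_out - n_in) // 2
    return slice(0, n_in), slice(start, start + n_in)


def center_crop_pad(img: ScoutImage, rows: int = 384, cols: int = 256) -> ScoutImage:
    """Crop the central ``rows x cols`` window; zero-pad any deficit."""
    arr = img.pixels
    out = np.zeros((rows, cols), dtype=arr.dtype)
    src_r, dst_r = _crop_pad_1d(arr.shape[0], rows)
    src_c, dst_c = _crop_pad_1d(arr.shape[1], cols)
    out[dst_r, dst_c] = arr[src_r, src_c]
    return replace(img, pixels=out)


def crop_pad_array(arr: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Array-level centered crop/pad (shared with the augmentation pipeline)."""
    out = np.zeros((rows, cols), dtype=arr.dtype)
    src_r, dst_r = _crop_pad_1d(arr.shape[0], rows)
    src_c, dst_c = _crop_pad_1d(arr.shape[1], cols)
    out[dst_r, dst_c] = arr[src_r, src_c]
    return out


def rescale_8bit(img: ScoutImage) -> ScoutImage:
    """Linear per-image min-max rescale to [0, 255] uint8.

    A constant image maps to all zeros (the window has zero width).
    """
    arr = img.pixels.astype(np.float64)
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        out = np.zeros(arr.shape, dtype=np.uint8)
    else:
        out = np.round(255.0 * (arr - lo) / (hi - lo)).astype(np.uint8)
    return replace(img, pixels=out)


def preprocess(img: ScoutImage, config: PreprocessConfig | None = None) -> ScoutImage:
    """Full chain: resample -> center crop/pad -> 8-bit rescale."""
    config = config or PreprocessConfig()
    out = resample_to_spacing(img, config.target_spacing)
    out = center_crop_pad(out, config.crop_rows, config.crop_cols)
    return rescale_8bit(out)


class ScoutPreprocessor(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer wrapping :func:`preprocess`.

    ``transform`` maps a list of :class:`ScoutImage` to a
    ``(n, crop_rows, crop_cols)`` uint8 array ready for the embedder.
    """

    def __init__(
        self,
        target_spacing: tuple[float, float] = (2.0, 2.0),
        crop_rows: int = 384,
        crop_cols: int = 256,
    ):
        self.target_spacing = target_spacing
        self.crop_rows = crop_rows
        self.crop_cols = crop_cols

    def fit(self, X, y=None):
        self.config_ = PreprocessConfig(
            target_spacing=self.target_spacing,
            crop_rows=self.crop_rows,
            crop_cols=self.crop_cols,
        )
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "config_"):
            self.fit(X)
        return np.stack([preprocess(img, self.config_).pixels for img in X])
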