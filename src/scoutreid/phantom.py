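"""Synthetic trunk scout-CT phantom.

Generates anterior-view trunk projections with the statistical structure a
scout re-identification method has to cope with:

* per-patient stable anatomy (torso outline, lungs, periodic spine, pelvis,
  optional implant, a patient-specific soft-tissue texture field),
* vendor-specific native pixel spacing / field of view and monotone
  contrast processing (an "S-like" scanner at 2.0 x 2.0 mm and a "G-like"
  scanner at 0.55 x 0.60 mm),
* table-height-dependent transversal magnification: with the X-ray source
  at distance ``d0`` above the isocenter plane, raising the patient by
  ``dh`` widens the projection by ``s(dh) = d0 / (d0 - dh)`` while leaving
  the longitudinal direction (the table-feed axis) unchanged,
* per-exam nuisances: scan-range shift, lung inflation, intestinal gas,
  arm position, additive noise.

The anatomy is a sum of soft-edged geometric primitives — fast and with a
controllable identity signal, not anatomically realistic.  All randomness
flows from explicit seeds; no global state is used.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .io_preproc import ScoutImage, write_image

__all__ = [
    "PatientLatent",
    "ExamParams",
    "GeometryModel",
    "VendorSpec",
    "NuisanceRates",
    "CohortSpec",
    "VENDORS",
    "make_patient",
    "sample_exam_params",
    "render_exam",
    "generate_cohort",
    "transversal_scale_factor",
    "silhouette_width_mm",
]


@dataclass(frozen=True)
class PatientLatent:
    """Stable anatomy of one phantom patient (the identity signal)."""

    patient_id: str
    torso_half_widths: tuple[float, float, float]  # shoulder/waist/pelvis, mm
    torso_height: float  # mm
    lung_area_base: float  # fraction of the thorax
    spine_period: float  # mm, vertebral periodicity
    pelvis_aspect: float  # ratio of pelvis ellipse semi-axes
    implant_flag: bool
    texture_seed: int

    def __post_init__(self):
        if not self.patient_id:
            raise ValueError("patient_id must be nonempty")
        for hw in self.torso_half_widths:
            if not 120.0 <= hw <= 220.0:
                raise ValueError(f"half width {hw} outside [120, 220] mm")
        if not 0.2 <= self.lung_area_base <= 0.5:
            raise ValueError(f"lung_area_base {self.lung_area_base} outside [0.2, 0.5]")


@dataclass(frozen=True)
class ExamParams:
    """Per-exam nuisance and geometry state (everything that varies)."""

    vendor: str
    table_offset_dh: float  # mm, signed deviation from centered table height
    scan_range_shift: float  # mm, longitudinal shift of the scanned window
    lung_inflation: float  # multiplier on lung size
    gas_blobs: tuple[tuple[float, float, float], ...]  # (z_mm, x_mm, radius_mm)
    arms_raised: bool  # raised arms are out of the field (the neutral state)
    noise_sigma: float  # additive noise, fraction of dynamic range
    exam_index: int = 0


@dataclass(frozen=True)
class GeometryModel:
    """Projection geometry of the scout acquisition.

    ``sid`` is the source-to-detector distance (~100 cm on clinical
    scanners); ``d0`` the source-to-isocenter distance.  Only the width
    direction is magnified when the table height changes, because the
    longitudinal axis is swept by table feed, not projected.
    """

    sid: float = 1000.0
    d0: float = 600.0

    def __post_init__(self):
        if not 0 < self.d0 < self.sid:
            raise ValueError(f"need 0 < d0 < sid, got d0={self.d0}, sid={self.sid}")

    def scale(self, dh: float) -> float:
        """Transversal scale factor s(dh) = d0 / (d0 - dh); s(0) = 1."""
        if abs(dh) >= self.d0:
            raise ValueError(f"|dh|={abs(dh)} >= d0={self.d0}: degenerate geometry")
        return self.d0 / (self.d0 - dh)


def transversal_scale_factor(dh: float, d0: float = 600.0) -> float:
    """s(dh) = d0 / (d0 - dh) for a source-to-isocenter distance d0."""
    if abs(dh) >= d0:
        raise ValueError(f"|dh|={abs(dh)} >= d0={d0}: degenerate geometry")
    return d0 / (d0 - dh)


@dataclass(frozen=True)
class VendorSpec:
    """Native acquisition grid, contrast processing and table-height habit.

    ``dh_mean``/``dh_sd`` parameterize the table-height deviation from the
    centered position; vendors (sites) differ slightly in their mean set
    height, which makes cross-vendor query/gallery pairs carry a
    systematic width-magnification mismatch on top of the contrast shift.
    """

    name: str
    pixel_spacing: tuple[float, float]  # (row_mm, col_mm)
    fov_mm: float
    contrast: str  # "gamma_log" | "sigmoid"
    dh_mean: float
    dh_sd: float
    noise_sigma: float

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (
            int(round(self.fov_mm / self.pixel_spacing[0])),
            int(round(self.fov_mm / self.pixel_spacing[1])),
        )


VENDORS: dict[str, VendorSpec] = {
    "S-like": VendorSpec(
        name="S-like",
        pixel_spacing=(2.0, 2.0),
        fov_mm=560.0,
        contrast="gamma_log",
        dh_mean=3.0,
        dh_sd=14.0,
        noise_sigma=0.012,
    ),
    "G-like": VendorSpec(
        name="G-like",
        pixel_spacing=(0.55, 0.60),
        fov_mm=530.0,
        contrast="sigmoid",
        dh_mean=-6.0,
        dh_sd=13.0,
        noise_sigma=0.015,
    ),
}


@dataclass(frozen=True)
class NuisanceRates:
    """Occurrence rates of the per-exam nuisances (all in [0, 1])."""

    scan_range: float = 0.5
    lung_condition: float = 0.4
    intestinal_gas: float = 0.325
    arm_position: float = 0.225


@dataclass
class CohortSpec:
    """Design of a synthetic cohort.

    Training patients have ``exams_per_patient`` (>= 3) exams, one of
    which is held out as validation, so the train/validation split is
    disjoint by image but shares patients.  Test patients have at most two
    exams: a baseline (enrolled in the gallery) and, for a
    ``followup_fraction`` subset, a follow-up (the query).
    """

    n_patients: int = 20
    exams_per_patient: int = 3
    vendor_policy: str = "random-exam"  # or "fixed-patient"
    split: tuple[float, float, float] = (0.4, 0.1, 0.5)  # train/val/test patient mass
    followup_fraction: float = 1.0
    master_seed: int = 0
    geometry: GeometryModel = field(default_factory=GeometryModel)
    nuisance_rates: NuisanceRates = field(default_factory=NuisanceRates)

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if self.exams_per_patient < 3:
            raise ValueError("training patients need >= 3 exams per patient")
        if self.vendor_policy not in ("random-exam", "fixed-patient"):
            raise ValueError(f"unknown vendor_policy {self.vendor_policy!r}")


# ---------------------------------------------------------------------------
# sampling


def _id_to_entropy(patient_id: str) -> int:
    # stable across runs/processes (unlike hash())
    return zlib.crc32(patient_id.encode("utf-8"))


def make_patient(master_seed: int, patient_id: str) -> PatientLatent:
    """Deterministically derive a patient's stable anatomy from (seed, id)."""
    if not patient_id:
        raise ValueError("patient_id must be nonempty")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, _id_to_entropy(patient_id)])
    )
    shoulder = rng.uniform(160.0, 215.0)
    waist = rng.uniform(125.0, min(shoulder - 5.0, 195.0))
    pelvis = rng.uniform(140.0, 205.0)
    return PatientLatent(
        patient_id=patient_id,
        torso_half_widths=(shoulder, waist, pelvis),
        torso_height=rng.uniform(560.0, 740.0),
        lung_area_base=rng.uniform(0.25, 0.45),
        spine_period=rng.uniform(22.0, 34.0),
        pelvis_aspect=rng.uniform(0.45, 0.75),
        implant_flag=bool(rng.random() < 0.15),
        texture_seed=int(rng.integers(0, 2**31 - 1)),
    )


def sample_exam_params(
    latent: PatientLatent,
    vendor: str,
    exam_index: int,
    seed: int,
    rates: NuisanceRates | None = None,
) -> ExamParams:
    """Draw one exam's nuisance/geometry state.

    Table height deviates from the centered position as
    Normal(dh_mean_vendor, dh_sd_vendor); nuisance toggles fire with the
    configured rates and sit at neutral values otherwise.
    """
    if vendor not in VENDORS:
        raise ValueError(f"unknown vendor {vendor!r}; choose from {sorted(VENDORS)}")
    rates = rates or NuisanceRates()
    vs = VENDORS[vendor]
    rng = np.random.default_rng(
        np.random.SeedSequence(
            [int(seed) & 0x7FFFFFFF, _id_to_entropy(latent.patient_id), int(exam_index)]
        )
    )
    dh = float(rng.normal(vs.dh_mean, vs.dh_sd))

    scan_shift = float(rng.normal(0.0, 20.0)) if rng.random() < rates.scan_range else 0.0
    inflation = float(rng.uniform(0.8, 1.25)) if rng.random() < rates.lung_condition else 1.0

    gas: list[tuple[float, float, float]] = []
    if rng.random() < rates.intestinal_gas:
        for _ in range(int(rng.integers(1, 4))):
            gas.append(
                (
                    float(rng.uniform(60.0, 200.0)),  # z in the abdomen (below center)
                    float(rng.uniform(-80.0, 80.0)),
                    float(rng.uniform(10.0, 28.0)),
                )
            )
    arms_raised = not (rng.random() < rates.arm_position)

    return ExamParams(
        vendor=vendor,
        table_offset_dh=dh,
        scan_range_shift=scan_shift,
        lung_inflation=inflation,
        gas_blobs=tuple(gas),
        arms_raised=arms_raised,
        noise_sigma=vs.noise_sigma,
        exam_index=exam_index,
    )


# ---------------------------------------------------------------------------
# rendering


def _soft_step(x: np.ndarray, edge_mm: float = 1.5) -> np.ndarray:
    """Smooth 0->1 step; x > 0 is inside.  Steep edge keeps silhouettes crisp."""
    return 1.0 / (1.0 + np.exp(-np.clip(x / edge_mm, -40.0, 40.0)))


def _half_width(t: np.ndarray, hws: tuple[float, float, float]) -> np.ndarray:
    """Torso half-width profile along the normalized axis t (0 shoulder, 1 pelvis).

    Quadratic through (0.1, shoulder), (0.5, waist), (0.9, pelvis).
    """
    s, w, p = hws
    # Lagrange through three nodes
    t0, t1, t2 = 0.1, 0.5, 0.9
    l0 = (t - t1) * (t - t2) / ((t0 - t1) * (t0 - t2))
    l1 = (t - t0) * (t - t2) / ((t1 - t0) * (t1 - t2))
    l2 = (t - t0) * (t - t1) / ((t2 - t0) * (t2 - t1))
    return np.clip(s * l0 + w * l1 + p * l2, 80.0, 240.0)


@lru_cache(maxsize=256)
def _texture_coarse(texture_seed: int, nz: int = 28, nx: int = 18) -> np.ndarray:
    rng = np.random.default_rng(texture_seed)
    return rng.normal(0.0, 1.0, size=(nz, nx)).astype(np.float32)


def _texture_field(latent: PatientLatent, z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Patient-specific smooth random field, defined in patient coordinates.

    A coarse Gaussian grid is spline-interpolated at the queried (z, x)
    locations, so the same anatomy location shows the same texture under
    any vendor grid or magnification.
    """
    nz, nx = 28, 18
    coarse = _texture_coarse(latent.texture_seed)
    H = latent.torso_height
    zi = (z + H / 2.0) / H * (nz - 1)
    xi = (x + 240.0) / 480.0 * (nx - 1)
    return map_coordinates(coarse, [zi.ravel(), xi.ravel()], order=3, mode="nearest").reshape(z.shape)


def _attenuation(latent: PatientLatent, params: ExamParams, z: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Projected attenuation of the phantom at patient coordinates (z, x) in mm.

    z runs superior -> inferior with 0 at the torso center; x is lateral.
    """
    H = latent.torso_height
    t = np.clip((z + H / 2.0) / H, 0.0, 1.0)
    hw = _half_width(t, latent.torso_half_widths)
    body = _soft_step(hw - np.abs(x))

    a = 0.55 * body

    # lungs: two soft ellipses in the thorax
    area = latent.lung_area_base * params.lung_inflation
    ax = 0.30 * hw * np.sqrt(area / 0.35)
    az = 0.17 * H * np.sqrt(area / 0.35)
    zc = -0.28 * H
    for side in (-1.0, 1.0):
        xc = side * 0.42 * _half_width(np.asarray(0.22), latent.torso_half_widths)
        d2 = ((x - xc) / np.maximum(ax, 1.0)) ** 2 + ((z - zc) / az) ** 2
        a -= 0.33 * body * _soft_step(1.0 - d2, 0.08)

    # spine: central periodic band
    band = _soft_step(15.0 - np.abs(x), 2.0)
    a += 0.28 * band * body * (0.6 + 0.4 * np.sin(2.0 * np.pi * z / latent.spine_period))

    # pelvis ring
    zp = 0.38 * H
    axp = 0.80 * latent.torso_half_widths[2]
    azp = axp * latent.pelvis_aspect
    d = np.sqrt((x / axp) ** 2 + ((z - zp) / azp) ** 2)
    a += 0.30 * body * np.exp(-(((d - 0.85) / 0.13) ** 2))

    # implant: small bright disk at the right hip
    if latent.implant_flag:
        d2 = ((x - 0.55 * axp) ** 2 + (z - zp) ** 2) / 12.0**2
        a += 0.8 * np.exp(-d2)

    # intestinal gas: dark blobs in the abdomen
    for gz, gx, gr in params.gas_blobs:
        d2 = ((x - gx) ** 2 + (z - gz) ** 2) / gr**2
        a -= 0.25 * body * np.exp(-d2)

    # arms alongside the trunk when not raised (separate strips, below shoulder)
    if not params.arms_raised:
        in_z = _soft_step(z - (-0.45 * H), 8.0) * _soft_step((0.15 * H) - z, 8.0)
        for side in (-1.0, 1.0):
            ctr = side * (hw + 28.0)
            a += 0.35 * in_z * _soft_step(16.0 - np.abs(x - ctr), 2.0)

    # patient-specific soft-tissue texture
    a += 0.10 * body * _texture_field(latent, z, x)
    return a


def _vendor_contrast(a: np.ndarray, kind: str) -> np.ndarray:
    """Monotone vendor post-processing; input/output roughly in [0, 1]."""
    y = np.clip(a / 1.4, 0.0, 1.0)
    if kind == "gamma_log":
        y = y**0.8
        return np.log1p(4.0 * y) / np.log(5.0)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-6.0 * (y - 0.5)))
    raise ValueError(f"unknown contrast curve {kind!r}")


def render_exam(
    latent: PatientLatent,
    params: ExamParams,
    geometry: GeometryModel | None = None,
    noise_seed: int = 0,
) -> ScoutImage:
    """Render one exam on the vendor's native grid as a 16-bit image.

    The whole image width is scaled by s(dh) = d0/(d0 - dh) before
    discretization (detector column x maps to object coordinate x/s);
    the longitudinal axis is unaffected.  Rendering is deterministic
    given (latent, params, noise_seed).
    """
    geometry = geometry or GeometryModel()
    s = geometry.scale(params.table_offset_dh)  # raises on degenerate |dh| >= d0
    vs = VENDORS[params.vendor]
    n_rows, n_cols = vs.grid_shape
    sr, sc = vs.pixel_spacing

    r = (np.arange(n_rows, dtype=np.float32) + 0.5) - n_rows / 2.0
    c = (np.arange(n_cols, dtype=np.float32) + 0.5) - n_cols / 2.0
    z = (r * sr + params.scan_range_shift).astype(np.float32)
    x_det = c * sc
    zz, xx = np.meshgrid(z, (x_det / s).astype(np.float32), indexing="ij")

    a = _attenuation(latent, params, zz, xx)
    y = _vendor_contrast(a, vs.contrast)
    if params.noise_sigma > 0:
        rng = np.random.default_rng(
            np.random.SeedSequence(
                [int(noise_seed) & 0x7FFFFFFF, _id_to_entropy(latent.patient_id), params.exam_index]
            )
        )
        y = y + rng.normal(0.0, params.noise_sigma, size=y.shape)
    pixels = np.round(np.clip(y, 0.0, 1.0) * 65535.0).astype(np.uint16)
    return ScoutImage(
        pixels=pixels,
        pixel_spacing=vs.pixel_spacing,
        patient_id=latent.patient_id,
        vendor=params.vendor,
        table_height=params.table_offset_dh,
    )


def silhouette_width_mm(img: ScoutImage, z_mm: float = 0.0) -> float:
    """Physical silhouette width at longitudinal position ``z_mm``.

    Thresholds the row profile at the half-body attenuation level mapped
    through the image's vendor contrast curve, then locates the two edge
    crossings with linear (subpixel) interpolation.  Because the phantom
    body edge is a sigmoid centered on the true outline, the measured
    width is vendor- and contrast-independent up to discretization.
    """
    if img.vendor not in VENDORS:
        raise ValueError(f"image vendor {img.vendor!r} is not a phantom vendor")
    vs = VENDORS[img.vendor]
    thr = float(_vendor_contrast(np.asarray(0.5 * 0.55), vs.contrast)) * 65535.0
    n_rows, n_cols = img.pixels.shape
    sr, sc = img.pixel_spacing
    r = int(round(z_mm / sr + n_rows / 2.0 - 0.5))
    row = img.pixels[r].astype(np.float64)
    above = row > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        return 0.0
    left, right = idx[0], idx[-1]

    def cross(i_out: int, i_in: int) -> float:
        # linear interpolation of the threshold crossing between two pixels
        if i_out < 0 or i_out >= n_cols or row[i_in] == row[i_out]:
            return float(i_in)
        frac = (thr - row[i_out]) / (row[i_in] - row[i_out])
        return i_out + frac * (i_in - i_out)

    x_left = cross(left - 1, left)
    x_right = cross(right + 1, right)
    return float((x_right - x_left) * sc)


# ---------------------------------------------------------------------------
# cohort generation


def _assign_vendor(rng: np.random.Generator, policy: str, patient_vendor: str) -> str:
    if policy == "fixed-patient":
        return patient_vendor
    names = sorted(VENDORS)
    return names[int(rng.integers(len(names)))]


def generate_cohort(
    spec: CohortSpec, out_dir: str | Path | None = None
) -> tuple[pd.DataFrame, list[ScoutImage]]:
    """Generate a full cohort: manifest plus rendered images.

    Returns ``(manifest, images)``; ``manifest.iloc[i]`` describes
    ``images[i]``.  With ``out_dir`` set, images are written as 16-bit
    PNG + JSON sidecar and the manifest as ``manifest.csv`` with a
    ``path`` column.

    Split policy: train/val patients carry ``exams_per_patient`` exams
    with the last exam of each patient held out for validation; test
    patients carry a baseline exam and (for ``followup_fraction`` of
    them) one follow-up.  Baseline and follow-up table heights are drawn
    independently.
    """
    n = spec.n_patients
    n_trainval = int(round(n * (spec.split[0] + spec.split[1])))
    n_test = n - n_trainval
    if n_trainval < 3 and spec.split[0] + spec.split[1] > 0:
        raise ValueError(
            f"n_patients={n} too small for split {spec.split}: "
            f"only {n_trainval} training patients (need >= 3 classes)"
        )
    if n_test < 1 and spec.split[2] > 0:
        raise ValueError(f"n_patients={n} too small for split {spec.split}: no test patients")

    rng = np.random.default_rng(np.random.SeedSequence([spec.master_seed & 0x7FFFFFFF, 0xC0B0]))
    order = rng.permutation(n)
    ids = [f"P{i + 1:04d}" for i in range(n)]
    trainval_ids = {ids[i] for i in order[:n_trainval]}
    vendor_names = sorted(VENDORS)

    rows: list[dict] = []
    images: list[ScoutImage] = []
    for pid in ids:
        latent = make_patient(spec.master_seed, pid)
        patient_vendor = vendor_names[int(rng.integers(len(vendor_names)))]
        if pid in trainval_ids:
            exam_roles = [
                ("train", "train")
            ] * (spec.exams_per_patient - 1) + [("val", "val")]
            split_name = None  # per-exam below
        else:
            exam_roles = [("test", "baseline")]
            if rng.random() < spec.followup_fraction:
                exam_roles.append(("test", "follow-up"))
        for k, (split_name, role) in enumerate(exam_roles):
            vendor = _assign_vendor(rng, spec.vendor_policy, patient_vendor)
            params = sample_exam_params(
                latent, vendor, k, spec.master_seed, spec.nuisance_rates
            )
            img = render_exam(latent, params, spec.geometry, noise_seed=spec.master_seed)
            img = replace(img, exam_role=role if role in ("baseline", "follow-up") else "unknown")
            rows.append(
                {
                    "patient_id": pid,
                    "exam_index": k,
                    "vendor": vendor,
                    "dh_mm": params.table_offset_dh,
                    "split": split_name,
                    "role": role,
                    "path": "",
                }
            )
            images.append(img)

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for i, img in enumerate(images):
            p = out_dir / f"{manifest.patient_id[i]}_e{manifest.exam_index[i]}.png"
            write_image(img, p)
            paths.append(str(p))
        manifest["path"] = paths
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest, images
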