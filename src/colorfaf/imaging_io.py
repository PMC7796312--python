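"""Reading and writing of color-FAF images, exclusion masks, metadata, and cohort tables.

Images are 8-bit RGB rasters (PNG or TIFF) with a JSON metadata sidecar
carrying the fovea center in pixel coordinates, the physical scale in
micrometers per pixel, laterality (OD/OS) and the image side of the optic
disc.  All pixel coordinates in this package are 0-based ``(row, col)``
pairs measured between pixel centers.  Channel values are raw 8-bit sensor
counts; no photometric calibration to qAF units is attempted.

Cohort tables are one-row-per-eye CSV files with per-sector measurement
columns for the nine ETDRS sectors.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from PIL import Image

#: Canonical order of the nine ETDRS sectors used in cohort CSV columns.
SECTORS: tuple[str, ...] = (
    "fovea",
    "inner_nasal",
    "inner_superior",
    "inner_inferior",
    "inner_temporal",
    "outer_nasal",
    "outer_superior",
    "outer_inferior",
    "outer_temporal",
)

#: Central retinal thickness threshold (µm) defining center-involving DME.
DME_CRT_THRESHOLD_UM: float = 300.0

GROUPS: tuple[str, ...] = (
    "control",
    "noDR",
    "mildDR",
    "moderateDR",
    "sightThreateningDR",
)


class MetadataError(ValueError):
    """Raised when an image metadata record is missing or inconsistent."""


@dataclass(frozen=True)
class ImageMetadata:
    """Per-image acquisition metadata.

    Parameters
    ----------
    eye_id : str
        Identifier of the eye (one eye per patient).
    fovea_center : tuple of (float, float)
        Fovea position as 0-based ``(row, col)`` pixel coordinates.
    um_per_pixel : float
        Physical scale; the acquisition device resolves roughly
        5 µm x 5 µm per pixel, which is the package default elsewhere.
    laterality : {"OD", "OS"}
        Right (OD) or left (OS) eye.
    disc_side : {"left", "right"}
        Image side on which the optic disc lies.  Stored explicitly
        because fundus-camera display conventions vary; nasal/temporal
        sector labels derive from it.
    """

    eye_id: str
    fovea_center: tuple[float, float]
    um_per_pixel: float
    laterality: str
    disc_side: str

    def __post_init__(self) -> None:
        if self.um_per_pixel <= 0:
            raise MetadataError(f"um_per_pixel must be > 0, got {self.um_per_pixel}")
        if self.laterality not in ("OD", "OS"):
            raise MetadataError(f"laterality must be OD or OS, got {self.laterality!r}")
        if self.disc_side not in ("left", "right"):
            raise MetadataError(f"disc_side must be left or right, got {self.disc_side!r}")
        if len(self.fovea_center) != 2:
            raise MetadataError("fovea_center must be a (row, col) pair")


def default_disc_side(laterality: str) -> str:
    """Default optic-disc side for an erect, non-mirrored fundus image.

    The disc lies on the nasal retina; in the standard presentation this
    is the right side of the image for a right eye (OD) and the left side
    for a left eye (OS).
    """
    if laterality == "OD":
        return "right"
    if laterality == "OS":
        return "left"
    raise MetadataError(f"laterality must be OD or OS, got {laterality!r}")


@dataclass(frozen=True)
class FundusImage:
    """An 8-bit RGB color-FAF raster with its metadata.

    ``pixels`` is an ``H x W x 3`` uint8 array in (R, G, B) channel order.
    The red channel carries the long-wavelength (560-700 nm) emission
    component and the green channel the short-wavelength (500-560 nm)
    component; the blue channel lies below the emission cut-on and is not
    used for quantification.
    """

    pixels: np.ndarray
    metadata: ImageMetadata

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {px.shape}")
        if px.dtype != np.uint8:
            raise ValueError(f"pixels must be uint8 (8-bit), got {px.dtype}")
        r, c = self.metadata.fovea_center
        h, w = px.shape[:2]
        if not (0 <= r < h and 0 <= c < w):
            raise MetadataError(
                f"fovea_center {self.metadata.fovea_center} outside image bounds {h}x{w}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass(frozen=True)
class ExclusionMask:
    """Boolean raster marking pixels to avoid during measurement.

    True marks pixels occupied by retinal vessels or lesions
    (microaneurysms, hemorrhages, hard exudates).
    """

    pixels: np.ndarray

    def __post_init__(self) -> None:
        if self.pixels.ndim != 2 or self.pixels.dtype != bool:
            raise ValueError("mask must be a 2-D boolean array")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def n_excluded(self) -> int:
        return int(self.pixels.sum())


@dataclass
class EyeRecord:
    """One eye's clinical data and per-sector color-FAF measurements."""

    eye_id: str
    group: str
    dme: bool
    irf_by_sector: dict[str, bool] = field(default_factory=dict)
    thickness_by_sector: dict[str, float] = field(default_factory=dict)
    gefc_by_sector: dict[str, float] = field(default_factory=dict)
    refc_by_sector: dict[str, float] = field(default_factory=dict)
    wavelength_by_sector: dict[str, float] = field(default_factory=dict)
    hba1c: float = float("nan")
    dm_duration_y: float = float("nan")
    bcva: float = float("nan")

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        self.validate()

    def validate(self) -> list[str]:
        """Return (and warn about) soft invariant violations."""
        problems = []
        for s, t in self.thickness_by_sector.items():
            if np.isfinite(t) and t <= 0:
                problems.append(f"{self.eye_id}: non-positive thickness in {s}")
        crt = self.thickness_by_sector.get("fovea", float("nan"))
        if self.dme and np.isfinite(crt) and crt < DME_CRT_THRESHOLD_UM:
            problems.append(
                f"{self.eye_id}: labeled DME but central thickness "
                f"{crt:.0f} µm < {DME_CRT_THRESHOLD_UM:.0f} µm"
            )
        for p in problems:
            warnings.warn(p, stacklevel=3)
        return problems

    def to_row(self) -> dict:
        row: dict = {
            "eye_id": self.eye_id,
            "group": self.group,
            "dme": int(self.dme),
        }
        for s in SECTORS:
            row[f"irf_{s}"] = int(self.irf_by_sector.get(s, False))
        for prefix, d in (
            ("thickness", self.thickness_by_sector),
            ("gefc", self.gefc_by_sector),
            ("refc", self.refc_by_sector),
            ("wavelength", self.wavelength_by_sector),
        ):
            for s in SECTORS:
                row[f"{prefix}_{s}"] = d.get(s, float("nan"))
        row["hba1c"] = self.hba1c
        row["dm_duration_y"] = self.dm_duration_y
        row["bcva"] = self.bcva
        return row

    @classmethod
    def from_row(cls, row: dict) -> "EyeRecord":
        return cls(
            eye_id=str(row["eye_id"]),
            group=str(row["group"]),
            dme=bool(int(row["dme"])),
            irf_by_sector={s: bool(int(row[f"irf_{s}"])) for s in SECTORS if f"irf_{s}" in row},
            thickness_by_sector={
                s: float(row[f"thickness_{s}"]) for s in SECTORS if f"thickness_{s}" in row
            },
            gefc_by_sector={s: float(row[f"gefc_{s}"]) for s in SECTORS if f"gefc_{s}" in row},
            refc_by_sector={s: float(row[f"refc_{s}"]) for s in SECTORS if f"refc_{s}" in row},
            wavelength_by_sector={
                s: float(row[f"wavelength_{s}"]) for s in SECTORS if f"wavelength_{s}" in row
            },
            hba1c=float(row.get("hba1c", float("nan"))),
            dm_duration_y=float(row.get("dm_duration_y", float("nan"))),
            bcva=float(row.get("bcva", float("nan"))),
        )


#: Mandatory columns of a cohort CSV.
COHORT_COLUMNS: tuple[str, ...] = (
    ("eye_id", "group", "dme")
    + tuple(f"irf_{s}" for s in SECTORS)
    + tuple(f"thickness_{s}" for s in SECTORS)
    + tuple(f"gefc_{s}" for s in SECTORS)
    + tuple(f"refc_{s}" for s in SECTORS)
    + tuple(f"wavelength_{s}" for s in SECTORS)
    + ("hba1c", "dm_duration_y", "bcva")
)


# ---------------------------------------------------------------------------
# image / mask / metadata IO
# ---------------------------------------------------------------------------

def read_metadata(path: str | Path) -> ImageMetadata:
    """Read a JSON metadata sidecar."""
    with open(path) as fh:
        raw = json.load(fh)
    required = {"eye_id", "fovea_row", "fovea_col", "um_per_pixel", "laterality"}
    missing = required - raw.keys()
    if missing:
        raise MetadataError(f"metadata {path} missing fields: {sorted(missing)}")
    disc_side = raw.get("disc_side") or default_disc_side(raw["laterality"])
    return ImageMetadata(
        eye_id=str(raw["eye_id"]),
        fovea_center=(float(raw["fovea_row"]), float(raw["fovea_col"])),
        um_per_pixel=float(raw["um_per_pixel"]),
        laterality=str(raw["laterality"]),
        disc_side=disc_side,
    )


def write_metadata(meta: ImageMetadata, path: str | Path) -> None:
    record = {
        "eye_id": meta.eye_id,
        "fovea_row": meta.fovea_center[0],
        "fovea_col": meta.fovea_center[1],
        "um_per_pixel": meta.um_per_pixel,
        "laterality": meta.laterality,
        "disc_side": meta.disc_side,
    }
    with open(path, "w") as fh:
        json.dump(record, fh, indent=1)


def read_image(path: str | Path, metadata_path: str | Path) -> FundusImage:
    """Read an 8-bit RGB PNG/TIFF and its metadata sidecar.

    Rejects grayscale, paletted, 16-bit and RGBA inputs with a clear
    error rather than silently converting: channel identity (R = red
    emission component, G = green emission component) is the whole point.
    """
    img = Image.open(path)
    if img.mode != "RGB":
        raise ValueError(f"{path}: not RGB (mode {img.mode!r}); need 8-bit 3-channel")
    pixels = np.asarray(img, dtype=np.uint8)
    meta = read_metadata(metadata_path)
    return FundusImage(pixels=pixels, metadata=meta)


def write_image(image: FundusImage, path: str | Path) -> None:
    Image.fromarray(image.pixels, mode="RGB").save(path)


def read_mask(path: str | Path, companion_shape: tuple[int, int] | None = None) -> ExclusionMask:
    """Read a single-channel 0/255 PNG exclusion mask."""
    img = Image.open(path)
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise ValueError(f"{path}: mask must be single-channel, got shape {arr.shape}")
    if not np.isin(np.unique(arr), (0, 255)).all():
        raise ValueError(f"{path}: mask values must be 0 or 255")
    mask = ExclusionMask(pixels=arr == 255)
    if companion_shape is not None and mask.shape != tuple(companion_shape):
        raise ValueError(
            f"{path}: mask shape {mask.shape} != image shape {tuple(companion_shape)}"
        )
    return mask


def write_mask(mask: ExclusionMask, path: str | Path) -> None:
    Image.fromarray(np.where(mask.pixels, 255, 0).astype(np.uint8), mode="L").save(path)


# ---------------------------------------------------------------------------
# cohort table IO
# ---------------------------------------------------------------------------

def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV into a typed DataFrame (one row per eye).

    Unknown columns are preserved.  Soft invariants (positive thickness,
    DME implies central thickness >= 300 µm) are checked with warnings.
    """
    df = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing mandatory columns: {sorted(missing)}")
    bad = df["thickness_fovea"].apply(
        lambda v: not isinstance(v, (int, float, np.integer, np.floating))
    )
    if bad.any():
        raise ValueError("non-numeric thickness values in cohort CSV")
    validate_cohort(df)
    return df


def validate_cohort(df: pd.DataFrame) -> list[str]:
    """Warn about per-row invariant violations; return the messages."""
    problems: list[str] = []
    for _, row in df.iterrows():
        if row["dme"] and np.isfinite(row["thickness_fovea"]) and (
            row["thickness_fovea"] < DME_CRT_THRESHOLD_UM
        ):
            problems.append(
                f"{row['eye_id']}: labeled DME but central thickness "
                f"{row['thickness_fovea']:.0f} µm < {DME_CRT_THRESHOLD_UM:.0f} µm"
            )
        for s in SECTORS:
            t = row[f"thickness_{s}"]
            if np.isfinite(t) and t <= 0:
                problems.append(f"{row['eye_id']}: non-positive thickness in {s}")
    for p in problems:
        warnings.warn(p, stacklevel=2)
    return problems


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def cohort_from_records(records: Iterable[EyeRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in records], columns=list(COHORT_COLUMNS))
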