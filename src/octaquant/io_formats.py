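"""Image and table IO: readers, writers, and the bundled density dataset.

Angiography exports arrive as ordinary raster files (PNG/BMP from OCTA
systems, JPEG from dye angiography, single- or multi-page TIFF for
volumes); everything tabular is plain CSV with a header row, UTF-8 and
'.' decimals.

The package ships ``table1.csv``: the 32 matched vessel-density
measurements (16 subjects x 2 weekly time points, each measured with
ICGA, OMAG OCTA and SSADA OCTA).  Serials 1-16 are the week-2 scans and
17-32 the week-1 scans of subjects 1-16 — an ordering inferred from the
magnitude pattern (vessels reach the central cornea by week 2, so the
high-density block is the later time point); the mapping is recorded
here as an assumption, not a measured fact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FixtureError, FormatError, InvalidParameterError
from .pipeline import AngiographyVolume, EnFaceImage, VesselDensityRecord

__all__ = [
    "ManifestEntry",
    "DatasetManifest",
    "read_image",
    "write_image",
    "read_volume",
    "write_volume",
    "write_mask",
    "records_to_csv",
    "records_from_csv",
    "load_table1_fixture",
    "TABLE1_SHA256",
]

_IMAGE_SUFFIXES = {".png", ".bmp", ".jpg", ".jpeg", ".tif", ".tiff"}

TABLE1_SHA256 = "5b2acd2cf851848abdc87bd0e37a3b8cacd9c02dac12b29f9224aa5449d0d7a8"


@dataclass(frozen=True)
class ManifestEntry:
    subject_id: str
    week: int
    modality: str
    path: str
    pixel_size_um: float
    axial_spacing_um: float | None = None


@dataclass(frozen=True)
class DatasetManifest:
    """Catalogue of matched image files for a quantification run."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        paths = [e.path for e in self.entries]
        if len(set(paths)) != len(paths):
            raise InvalidParameterError("manifest paths must be unique")
        for e in self.entries:
            if e.pixel_size_um <= 0:
                raise InvalidParameterError(f"{e.path}: pixel_size_um must be > 0")
            if e.axial_spacing_um is not None and e.axial_spacing_um <= 0:
                raise InvalidParameterError(f"{e.path}: axial_spacing_um must be > 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DatasetManifest":
        df = pd.read_csv(path)
        entries = []
        for row in df.itertuples(index=False):
            spacing = getattr(row, "axial_spacing_um", None)
            if spacing is not None and pd.isna(spacing):
                spacing = None
            entries.append(
                ManifestEntry(
                    subject_id=str(row.subject_id),
                    week=int(row.week),
                    modality=str(row.modality),
                    path=str(row.path),
                    pixel_size_um=float(row.pixel_size_um),
                    axial_spacing_um=None if spacing is None else float(spacing),
                )
            )
        return cls(entries=tuple(entries))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame([e.__dict__ for e in self.entries]).to_csv(path, index=False)


def read_image(
    path: str | Path,
    pixel_size_um: float = 1.0,
    modality: str = "",
) -> EnFaceImage:
    """Read a 2D angiogram (PNG/BMP/JPEG/TIFF) as an 8-bit grayscale image.

    RGB collapses to grayscale by the unweighted channel mean; images
    with more than 8 bits per sample are rescaled so their maximum maps
    to 255 (noted in the provenance).
    """
    path = Path(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"{path}: unsupported image format {path.suffix!r}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            with Image.open(path) as im:
                arr = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # noqa: BLE001 - decoding errors vary by codec
        raise FormatError(f"{path}: could not be decoded ({exc})") from exc
    arr = np.asarray(arr)
    deep_sample = arr.dtype != np.uint8
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim == 3:
        arr = arr.astype(float).mean(axis=2)
    provenance = str(path)
    if deep_sample:
        top = float(arr.max())
        arr = np.zeros_like(arr, dtype=float) if top == 0 else arr / top * 255.0
        provenance += " rescaled-to-8bit"
    arr = np.round(arr).astype(np.uint8)
    return EnFaceImage(
        pixels=arr, pixel_size_um=pixel_size_um, modality=modality,
        provenance=provenance,
    )


def write_image(image: EnFaceImage, path: str | Path) -> None:
    """Write an image as 8-bit grayscale PNG/BMP/JPEG/TIFF."""
    path = Path(path)
    px = image.pixels if image.scale == "uint8" else np.round(
        image.as_unit() * 255.0
    ).astype(np.uint8)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, px)
    else:
        Image.fromarray(px, mode="L").save(path)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean vessel mask as a black/white PNG."""
    Image.fromarray(np.where(mask, 255, 0).astype(np.uint8), mode="L").save(path)


def read_volume(
    source: str | Path | Sequence[str | Path],
    axial_spacing_um: float,
    pixel_size_um: float = 1.0,
    modality: str = "",
) -> AngiographyVolume:
    """Read a volume from a multi-page TIFF, a directory of slices, or a
    list of per-slice image paths.  Slices stack anterior-first.
    """
    if axial_spacing_um <= 0:
        raise InvalidParameterError("axial_spacing_um must be > 0")
    if isinstance(source, (str, Path)):
        src = Path(source)
        if src.is_dir():
            paths = sorted(
                p for p in src.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
            )
            slices = [read_image(p, pixel_size_um).pixels for p in paths]
        else:
            arr = tifffile.imread(src)
            if arr.ndim == 2:
                slices = [arr]
            else:
                slices = [arr[k] for k in range(arr.shape[0])]
            slices = [s.astype(np.uint8) for s in slices]
    else:
        slices = [read_image(Path(p), pixel_size_um).pixels for p in source]
    if len(slices) < 2:
        raise FormatError("a volume needs at least 2 slices")
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise FormatError(f"inconsistent slice shapes: {sorted(shapes)}")
    voxels = np.stack(slices, axis=2)
    return AngiographyVolume(
        voxels=voxels,
        axial_spacing_um=axial_spacing_um,
        pixel_size_um=pixel_size_um,
        modality=modality,
    )


def write_volume(volume: AngiographyVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF, one page per depth slice."""
    pages = np.moveaxis(volume.voxels, 2, 0)
    tifffile.imwrite(Path(path), pages, photometric="minisblack")


def records_to_csv(records: Iterable[VesselDensityRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "week": r.week,
                "modality": r.modality,
                "slab_low_um": r.slab_low_um,
                "slab_high_um": r.slab_high_um,
                "density_percent": r.density_percent,
                "threshold": r.threshold,
                "roi": "" if r.roi is None else ";".join(map(str, r.roi)),
                "degenerate": r.degenerate,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[VesselDensityRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        slab_lo = getattr(row, "slab_low_um", None)
        slab_hi = getattr(row, "slab_high_um", None)
        records.append(
            VesselDensityRecord(
                subject_id=str(row.subject_id),
                week=int(row.week),
                modality=str(row.modality),
                density_percent=float(row.density_percent),
                slab_low_um=None if slab_lo is None or pd.isna(slab_lo) else float(slab_lo),
                slab_high_um=None if slab_hi is None or pd.isna(slab_hi) else float(slab_hi),
            )
        )
    return records


def load_table1_fixture() -> list[VesselDensityRecord]:
    """Load the bundled 32-measurement, three-modality density dataset.

    Returns 96 records (32 serials x 3 modalities).  Serial s in 1..16
    maps to (subject s, week 2); serial s in 17..32 to (subject s-16,
    week 1).  The file's checksum is verified before parsing.
    """
    data = (
        resources.files("octaquant").joinpath("data/table1.csv").read_bytes()
    )
    digest = hashlib.sha256(data).hexdigest()
    if digest != TABLE1_SHA256:
        raise FixtureError(
            f"table1.csv checksum mismatch: {digest} != {TABLE1_SHA256}"
        )
    from io import BytesIO

    df = pd.read_csv(BytesIO(data))
    records = []
    for row in df.itertuples(index=False):
        serial = int(row.serial)
        subject = serial if serial <= 16 else serial - 16
        week = 2 if serial <= 16 else 1
        for modality, value in (
            ("ICGA", row.icga), ("OMAG", row.omag), ("SSADA", row.ssada)
        ):
            records.append(
                VesselDensityRecord(
                    subject_id=f"rabbit{subject:02d}",
                    week=week,
                    modality=modality,
                    density_percent=float(value),
                )
            )
    if len(records) != 96:
        raise FixtureError(f"expected 96 records, parsed {len(records)}")
    return records
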