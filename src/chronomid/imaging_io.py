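"""Reading and writing timestamped cross-sectional slice images.

Slices are 2-D monochrome images organised by subject (mouse), integer week
and slice index along the bone axis. DICOM is the native on-disk format;
PNG (8/16-bit grayscale) is supported for lightweight fixtures. A
``manifest.csv`` accompanies every dataset and is the authoritative source
of subject/week/label metadata; the DICOM private tag merely mirrors the
week so single files remain self-describing.

Conventions used throughout the package:

* arrays are row-major, 0-based, indexed ``(row=y, col=x)``;
* translations are reported as ``(dy, dx)``;
* weeks are raw non-negative integers, never normalised;
* pixel values are non-negative integers preserved exactly (no rescaling).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MANIFEST_COLUMNS = ["path", "mouse_id", "group", "week", "slice_index", "height", "width"]

#: DICOM private creator string for the week timestamp mirror.
PRIVATE_CREATOR = "CHRONOMID"
PRIVATE_GROUP = 0x000B


class UntimestampedError(ValueError):
    """Raised when an image has no week timestamp in metadata or manifest."""


class DuplicateKeyError(ValueError):
    """Raised when two records share the same (mouse, week, slice) key."""


@dataclass
class SliceRecord:
    """One 2-D monochrome slice with its identifying metadata."""

    mouse_id: str
    week: int
    slice_index: int
    label: str | None = None
    pixels: np.ndarray | None = None
    path: str | None = None

    def __post_init__(self):
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels)
            if self.pixels.ndim != 2:
                raise ValueError("slice pixels must be a 2-D monochrome grid")
        if self.week is not None:
            _check_week(self.week)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def key(self):
        return (self.mouse_id, self.week, self.slice_index)

    def loaded(self) -> "SliceRecord":
        """Return a record with pixels in memory, reading from disk if needed."""
        if self.pixels is not None:
            return self
        if self.path is None:
            raise ValueError("record has neither pixels nor a path")
        on_disk = read_slice(self.path, week=self.week)
        return replace(self, pixels=on_disk.pixels)


def _check_week(week) -> int:
    if isinstance(week, (bool, float)) and not float(week).is_integer():
        raise ValueError(f"week must be an integer, got {week!r}")
    if int(week) != week:
        raise ValueError(f"week must be an integer, got {week!r}")
    if week < 0:
        raise ValueError(f"week must be non-negative, got {week!r}")
    return int(week)


def attach_timestamp(record: SliceRecord, week: int) -> SliceRecord:
    """Attach an integer week timestamp, stored raw and unscaled.

    Week numbers are deliberately kept as plain integers (week 5 is stored
    as 5, not 5/8): normalised timestamps would bake the study duration
    into every record and break comparability across studies.
    """
    return replace(record, week=_check_week(week))


# ---------------------------------------------------------------------------
# single-file I/O


def _read_png(path: Path) -> np.ndarray:
    from PIL import Image

    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im)
        else:
            raise ValueError(
                f"{path}: mode {im.mode!r} is not monochrome; slices must be grayscale"
            )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image")
    return arr


def _read_dicom(path: Path):
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-frame monochrome DICOM")
    week = None
    try:
        block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR)
        week = int(block[0x01].value)
    except KeyError:
        pass
    return arr, week


def read_slice(
    path,
    week: int | None = None,
    mouse_id: str = "",
    slice_index: int = 0,
    label: str | None = None,
) -> SliceRecord:
    """Read one slice image, preserving pixel values and dimensions exactly.

    The week may be supplied from a manifest (authoritative) or, for DICOM,
    read back from the private tag mirror. A slice without any week source
    raises :class:`UntimestampedError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".dcm", ".dicom"):
        pixels, tag_week = _read_dicom(path)
        if week is None:
            week = tag_week
    else:
        pixels = _read_png(path)
    if week is None:
        raise UntimestampedError(f"{path}: no week timestamp in metadata or manifest")
    return SliceRecord(
        mouse_id=mouse_id,
        week=_check_week(week),
        slice_index=slice_index,
        label=label,
        pixels=pixels,
        path=str(path),
    )


def write_slice(record: SliceRecord, path) -> None:
    """Write a slice as monochrome DICOM or grayscale PNG (by extension)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = record.pixels
    if pixels is None:
        raise ValueError("record has no pixels to write")
    if np.any(pixels < 0):
        raise ValueError("slice intensities must be non-negative")
    if path.suffix.lower() == ".png":
        _write_png(pixels, path)
    elif path.suffix.lower() in (".dcm", ".dicom"):
        _write_dicom(record, path)
    else:
        raise ValueError(f"unsupported slice format: {path.suffix}")


def _write_png(pixels: np.ndarray, path: Path) -> None:
    from PIL import Image

    if pixels.max(initial=0) > 65535:
        raise ValueError("PNG supports at most 16-bit intensities")
    if pixels.max(initial=0) > 255:
        Image.fromarray(pixels.astype(np.uint16)).save(path)
    else:
        Image.fromarray(pixels.astype(np.uint8), mode="L").save(path)


def _write_dicom(record: SliceRecord, path: Path) -> None:
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage

    pixels = record.pixels
    if pixels.max(initial=0) > 65535:
        raise ValueError("DICOM writer supports at most 16-bit intensities")
    arr = pixels.astype(np.uint16)

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid(
        entropy_srcs=[record.mouse_id, str(record.week), str(record.slice_index)]
    )
    meta.TransferSyntaxUID = ExplicitVRLittleEndian

    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.Modality = "OT"
    ds.PatientID = record.mouse_id
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.Rows, ds.Columns = arr.shape
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.PixelData = arr.tobytes()
    block = ds.private_block(PRIVATE_GROUP, PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "IS", str(record.week))
    ds.save_as(path, enforce_file_format=True)


# ---------------------------------------------------------------------------
# dataset index


class DatasetIndex:
    """Ordered, de-duplicated collection of slices keyed (mouse, week, slice)."""

    def __init__(self, records=()):
        self._records: dict[tuple, SliceRecord] = {}
        for r in records:
            self.add(r)

    def add(self, record: SliceRecord) -> None:
        if record.key in self._records:
            raise DuplicateKeyError(f"duplicate slice key {record.key}")
        self._records[record.key] = record

    def __len__(self):
        return len(self._records)

    def __iter__(self):
        return iter(sorted(self._records.values(), key=lambda r: r.key))

    def __contains__(self, key):
        return key in self._records

    def get(self, mouse_id, week, slice_index) -> SliceRecord:
        return self._records[(mouse_id, week, slice_index)]

    def mice(self):
        return sorted({k[0] for k in self._records})

    def weeks_of(self, mouse_id):
        return sorted({k[1] for k in self._records if k[0] == mouse_id})

    def mouse_weeks(self):
        return sorted({(k[0], k[1]) for k in self._records})

    def slices_of(self, mouse_id, week):
        recs = [r for k, r in self._records.items() if k[0] == mouse_id and k[1] == week]
        return sorted(recs, key=lambda r: r.slice_index)

    def labels(self) -> dict[str, str]:
        out = {}
        for r in self._records.values():
            if r.label is not None:
                out.setdefault(r.mouse_id, r.label)
        return out


def write_manifest(records, path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "path": r.path,
                "mouse_id": r.mouse_id,
                "group": r.label,
                "week": r.week,
                "slice_index": r.slice_index,
                "height": r.height,
                "width": r.width,
            }
        )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def scan_dataset(source) -> DatasetIndex:
    """Build a :class:`DatasetIndex` from a manifest CSV or a dataset directory.

    Pixels are left on disk (records carry paths); call
    :meth:`SliceRecord.loaded` when the grid is needed. Per-(mouse, week)
    slice counts are logged; an empty source yields an empty index with a
    warning.
    """
    source = Path(source)
    if source.is_dir():
        manifest = source / "manifest.csv"
        if not manifest.exists():
            return _scan_directory(source)
        source = manifest
    df = pd.read_csv(source)
    index = DatasetIndex()
    root = source.parent
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = root / p
        if not p.exists():
            raise FileNotFoundError(p)
        index.add(
            SliceRecord(
                mouse_id=str(row.mouse_id),
                week=int(row.week),
                slice_index=int(row.slice_index),
                label=None if pd.isna(row.group) else str(row.group),
                pixels=None,
                path=str(p),
            )
        )
    _log_counts(index)
    return index


def _scan_directory(root: Path) -> DatasetIndex:
    index = DatasetIndex()
    files = sorted(root.rglob("*.dcm"))
    if not files:
        warnings.warn(f"{root}: no manifest and no DICOM files; empty index")
        return index
    for i, f in enumerate(files):
        rec = read_slice(f, mouse_id=f.stem, slice_index=i)
        index.add(rec)
    _log_counts(index)
    return index


def _log_counts(index: DatasetIndex) -> None:
    if len(index) == 0:
        warnings.warn("scanned dataset is empty")
        return
    for mouse, week in index.mouse_weeks():
        logger.info("mouse %s week %d: %d slices", mouse, week, len(index.slices_of(mouse, week)))
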