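"""Reading and writing CT slices.

Chest CT exams arrive either as DICOM files (one file per axial slice) or as
8-bit grayscale PNG exports of those slices.  This module loads single slices,
orders a directory of them into a :class:`SliceStack`, and writes binary masks
back out as loss-less PNG.  DICOM pixel data are reduced to 8-bit grayscale on
load and all patient-identifying metadata are dropped: the returned objects
carry only pixels, an ordinal slice index, and an opaque source id.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Tuple

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import InconsistentSeriesError, InputError, UnsupportedFormatError

__all__ = [
    "GrayscaleSlice",
    "SliceStack",
    "load_slice",
    "load_series",
    "write_mask_image",
]

_DICOM_SUFFIXES = {".dcm", ".dicom", ".ima"}
_PNG_SUFFIXES = {".png"}


def _opaque_id(path: Path) -> str:
    """De-identified handle for a source file (never exposes metadata)."""
    return hashlib.sha1(path.name.encode("utf-8")).hexdigest()[:12]


@dataclass(frozen=True)
class GrayscaleSlice:
    """One axial CT slice as an M x N grid of 8-bit intensities.

    Parameters
    ----------
    pixels
        2-D ``uint8`` array of intensities in [0, 255].
    slice_index
        Ordinal position ``j`` of the slice within its exam (1-based).
    source_id
        Opaque, de-identified string naming the origin of the slice.
    """

    pixels: np.ndarray
    slice_index: int = 1
    source_id: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise InputError(f"slice pixels must be 2-D, got shape {arr.shape}")
        if arr.dtype != np.uint8:
            if not (np.issubdtype(arr.dtype, np.integer) and arr.min() >= 0 and arr.max() <= 255):
                raise InputError("slice intensities must be integers in [0, 255]")
            arr = arr.astype(np.uint8)
        if self.slice_index < 1:
            raise InputError("slice_index must be >= 1")
        object.__setattr__(self, "pixels", arr)

    @property
    def rows(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def cols(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def shape(self) -> Tuple[int, int]:
        return (self.rows, self.cols)


@dataclass
class SliceStack:
    """Ordered sequence of slices of one exam.

    Invariants: slices sorted strictly ascending by ``slice_index`` and all
    slices share identical dimensions.
    """

    slices: Sequence[GrayscaleSlice]
    spacing_mm: Optional[Tuple[float, float, float]] = None
    exam_id: str = ""

    def __post_init__(self) -> None:
        slices = list(self.slices)
        if not slices:
            raise InputError("a slice stack needs at least one slice")
        shape = slices[0].shape
        for s in slices[1:]:
            if s.shape != shape:
                raise InconsistentSeriesError(
                    f"mixed slice dimensions in series: {s.shape} vs {shape}"
                )
        idx = [s.slice_index for s in slices]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise InputError("slice indices must be strictly ascending and unique")
        self.slices = slices

    def __len__(self) -> int:
        return len(self.slices)

    def __iter__(self) -> Iterator[GrayscaleSlice]:
        return iter(self.slices)

    def __getitem__(self, i: int) -> GrayscaleSlice:
        return self.slices[i]

    @property
    def shape(self) -> Tuple[int, int]:
        return self.slices[0].shape

    def by_index(self) -> dict[int, GrayscaleSlice]:
        return {s.slice_index: s for s in self.slices}


def _to_uint8(raw: np.ndarray, window: Optional[Tuple[float, float]]) -> np.ndarray:
    """Map raw DICOM stored values linearly to [0, 255].

    Default is per-slice min-max scaling; an explicit ``(center, width)``
    window overrides it.  A degenerate range (max == min) maps to all zeros.
    """
    raw = raw.astype(np.float64)
    if window is not None:
        center, width = float(window[0]), float(window[1])
        if width <= 0:
            raise InputError("window width must be positive")
        lo, hi = center - width / 2.0, center + width / 2.0
    else:
        lo, hi = float(raw.min()), float(raw.max())
        if hi == lo:
            return np.zeros(raw.shape, dtype=np.uint8)
    scaled = (np.clip(raw, lo, hi) - lo) / (hi - lo) * 255.0
    return np.rint(scaled).astype(np.uint8)


def _read_png(path: Path) -> np.ndarray:
    try:
        with Image.open(path) as img:
            if img.mode != "L":
                raise UnsupportedFormatError(
                    f"{path.name}: only 8-bit grayscale PNG is supported (mode {img.mode!r})"
                )
            return np.asarray(img, dtype=np.uint8)
    except UnidentifiedImageError as exc:
        raise InputError(f"unreadable image file: {path}") from exc


def _read_dicom(path: Path, window: Optional[Tuple[float, float]]):
    import pydicom

    try:
        ds = pydicom.dcmread(path)
    except Exception as exc:  # pydicom raises several error types
        raise InputError(f"unreadable DICOM file: {path}") from exc
    if int(getattr(ds, "NumberOfFrames", 1) or 1) > 1:
        raise UnsupportedFormatError(f"{path.name}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1) or 1) != 1:
        raise UnsupportedFormatError(f"{path.name}: color DICOM payload is not supported")
    try:
        raw = ds.pixel_array
    except Exception as exc:
        raise InputError(f"cannot decode pixel data of {path}") from exc
    if raw.ndim != 2:
        raise UnsupportedFormatError(f"{path.name}: expected a single 2-D frame")
    instance = getattr(ds, "InstanceNumber", None)
    instance = int(instance) if instance is not None else None
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None and len(ps) == 2:
        thickness = float(getattr(ds, "SliceThickness", 0.0) or 0.0)
        spacing = (float(ps[0]), float(ps[1]), thickness)
    return _to_uint8(raw, window), instance, spacing


def load_slice(
    path, window: Optional[Tuple[float, float]] = None, slice_index: int = 1
) -> GrayscaleSlice:
    """Load one DICOM or 8-bit grayscale PNG slice.

    PNG pixels are read verbatim; DICOM stored values are mapped linearly to
    [0, 255] (min-max by default, or an explicit ``(center, width)`` window).
    No patient-identifying metadata is retained.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in _PNG_SUFFIXES:
        pixels = _read_png(path)
    elif suffix in _DICOM_SUFFIXES:
        pixels, _, _ = _read_dicom(path, window)
    else:
        raise UnsupportedFormatError(f"unsupported file type: {path.name}")
    return GrayscaleSlice(pixels=pixels, slice_index=slice_index, source_id=_opaque_id(path))


def load_series(
    directory, window: Optional[Tuple[float, float]] = None, exam_id: Optional[str] = None
) -> SliceStack:
    """Order all slice files of a directory into a :class:`SliceStack`.

    DICOM files are ordered by InstanceNumber when every file carries one,
    otherwise files are ordered lexicographically by name.  ``slice_index`` is
    assigned 1..m in that order.  Non-image files in the directory are ignored.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise InputError(f"no such directory: {directory}")
    files = sorted(
        p
        for p in directory.iterdir()
        if p.is_file() and p.suffix.lower() in (_PNG_SUFFIXES | _DICOM_SUFFIXES)
    )
    if not files:
        raise InputError(f"no slice files (PNG/DICOM) in {directory}")

    loaded = []  # (sort key available?, instance, name, pixels, spacing)
    spacing = None
    all_instances = True
    for p in files:
        if p.suffix.lower() in _PNG_SUFFIXES:
            loaded.append((None, p, _read_png(p)))
            all_instances = False
        else:
            pixels, instance, sp = _read_dicom(p, window)
            spacing = spacing or sp
            loaded.append((instance, p, pixels))
            if instance is None:
                all_instances = False

    if all_instances:
        loaded.sort(key=lambda t: (t[0], t[1].name))
    else:
        loaded.sort(key=lambda t: t[1].name)

    shape = loaded[0][2].shape
    for _, p, pixels in loaded:
        if pixels.shape != shape:
            raise InconsistentSeriesError(
                f"{p.name} has dimensions {pixels.shape}, expected {shape}"
            )
    slices = [
        GrayscaleSlice(pixels=pixels, slice_index=i + 1, source_id=_opaque_id(p))
        for i, (_, p, pixels) in enumerate(loaded)
    ]
    return SliceStack(
        slices=slices,
        spacing_mm=spacing,
        exam_id=exam_id if exam_id is not None else _opaque_id(directory),
    )


def write_mask_image(mask: np.ndarray, path) -> None:
    """Write a binary mask as loss-less PNG (foreground 255, background 0)."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise InputError("mask must be 2-D")
    uniq = np.unique(mask)
    if not np.all(np.isin(uniq, (0, 1, 255, True, False))):
        raise InputError("mask must be binary")
    out = np.where(mask.astype(bool), 255, 0).astype(np.uint8)
    path = Path(path)
    try:
        Image.fromarray(out, mode="L").save(path, format="PNG")
    except OSError as exc:
        raise InputError(f"cannot write mask to {path}") from exc
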