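"""Reading, windowing, and frame extraction for abdominal CT volumes.

A CT volume is treated as an ordered stack of axial slices, indexed
``(z, y, x)`` with ``z`` increasing cranially (toward the head).  Slice
propagation backends consume the volume as a "video" of 2D frames, so this
module converts Hounsfield-unit volumes to ordered 8-bit frame sequences
via standard soft-tissue CT windowing (window level 50 HU, window width
400 HU), and provides the dataset-level mask filters applied before
evaluation.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from io import BytesIO
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
from PIL import Image

# Soft-tissue CT display window.
DEFAULT_WINDOW_LEVEL = 50.0  # HU
DEFAULT_WINDOW_WIDTH = 400.0  # HU

# Ground-truth masks at or below this voxel count are treated as annotation
# deficiencies and excluded from analysis.
SMALL_MASK_THRESHOLD = 100

# Canonical vocabulary of the eight evaluated abdominal organs.
ABDOMINAL_ORGANS = (
    "liver",
    "right_kidney",
    "left_kidney",
    "spleen",
    "gallbladder",
    "pancreas",
    "right_adrenal",
    "left_adrenal",
)

LOSSLESS = "lossless"


class VolumeIOError(ValueError):
    """Raised for unreadable, malformed, or non-3D volume inputs."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D grid of Hounsfield-unit intensities, axial axis first.

    ``intensities`` is indexed ``(z, y, x)`` with z increasing cranially.
    """

    intensities: np.ndarray
    scan_id: str
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=np.float64)
        if arr.ndim != 3:
            raise VolumeIOError(
                f"expected 3D volume, got {arr.ndim}D array for scan {self.scan_id!r}"
            )
        if not np.all(np.isfinite(arr)):
            raise VolumeIOError(f"non-finite voxel intensities in scan {self.scan_id!r}")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def height(self) -> int:
        return self.intensities.shape[1]

    @property
    def width(self) -> int:
        return self.intensities.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass(frozen=True)
class LabelMask:
    """Binary 3D mask for one named organ, voxel-aligned to its CTVolume."""

    organ: str
    mask: np.ndarray

    def __post_init__(self) -> None:
        if not self.organ:
            raise VolumeIOError("organ name must be non-empty")
        arr = np.asarray(self.mask)
        if arr.ndim != 3:
            raise VolumeIOError(f"mask for {self.organ!r} must be 3D, got {arr.ndim}D")
        object.__setattr__(self, "mask", arr.astype(bool))

    @property
    def voxel_volume(self) -> int:
        """Count of true voxels (organ volume in voxels, not physical units)."""
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape


@dataclass(frozen=True)
class FrameStack:
    """Ordered 8-bit axial frames; frame index is identical to z."""

    frames: np.ndarray  # (n_slices, height, width) uint8
    encoding: str = LOSSLESS  # "lossless" or "jpeg:q<quality>"

    def __post_init__(self) -> None:
        arr = np.asarray(self.frames)
        if arr.ndim != 3 or arr.dtype != np.uint8:
            raise VolumeIOError("frames must be a 3D uint8 array (n, h, w)")
        object.__setattr__(self, "frames", arr)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


def read_volume(path: str | os.PathLike, scan_id: str | None = None) -> CTVolume:
    """Read a 3D NIfTI image as a CTVolume with the axial axis at index 0.

    The voxel array is taken in file order with axis 0 as the axial (z)
    axis; the affine's orientation codes are recorded in ``provenance`` so
    the convention is auditable.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several error types
        raise VolumeIOError(f"unreadable NIfTI file {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeIOError(f"expected 3D volume, got {data.ndim}D image at {path}")
    data = np.asarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise VolumeIOError(f"non-finite voxels in {path}")
    try:
        axcodes = "".join(nib.aff2axcodes(img.affine))
    except Exception:
        axcodes = "unknown"
    sid = scan_id if scan_id is not None else path.name.split(".")[0]
    return CTVolume(
        intensities=data,
        scan_id=sid,
        provenance=f"nifti:{path.name};axis0=axial;axcodes={axcodes}",
    )


def write_volume(vol: CTVolume, path: str | os.PathLike) -> Path:
    """Write a CTVolume to NIfTI with an identity affine (voxel units)."""
    path = Path(path)
    img = nib.Nifti1Image(vol.intensities.astype(np.float32), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def write_label_volume(
    masks: Sequence[LabelMask], path: str | os.PathLike
) -> dict[str, int]:
    """Write disjoint LabelMasks as one integer label NIfTI.

    Returns the organ-name -> integer-label map (labels assigned 1..n in
    input order; 0 is background).
    """
    if not masks:
        raise VolumeIOError("no masks to write")
    shape = masks[0].shape
    label = np.zeros(shape, dtype=np.int16)
    name_to_label: dict[str, int] = {}
    for i, m in enumerate(masks, start=1):
        if m.shape != shape:
            raise VolumeIOError(f"mask shape mismatch for {m.organ!r}")
        if np.any(label[m.mask] != 0):
            raise VolumeIOError(f"mask {m.organ!r} overlaps a previously written mask")
        label[m.mask] = i
        name_to_label[m.organ] = i
    img = nib.Nifti1Image(label, affine=np.eye(4))
    nib.save(img, str(Path(path)))
    return name_to_label


def read_label_volume(
    path: str | os.PathLike, name_to_label: Mapping[str, int]
) -> list[LabelMask]:
    """Split an integer label NIfTI into per-organ LabelMasks."""
    vol = read_volume(path)
    return split_label_volume(vol.intensities, name_to_label)


def split_label_volume(
    label_array: np.ndarray, name_to_label: Mapping[str, int]
) -> list[LabelMask]:
    """Split an integer label volume into binary per-organ masks."""
    arr = np.asarray(label_array)
    if arr.ndim != 3:
        raise VolumeIOError(f"label volume must be 3D, got {arr.ndim}D")
    return [
        LabelMask(organ=name, mask=(arr == lab)) for name, lab in name_to_label.items()
    ]


def apply_window(
    hu,
    level: float = DEFAULT_WINDOW_LEVEL,
    width: float = DEFAULT_WINDOW_WIDTH,
):
    """Window Hounsfield units to 8-bit intensities.

    Values are clipped to ``[level - width/2, level + width/2]``, linearly
    mapped to [0, 255], and rounded half-away-from-zero to integers so the
    conversion is bit-reproducible across platforms.

    Accepts scalars or arrays; returns uint8 of matching shape (a Python
    int for scalar input).
    """
    if width <= 0:
        raise VolumeIOError(f"window width must be positive, got {width}")
    arr = np.asarray(hu, dtype=np.float64)
    lo = level - width / 2.0
    clipped = np.clip(arr, lo, level + width / 2.0)
    scaled = (clipped - lo) / width * 255.0
    # scaled >= 0, so floor(x + 0.5) rounds half away from zero
    out = np.floor(scaled + 0.5).astype(np.uint8)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return int(out)
    return out


def _jpeg_roundtrip(frame: np.ndarray, quality: int) -> np.ndarray:
    buf = BytesIO()
    Image.fromarray(frame, mode="L").save(buf, format="JPEG", quality=quality)
    buf.seek(0)
    return np.asarray(Image.open(buf), dtype=np.uint8)


def parse_encoding(encoding: str) -> tuple[str, int | None]:
    """Parse an encoding string: 'lossless' or 'jpeg[:q<quality>]'."""
    if encoding == LOSSLESS:
        return LOSSLESS, None
    m = re.fullmatch(r"jpeg(?::q(\d{1,3}))?", encoding)
    if m:
        q = int(m.group(1)) if m.group(1) else 95
        if not 1 <= q <= 100:
            raise VolumeIOError(f"jpeg quality out of range: {q}")
        return "jpeg", q
    raise VolumeIOError(f"unknown frame encoding {encoding!r}")


def to_frames(
    vol: CTVolume,
    encoding: str = LOSSLESS,
    level: float = DEFAULT_WINDOW_LEVEL,
    width: float = DEFAULT_WINDOW_WIDTH,
) -> FrameStack:
    """Window every axial slice of ``vol`` into an ordered 8-bit FrameStack.

    With ``encoding='lossless'`` frame i is exactly ``apply_window`` applied
    to slice i.  With ``encoding='jpeg:q<N>'`` each frame is additionally
    passed through an in-memory JPEG encode/decode cycle at quality N, so
    downstream consumers see the same lossy pixels a JPEG-on-disk pipeline
    would.
    """
    kind, quality = parse_encoding(encoding)
    windowed = apply_window(vol.intensities, level=level, width=width)
    if kind == "jpeg":
        windowed = np.stack(
            [_jpeg_roundtrip(windowed[z], quality) for z in range(windowed.shape[0])]
        )
        encoding = f"jpeg:q{quality}"
    return FrameStack(frames=windowed, encoding=encoding)


def write_frames(stack: FrameStack, directory: str | os.PathLike) -> list[Path]:
    """Write frames as zero-padded numeric files so lexical order equals z.

    Lossless stacks are written as PNG, JPEG stacks as .jpg at the recorded
    quality.  Returns the written paths in z order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    kind, quality = parse_encoding(stack.encoding)
    ext = "png" if kind == LOSSLESS else "jpg"
    n = stack.n_frames
    pad = max(4, len(str(n - 1)))
    paths: list[Path] = []
    for z in range(n):
        p = directory / f"{z:0{pad}d}.{ext}"
        try:
            img = Image.fromarray(stack.frames[z], mode="L")
            if kind == "jpeg":
                img.save(p, quality=quality)
            else:
                img.save(p)
        except OSError as exc:
            raise VolumeIOError(f"failed to write frame {z} to {p}: {exc}") from exc
        paths.append(p)
    return paths


def read_frames(directory: str | os.PathLike) -> FrameStack:
    """Read a frame directory written by :func:`write_frames` back to a stack."""
    directory = Path(directory)
    files = sorted(
        p for p in directory.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not files:
        raise VolumeIOError(f"no frame files in {directory}")
    frames = np.stack([np.asarray(Image.open(p), dtype=np.uint8) for p in files])
    ext = files[0].suffix.lower()
    encoding = LOSSLESS if ext == ".png" else "jpeg:q95"
    return FrameStack(frames=frames, encoding=encoding)


def filter_small_masks(
    masks: Iterable[LabelMask], min_voxels: int = SMALL_MASK_THRESHOLD
) -> tuple[list[LabelMask], list[LabelMask]]:
    """Partition masks into (kept, excluded) by voxel volume.

    Masks with ``voxel_volume <= min_voxels`` are excluded — the boundary
    case (exactly ``min_voxels`` voxels) is dropped, so the default keeps
    only masks strictly larger than 100 voxels.
    """
    kept: list[LabelMask] = []
    excluded: list[LabelMask] = []
    for m in masks:
        (excluded if m.voxel_volume <= min_voxels else kept).append(m)
    return kept, excluded
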