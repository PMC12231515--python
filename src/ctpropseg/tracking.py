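"""Bidirectional slice propagation through a pluggable segmenter backend.

A promptable video segmenter predicts one frame at a time in a single
direction, so a full 3D mask is assembled by running the tracker twice from
the prompted start slice — forward to the cranial end and in reverse to the
caudal end — and merging the two directional predictions by voxelwise
union.

The backend contract is deliberately small: given a FrameStack, a
PromptSet, and a direction, produce a binary mask for every frame from the
start slice to the corresponding volume end (inclusive).  Adapters for real
video segmenters (e.g. SAM 2's video predictor) plug in behind the same
contract; the package ships a deterministic intensity-band tracking backend
that exercises the whole pipeline at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Protocol, runtime_checkable

import numpy as np
from scipy import ndimage

from .prompting import PromptSet
from .volume_io import FrameStack

FORWARD = "forward"
REVERSE = "reverse"
DIRECTIONS = (FORWARD, REVERSE)

# Reference backend defaults: intensity-band half-margin (8-bit units),
# minimum fractional overlap for a component to be tracked, and in-plane
# connectivity of thresholded components.
DEFAULT_BAND_MARGIN = 10
DEFAULT_OVERLAP_FRACTION = 0.10
CONNECTIVITY_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connectivity


class TrackingError(RuntimeError):
    """Raised when propagation fails; message carries frame-index context."""


@runtime_checkable
class SegmenterBackend(Protocol):
    """Contract for promptable slice-propagation backends.

    ``propagate`` must return a mask (possibly empty) for every frame from
    ``prompts.start_z`` to the directional end, keyed by z.  Backends are
    deterministic for identical inputs unless they declare otherwise and
    accept a seed (the reference backend ignores it).
    """

    name: str

    def propagate(
        self,
        frames: FrameStack,
        prompts: PromptSet,
        direction: str,
        seed: int | None = None,
    ) -> dict[int, np.ndarray]: ...


@dataclass(frozen=True)
class PropagationResult:
    """A predicted binary 3D mask with full provenance."""

    scan_id: str
    organ: str
    level: str
    predicted: np.ndarray  # bool, volume shape
    backend: str
    include_negatives: bool
    coverage: Mapping[str, tuple[int, int]]  # direction -> inclusive z range

    def __post_init__(self) -> None:
        object.__setattr__(self, "predicted", np.asarray(self.predicted, dtype=bool))


def direction_range(direction: str, start_z: int, n_slices: int) -> list[int]:
    """Frame indices covered by one directional pass, start slice first."""
    if direction == FORWARD:
        return list(range(start_z, n_slices))
    if direction == REVERSE:
        return list(range(start_z, -1, -1))
    raise TrackingError(f"unknown direction {direction!r}")


def propagate(
    backend: SegmenterBackend,
    frames: FrameStack,
    prompts: PromptSet,
    direction: str,
    seed: int | None = None,
) -> dict[int, np.ndarray]:
    """Run one directional pass and validate the backend's coverage."""
    n = frames.n_frames
    if not 0 <= prompts.start_z < n:
        raise TrackingError(
            f"start slice {prompts.start_z} outside frame range [0, {n - 1}]"
        )
    try:
        masks = backend.propagate(frames, prompts, direction, seed=seed)
    except TrackingError:
        raise
    except Exception as exc:
        raise TrackingError(
            f"backend {backend.name!r} failed in {direction} pass from frame "
            f"{prompts.start_z}: {exc}"
        ) from exc
    expected = set(direction_range(direction, prompts.start_z, n))
    if set(masks) != expected:
        raise TrackingError(
            f"backend {backend.name!r} covered frames {sorted(masks)} but the "
            f"{direction} pass from {prompts.start_z} requires {sorted(expected)}"
        )
    for z, m in masks.items():
        if np.asarray(m).shape != frames.frame_shape:
            raise TrackingError(f"backend mask at frame {z} has wrong shape")
    return {z: np.asarray(m, dtype=bool) for z, m in masks.items()}


def merge_bidirectional(
    forward: Mapping[int, np.ndarray],
    reverse: Mapping[int, np.ndarray],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxelwise union of the two directional passes into one 3D mask.

    The start frame appears in both passes; union resolves any disagreement
    (possible only with stochastic backends).  Slices outside both passes
    are false.
    """
    merged = np.zeros(shape, dtype=bool)
    for masks in (forward, reverse):
        for z, m in masks.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != shape[1:]:
                raise TrackingError(
                    f"frame mask shape {m.shape} does not match volume slices {shape[1:]}"
                )
            merged[z] |= m
    return merged


class IntensityBandBackend:
    """Deterministic reference backend: intensity-band component tracking.

    On the start frame it thresholds to the band
    ``[min(I+) - margin, max(I+) + margin]`` where ``I+`` are the 8-bit
    intensities at the positive prompts, labels 8-connected components, and
    takes the union of components containing a positive prompt minus any
    component containing a negative prompt.  Each subsequent frame (in the
    pass direction) is thresholded with the same band, and a component is
    kept if its overlap with the previous frame's mask is at least
    ``max(1 pixel, overlap_fraction * component area)``.  Once a frame's
    mask is empty all remaining frames are empty.  Fully deterministic;
    the seed argument is ignored.
    """

    name = "intensity-band"

    def __init__(
        self,
        band_margin: int = DEFAULT_BAND_MARGIN,
        overlap_fraction: float = DEFAULT_OVERLAP_FRACTION,
    ) -> None:
        if band_margin < 0:
            raise ValueError("band_margin must be non-negative")
        if not 0 <= overlap_fraction <= 1:
            raise ValueError("overlap_fraction must be in [0, 1]")
        self.band_margin = int(band_margin)
        self.overlap_fraction = float(overlap_fraction)

    def _band(self, start_frame: np.ndarray, prompts: PromptSet) -> tuple[float, float]:
        pos = prompts.positives
        if not pos:
            raise TrackingError("reference backend requires at least one positive prompt")
        vals = np.array([int(start_frame[p.y, p.x]) for p in pos])
        return float(vals.min() - self.band_margin), float(vals.max() + self.band_margin)

    def _start_mask(self, frame: np.ndarray, prompts: PromptSet, band) -> np.ndarray:
        lo, hi = band
        in_band = (frame >= lo) & (frame <= hi)
        labels, _ = ndimage.label(in_band, structure=CONNECTIVITY_STRUCTURE)
        keep = {labels[p.y, p.x] for p in prompts.positives}
        drop = {labels[p.y, p.x] for p in prompts.negatives}
        keep = {lab for lab in keep - drop if lab != 0}
        if not keep:
            return np.zeros_like(in_band)
        return np.isin(labels, sorted(keep))

    def _next_mask(self, frame: np.ndarray, prev: np.ndarray, band) -> np.ndarray:
        lo, hi = band
        in_band = (frame >= lo) & (frame <= hi)
        labels, n = ndimage.label(in_band, structure=CONNECTIVITY_STRUCTURE)
        if n == 0:
            return np.zeros_like(in_band)
        sizes = np.bincount(labels.ravel(), minlength=n + 1)
        overlaps = np.bincount(labels[prev].ravel(), minlength=n + 1)
        required = np.maximum(1.0, self.overlap_fraction * sizes)
        keep = np.flatnonzero(overlaps >= required)
        keep = keep[keep != 0]
        if keep.size == 0:
            return np.zeros_like(in_band)
        return np.isin(labels, keep)

    def propagate(
        self,
        frames: FrameStack,
        prompts: PromptSet,
        direction: str,
        seed: int | None = None,
    ) -> dict[int, np.ndarray]:
        order = direction_range(direction, prompts.start_z, frames.n_frames)
        band = self._band(frames.frames[prompts.start_z], prompts)
        out: dict[int, np.ndarray] = {}
        prev: np.ndarray | None = None
        stopped = False
        for z in order:
            if prev is None:
                mask = self._start_mask(frames.frames[z], prompts, band)
            elif stopped:
                mask = np.zeros(frames.frame_shape, dtype=bool)
            else:
                mask = self._next_mask(frames.frames[z], prev, band)
            if not mask.any():
                stopped = True
            out[z] = mask
            prev = mask
        return out


def run_bidirectional(
    backend: SegmenterBackend,
    frames: FrameStack,
    prompts: PromptSet,
    scan_id: str = "",
    seed: int | None = None,
) -> PropagationResult:
    """Propagate in both directions from the start slice and merge.

    The identical prompt set is supplied to both directional passes.
    """
    n = frames.n_frames
    fwd = propagate(backend, frames, prompts, FORWARD, seed=seed)
    rev = propagate(backend, frames, prompts, REVERSE, seed=seed)
    shape = (n, *frames.frame_shape)
    merged = merge_bidirectional(fwd, rev, shape)
    return PropagationResult(
        scan_id=scan_id,
        organ=prompts.organ,
        level=prompts.level,
        predicted=merged,
        backend=backend.name,
        include_negatives=prompts.include_negatives,
        coverage={
            FORWARD: (prompts.start_z, n - 1),
            REVERSE: (0, prompts.start_z),
        },
    )


_BACKEND_FACTORIES: dict[str, Callable[..., SegmenterBackend]] = {
    IntensityBandBackend.name: IntensityBandBackend,
}


def register_backend(name: str, factory: Callable[..., SegmenterBackend]) -> None:
    """Register a backend factory for discovery by name (plugin hook)."""
    _BACKEND_FACTORIES[name] = factory


def get_backend(name: str, **params) -> SegmenterBackend:
    """Instantiate a registered backend by name with keyword parameters."""
    try:
        factory = _BACKEND_FACTORIES[name]
    except KeyError:
        raise TrackingError(
            f"unknown backend {name!r}; registered: {sorted(_BACKEND_FACTORIES)}"
        ) from None
    return factory(**params)
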