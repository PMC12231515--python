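"""Automatic point-prompt generation on axial slices.

Propagation is started from one of three anatomical levels of each organ —
the 25th (caudal), 50th (mid), or 75th (cranial) percentile of its occupied
axial slices — and seeded with up to five positive point prompts drawn
uniformly from inside the organ's cross-section plus up to five negative
prompts drawn from a ring 2–3 pixels outside it (the immediate 1-pixel
margin is excluded).  All sampling is a pure function of its inputs and a
seed, so identical inputs reproduce identical prompt sets.

The "2–3 voxels outside" ring is measured with the in-plane Chebyshev
(L-infinity) distance, i.e. the ring is the set difference between a
dilation by a 7x7 square and a dilation by a 3x3 square of the organ's
cross-section; an isolated interior pixel therefore has exactly 40 ring
candidates.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volume_io import LabelMask

POSITIVE = "positive"
NEGATIVE = "negative"

N_POSITIVE_PROMPTS = 5
N_NEGATIVE_PROMPTS = 5

# Ring geometry: candidates at Chebyshev distance in [RING_INNER, RING_OUTER]
# from the mask cross-section; distance 1 is the excluded margin.
RING_INNER = 2
RING_OUTER = 3

LEVELS = ("caudal", "mid", "cranial")
LEVEL_PERCENTILE = {"caudal": 25, "mid": 50, "cranial": 75}


class PromptError(ValueError):
    """Raised for empty masks/slices or degenerate prompt geometry."""


class DegenerateGeometryError(PromptError):
    """The negative-prompt candidate ring is empty (mask fills the frame)."""


@dataclass(frozen=True)
class PointPrompt:
    """A single point prompt: slice index, in-plane pixel position, polarity."""

    z: int
    x: int
    y: int
    polarity: str

    def __post_init__(self) -> None:
        if self.polarity not in (POSITIVE, NEGATIVE):
            raise PromptError(f"invalid polarity {self.polarity!r}")


@dataclass(frozen=True)
class PromptSet:
    """Start slice plus the point prompts for one (organ, level) run."""

    organ: str
    level: str
    start_z: int
    prompts: tuple[PointPrompt, ...]
    seed: int
    include_negatives: bool

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise PromptError(f"invalid level {self.level!r}")
        if any(p.z != self.start_z for p in self.prompts):
            raise PromptError("all prompts must lie on the start slice")
        if not self.include_negatives and self.negatives:
            raise PromptError("negative prompts present with include_negatives=False")
        if len(self.positives) > N_POSITIVE_PROMPTS:
            raise PromptError("too many positive prompts")
        if len(self.negatives) > N_NEGATIVE_PROMPTS:
            raise PromptError("too many negative prompts")

    @property
    def positives(self) -> tuple[PointPrompt, ...]:
        return tuple(p for p in self.prompts if p.polarity == POSITIVE)

    @property
    def negatives(self) -> tuple[PointPrompt, ...]:
        return tuple(p for p in self.prompts if p.polarity == NEGATIVE)


def derive_subseed(*parts) -> int:
    """Stable sub-seed (< 2**31) from a tuple of seed components.

    Hash-based so per-organ results are independent of processing order.
    """
    key = "|".join(str(p) for p in parts)
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def occupied_slices(mask: LabelMask) -> np.ndarray:
    """Sorted unique z indices containing at least one true voxel."""
    occ = np.flatnonzero(mask.mask.any(axis=(1, 2)))
    if occ.size == 0:
        raise PromptError(f"mask {mask.organ!r} is empty")
    return occ


def percentile_slice(mask: LabelMask, p: float) -> int:
    """Nearest-rank percentile over the organ's occupied slices.

    Returns the r-th smallest occupied z index with ``r = ceil(p/100 * n)``
    (n = number of occupied slices), so the result is always an occupied
    slice and is monotone in p.
    """
    if not 0 < p <= 100:
        raise PromptError(f"percentile must be in (0, 100], got {p}")
    occ = occupied_slices(mask)
    r = max(1, math.ceil(p / 100.0 * occ.size))
    return int(occ[r - 1])


def _slice_or_error(mask: LabelMask, z: int) -> np.ndarray:
    section = mask.mask[z]
    if not section.any():
        raise PromptError(f"mask {mask.organ!r} has no pixels on slice {z}")
    return section


def sample_positive_prompts(
    mask: LabelMask, z: int, k: int = N_POSITIVE_PROMPTS, seed: int = 0
) -> list[PointPrompt]:
    """Sample up to k distinct pixels uniformly from inside the mask on slice z."""
    section = _slice_or_error(mask, z)
    ys, xs = np.nonzero(section)
    rng = np.random.default_rng(seed)
    take = min(k, ys.size)
    idx = rng.choice(ys.size, size=take, replace=False)
    return [
        PointPrompt(z=int(z), x=int(xs[i]), y=int(ys[i]), polarity=POSITIVE)
        for i in idx
    ]


def negative_candidate_region(section: np.ndarray) -> np.ndarray:
    """Boolean region at in-plane Chebyshev distance 2–3 from the cross-section."""
    square = np.ones((3, 3), dtype=bool)  # one iteration = Chebyshev distance 1
    outer = ndimage.binary_dilation(section, structure=square, iterations=RING_OUTER)
    margin = ndimage.binary_dilation(section, structure=square, iterations=RING_INNER - 1)
    return outer & ~margin


def sample_negative_prompts(
    mask: LabelMask, z: int, k: int = N_NEGATIVE_PROMPTS, seed: int = 0
) -> list[PointPrompt]:
    """Sample up to k pixels uniformly from the 2–3 pixel ring outside the mask."""
    section = _slice_or_error(mask, z)
    ring = negative_candidate_region(section)
    ys, xs = np.nonzero(ring)
    if ys.size == 0:
        raise DegenerateGeometryError(
            f"mask {mask.organ!r} fills slice {z}: no negative candidates"
        )
    rng = np.random.default_rng(seed)
    take = min(k, ys.size)
    idx = rng.choice(ys.size, size=take, replace=False)
    return [
        PointPrompt(z=int(z), x=int(xs[i]), y=int(ys[i]), polarity=NEGATIVE)
        for i in idx
    ]


def build_prompt_set(
    mask: LabelMask,
    level: str,
    seed: int,
    include_negatives: bool = True,
    scan_id: str = "",
    k_positive: int = N_POSITIVE_PROMPTS,
    k_negative: int = N_NEGATIVE_PROMPTS,
) -> PromptSet:
    """Compose start-slice selection and prompt sampling for one run.

    The start slice is the level's percentile slice (25/50/75 for
    caudal/mid/cranial) and is independent of the seed.  Positive and
    negative sampling use sub-seeds derived from
    ``(seed, scan_id, organ, level, polarity)`` so results do not depend on
    processing order.
    """
    if level not in LEVELS:
        raise PromptError(f"invalid level {level!r}; expected one of {LEVELS}")
    start_z = percentile_slice(mask, LEVEL_PERCENTILE[level])
    pos_seed = derive_subseed(seed, scan_id, mask.organ, level, POSITIVE)
    prompts: list[PointPrompt] = sample_positive_prompts(
        mask, start_z, k=k_positive, seed=pos_seed
    )
    if include_negatives:
        neg_seed = derive_subseed(seed, scan_id, mask.organ, level, NEGATIVE)
        prompts += sample_negative_prompts(mask, start_z, k=k_negative, seed=neg_seed)
    return PromptSet(
        organ=mask.organ,
        level=level,
        start_z=start_z,
        prompts=tuple(prompts),
        seed=seed,
        include_negatives=include_negatives,
    )


def prompt_set_to_json(ps: PromptSet) -> str:
    """Serialize a PromptSet to the JSON document backend adapters consume."""
    doc = {
        "organ": ps.organ,
        "level": ps.level,
        "start_z": ps.start_z,
        "seed": ps.seed,
        "include_negatives": ps.include_negatives,
        "prompts": [
            {"z": p.z, "x": p.x, "y": p.y, "polarity": p.polarity} for p in ps.prompts
        ],
    }
    return json.dumps(doc, indent=2, sort_keys=True)


def prompt_set_from_json(text: str) -> PromptSet:
    doc = json.loads(text)
    return PromptSet(
        organ=doc["organ"],
        level=doc["level"],
        start_z=int(doc["start_z"]),
        prompts=tuple(
            PointPrompt(z=int(p["z"]), x=int(p["x"]), y=int(p["y"]), polarity=p["polarity"])
            for p in doc["prompts"]
        ),
        seed=int(doc["seed"]),
        include_negatives=bool(doc["include_negatives"]),
    )
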