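"""Seeded 3D CT phantoms with multi-organ ground truth.

The generator emulates the statistical structure the pipeline assumes of
real abdominal CT: a Hounsfield-unit voxel grid with ~8 disjoint "organ"
regions spanning orders of magnitude in volume (the default spec keeps the
largest/smallest volume ratio above 100, echoing the liver-to-adrenal ratio
of real anatomy at reduced grid scale), soft-tissue organ intensities that
a WL 50 / WW 400 window renders clearly visible against background, and a
per-organ binary ground-truth mask for every region.

Organs are unions of analytic primitives (ellipsoids, optionally boxes for
constructed leakage cases) so rasterized volumes are checkable against
closed forms.  Named variants provide the study conditions for planted
effects:

* ``default_abdomen_spec`` — the base 96x96x96 eight-organ phantom.
* ``cranial_fade_spec`` — the same anatomy with organ-background contrast
  fading linearly over the cranial half of each organ, planting a
  caudal-better-than-cranial ordering of start-level difficulty.
* ``touching_blobs_spec`` — a two-lobed target organ whose small lobe
  touches a long same-intensity distractor "vessel", so the thresholded
  start-frame component containing that lobe also contains distractor
  tissue; negative prompts falling inside the distractor excise the leaky
  component, reproducing the mechanism by which negative prompts rescue
  boundary leakage.

Everything is a pure function of (spec, seed): regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .prompting import derive_subseed
from .volume_io import CTVolume, LabelMask, write_label_volume, write_volume

DEFAULT_GRID = (96, 96, 96)
DEFAULT_BACKGROUND_HU = -50.0
DEFAULT_NOISE_HU_SD = 8.0

ELLIPSOID = "ellipsoid"
BOX = "box"

MAX_JITTER_RETRIES = 8


class PhantomError(ValueError):
    """Raised for invalid phantom specs (overlaps, out-of-grid organs)."""


@dataclass(frozen=True)
class Lobe:
    """One analytic primitive of an organ: ellipsoid or axis-aligned box."""

    center: tuple[float, float, float]  # (z, y, x)
    semi_axes: tuple[float, float, float]  # (z, y, x) half-extents, voxels
    shape: str = ELLIPSOID

    def __post_init__(self) -> None:
        if self.shape not in (ELLIPSOID, BOX):
            raise PhantomError(f"unknown lobe shape {self.shape!r}")
        if any(s <= 0 for s in self.semi_axes):
            raise PhantomError("semi-axes must be positive")


@dataclass(frozen=True)
class OrganSpec:
    """A named intensity region: one or more lobes sharing an HU mean.

    Non-target organs (``is_target=False``) are rendered into the intensity
    volume — e.g. distractor vessels for leakage scenarios — but excluded
    from the ground-truth mask list.
    """

    name: str
    lobes: tuple[Lobe, ...]
    hu_mean: float
    hu_sd: float = 0.0
    is_target: bool = True


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of one phantom scan; deterministic given its seed."""

    grid: tuple[int, int, int] = DEFAULT_GRID
    background_hu_mean: float = DEFAULT_BACKGROUND_HU
    background_hu_sd: float = 0.0
    noise_hu_sd: float = DEFAULT_NOISE_HU_SD
    organs: tuple[OrganSpec, ...] = ()
    # Contrast fade over the cranial part of each organ: multiplier is 1.0
    # up to fade_start (fraction of the organ's z-extent) then falls
    # linearly to fade_floor at the cranial end.  fade_floor=1.0 disables.
    fade_start: float = 0.5
    fade_floor: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(isinstance(g, (int, np.integer)) and g > 0 for g in self.grid):
            raise PhantomError(f"invalid grid {self.grid}")
        if self.noise_hu_sd < 0 or self.background_hu_sd < 0:
            raise PhantomError("noise SDs must be non-negative")
        if not 0.0 <= self.fade_start <= 1.0 or not 0.0 <= self.fade_floor <= 1.0:
            raise PhantomError("fade parameters must lie in [0, 1]")


@dataclass(frozen=True)
class PhantomStudy:
    """A generated phantom: CT volume, target masks, and the generating spec."""

    volume: CTVolume
    masks: tuple[LabelMask, ...]
    spec: PhantomSpec


def _rasterize_lobe(grid: tuple[int, int, int], lobe: Lobe) -> np.ndarray:
    zz, yy, xx = np.ogrid[: grid[0], : grid[1], : grid[2]]
    (cz, cy, cx), (az, ay, ax) = lobe.center, lobe.semi_axes
    if lobe.shape == ELLIPSOID:
        return ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + (
            (xx - cx) / ax
        ) ** 2 <= 1.0
    return (
        (np.abs(zz - cz) <= az) & (np.abs(yy - cy) <= ay) & (np.abs(xx - cx) <= ax)
    )


def rasterize_organ(grid: tuple[int, int, int], organ: OrganSpec) -> np.ndarray:
    mask = np.zeros(grid, dtype=bool)
    for lobe in organ.lobes:
        for c, a, g in zip(lobe.center, lobe.semi_axes, grid):
            if c - a < 0 or c + a > g - 1:
                raise PhantomError(
                    f"organ {organ.name!r} lobe extends outside the {g}-voxel grid axis"
                )
        mask |= _rasterize_lobe(grid, lobe)
    return mask


def _fade_multiplier(mask: np.ndarray, fade_start: float, fade_floor: float) -> np.ndarray:
    """Per-slice contrast multiplier over the organ's occupied z-extent."""
    occ = np.flatnonzero(mask.any(axis=(1, 2)))
    z0, z1 = int(occ[0]), int(occ[-1])
    mult = np.ones(mask.shape[0])
    if fade_floor >= 1.0 or z1 == z0:
        return mult
    frac = (np.arange(z0, z1 + 1) - z0) / (z1 - z0)
    m = np.ones_like(frac)
    fading = frac > fade_start
    m[fading] = 1.0 - (frac[fading] - fade_start) / (1.0 - fade_start) * (
        1.0 - fade_floor
    )
    mult[z0 : z1 + 1] = m
    return mult


def generate_phantom(spec: PhantomSpec, scan_id: str = "phantom-000") -> PhantomStudy:
    """Rasterize a PhantomSpec into a CT volume plus ground-truth masks.

    Organ regions must be pairwise disjoint after rasterization (touching
    is allowed, overlap is an error naming the colliding pair).  Intensity
    = background field, overwritten inside each organ by the organ's HU
    draw (contrast optionally faded cranially), plus global voxel noise.
    All random draws come from one generator seeded by ``spec.seed`` in a
    fixed order, so regeneration is bit-identical.
    """
    if not spec.organs:
        raise PhantomError("spec contains no organs")
    grid = spec.grid
    rasters: list[tuple[OrganSpec, np.ndarray]] = [
        (o, rasterize_organ(grid, o)) for o in spec.organs
    ]
    for i in range(len(rasters)):
        for j in range(i + 1, len(rasters)):
            if np.any(rasters[i][1] & rasters[j][1]):
                raise PhantomError(
                    f"organs {rasters[i][0].name!r} and {rasters[j][0].name!r} "
                    "overlap after rasterization"
                )

    rng = np.random.default_rng(spec.seed)
    intensities = np.full(grid, spec.background_hu_mean, dtype=np.float64)
    if spec.background_hu_sd > 0:
        intensities += rng.normal(0.0, spec.background_hu_sd, size=grid)
    for organ, mask in rasters:
        contrast = organ.hu_mean - spec.background_hu_mean
        mult = _fade_multiplier(mask, spec.fade_start, spec.fade_floor)
        values = spec.background_hu_mean + contrast * mult[:, None, None]
        region = np.broadcast_to(values, grid)[mask]
        if organ.hu_sd > 0:
            region = region + rng.normal(0.0, organ.hu_sd, size=region.shape)
        intensities[mask] = region
    if spec.noise_hu_sd > 0:
        intensities += rng.normal(0.0, spec.noise_hu_sd, size=grid)

    volume = CTVolume(
        intensities=intensities, scan_id=scan_id, provenance=f"phantom;seed={spec.seed}"
    )
    masks = tuple(
        LabelMask(organ=o.name, mask=m) for o, m in rasters if o.is_target
    )
    return PhantomStudy(volume=volume, masks=masks, spec=spec)


# ----------------------------------------------------------- named specs


def default_abdomen_spec(seed: int = 0) -> PhantomSpec:
    """The base "abdomen-small" phantom: 96^3 grid, eight disjoint organs.

    Semi-axes are scaled so relative organ volumes echo real anatomy
    (liver largest, paired adrenals smallest, ratio > 100x).  HU means sit
    inside the WL 50 / WW 400 window but are not claimed to be anatomical:
    what matters for the tracker is organ-background contrast, and the
    small organs (pancreas, gallbladder, adrenals) are deliberately given
    low contrast so they exhibit the boundary-dropout and leakage failure
    modes that small, poorly contrasted structures show in real CT —
    producing the size-graded difficulty the evaluation harness expects.
    """

    def organ(name, center, semi, hu):
        return OrganSpec(name=name, lobes=(Lobe(center=center, semi_axes=semi),), hu_mean=hu)

    return PhantomSpec(
        grid=(96, 96, 96),
        organs=(
            organ("liver", (48, 40, 60), (18, 22, 24), 120.0),
            organ("spleen", (50, 40, 18), (10, 12, 12), 100.0),
            organ("right_kidney", (34, 74, 62), (9, 9, 8), 90.0),
            organ("left_kidney", (36, 74, 24), (9, 9, 8), 95.0),
            organ("pancreas", (24, 60, 30), (5, 6, 14), -8.0),
            organ("gallbladder", (22, 40, 55), (6, 5, 5), -12.0),
            organ("right_adrenal", (52, 74, 64), (4, 3, 3), -17.0),
            organ("left_adrenal", (52, 74, 24), (4, 3, 3), -15.0),
        ),
        seed=seed,
    )


def cranial_fade_spec(seed: int = 0, fade_floor: float = 0.3) -> PhantomSpec:
    """Default anatomy with organ contrast fading over the cranial half.

    Plants a difficulty gradient: propagation started cranially anchors its
    intensity model on low-contrast slices, so cranial-approach accuracy
    drops below caudal-approach accuracy.
    """
    return replace(default_abdomen_spec(seed), fade_start=0.5, fade_floor=fade_floor)


def touching_blobs_spec(seed: int = 0) -> PhantomSpec:
    """Leakage scenario: a two-lobed target touching a same-intensity vessel.

    The target "blob" has a large main lobe and a smaller parallel lobe
    separated in-plane by a 1-pixel margin (two components per axial
    slice).  A long distractor "vessel" of identical HU runs edge-adjacent
    to the small lobe, so any intensity-based component containing the
    small lobe also contains the vessel.  Box primitives keep the contact
    geometry constant along z.
    """
    return PhantomSpec(
        grid=(64, 64, 64),
        organs=(
            OrganSpec(
                name="blob",
                lobes=(
                    Lobe(center=(32, 32, 24), semi_axes=(12, 10, 10), shape=BOX),
                    Lobe(center=(32, 32, 41), semi_axes=(12, 12, 5), shape=BOX),
                ),
                hu_mean=120.0,
            ),
            OrganSpec(
                name="vessel",
                lobes=(Lobe(center=(32, 32, 53), semi_axes=(28, 12, 6), shape=BOX),),
                hu_mean=120.0,
                is_target=False,
            ),
        ),
        seed=seed,
    )


NAMED_SPECS = {
    "default": default_abdomen_spec,
    "cranial-fade": cranial_fade_spec,
    "touching-blobs": touching_blobs_spec,
}


# --------------------------------------------------------------- cohorts


@dataclass(frozen=True)
class CohortJitter:
    """Per-scan variation applied to a base spec.

    centroid: max |integer| voxel shift per axis; axes: max fractional
    change of each semi-axis; hu: max |HU| shift of each organ mean.
    """

    centroid: int = 2
    axes: float = 0.08
    hu: float = 5.0


def _jitter_spec(base: PhantomSpec, jitter: CohortJitter, seed: int) -> PhantomSpec:
    rng = np.random.default_rng(seed)
    organs = []
    for o in base.organs:
        lobes = []
        for lb in o.lobes:
            shift = rng.integers(-jitter.centroid, jitter.centroid + 1, size=3)
            scale = rng.uniform(1.0 - jitter.axes, 1.0 + jitter.axes, size=3)
            lobes.append(
                Lobe(
                    center=tuple(float(c + s) for c, s in zip(lb.center, shift)),
                    semi_axes=tuple(float(a * f) for a, f in zip(lb.semi_axes, scale)),
                    shape=lb.shape,
                )
            )
        dhu = float(rng.uniform(-jitter.hu, jitter.hu))
        organs.append(replace(o, lobes=tuple(lobes), hu_mean=o.hu_mean + dhu))
    return replace(base, organs=tuple(organs), seed=seed)


def generate_cohort(
    n_scans: int,
    base_spec: PhantomSpec | None = None,
    jitter: CohortJitter | None = None,
    seed: int = 0,
) -> list[PhantomStudy]:
    """Generate a cohort of jittered phantoms from one base spec.

    Each scan uses a sub-seed derived from the master seed and scan index,
    so results are independent of generation order.  A scan whose jitter
    produces overlapping or out-of-grid organs is retried with a fresh
    sub-seed up to a fixed bound, then the cohort fails loudly.
    """
    if n_scans < 1:
        raise PhantomError("n_scans must be >= 1")
    base = base_spec if base_spec is not None else default_abdomen_spec()
    jit = jitter if jitter is not None else CohortJitter()
    studies: list[PhantomStudy] = []
    for i in range(n_scans):
        last_error: Exception | None = None
        for attempt in range(MAX_JITTER_RETRIES):
            sub = derive_subseed(seed, "scan", i, "attempt", attempt)
            spec_i = _jitter_spec(base, jit, sub)
            try:
                studies.append(generate_phantom(spec_i, scan_id=f"phantom-{i:03d}"))
                break
            except PhantomError as exc:
                last_error = exc
        else:
            raise PhantomError(
                f"scan {i}: no valid jitter after {MAX_JITTER_RETRIES} attempts "
                f"(last error: {last_error})"
            )
    return studies


def write_study(study: PhantomStudy, directory) -> dict[str, int]:
    """Write a phantom as a NIfTI volume + integer label map pair.

    Returns the organ-name -> label map; files are named
    ``<scan_id>_ct.nii.gz`` and ``<scan_id>_labels.nii.gz``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sid = study.volume.scan_id
    write_volume(study.volume, directory / f"{sid}_ct.nii.gz")
    return write_label_volume(list(study.masks), directory / f"{sid}_labels.nii.gz")
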