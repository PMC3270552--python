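"""Synthetic MR/US phantom pairs with known ground-truth geometry.

The generator emulates the appearance that drives the registration method,
not acoustic physics:

* an MR-like volume: bright smooth tissue background containing dark tubular
  valleys (sulci) with smooth random curvature, an optional dark mid-plane
  sheet (cerebral falx), and a hypointense lesion, plus additive Gaussian
  noise;
* a US-like volume: bright at the same liquid interfaces (dilated valley
  centerlines) and homogeneously bright inside the lesion, dark elsewhere,
  corrupted by multiplicative unit-mean speckle, an optional acoustic-shadow
  region and a limited field of view.

The US simulation uses the ground-truth geometry directly (not the MR valley
detector), so feature extraction and registration remain independently
testable.  All generation is reproducible from the seed alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .geometry import RigidTransform
from .volume_io import BinaryMask, Volume3D, resample

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "RegistrationFixture",
    "generate_mr_phantom",
    "simulate_us_from_mr",
    "make_registration_fixture",
    "artifact_boxes",
]

Box = tuple  # ((i0, i1), (j0, j1), (k0, k1)) voxel index bounds, half-open


@dataclass
class PhantomSpec:
    """Geometry, structure and noise settings of a synthetic phantom.

    Intensities are arbitrary MR-like units; the background tissue level is
    100 with valleys dipping by ``valley_depth`` and a hypointense lesion at
    ``lesion_mr_level``.  ``us_speckle_var`` is the variance of the unit-mean
    multiplicative speckle (gamma) field.
    """

    shape: tuple = (64, 64, 64)
    spacing: tuple = (1.0, 1.0, 1.0)
    n_sulci: int = 6
    falx: bool = True
    lesion: bool = True
    lesion_center: tuple | None = None  # world mm; None = auto offset from center
    lesion_radius: float = 8.0
    lesion_mr_level: float = 40.0
    lesion_echo: float = 1.0
    background: float = 100.0
    valley_depth: float = 60.0
    valley_radius_mm: float = 1.5
    mr_noise_sigma: float = 2.0
    us_speckle_var: float = 0.25
    us_background_echo: float = 0.15
    interface_dilation: int = 1
    shadow: Box | None = None
    fov: Box | None = None
    seed: int = 0

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or min(shape) < 8:
            raise ValidationError(f"phantom shape must be 3D with sides >= 8, got {shape}")
        self.shape = shape
        self.spacing = tuple(float(s) for s in self.spacing)
        if min(self.spacing) <= 0:
            raise ValidationError("spacing must be strictly positive")
        if self.lesion:
            c = np.asarray(self.resolved_lesion_center())
            hi = (np.array(shape) - 1) * np.array(self.spacing)
            if np.any(c - self.lesion_radius < 0) or np.any(c + self.lesion_radius > hi):
                raise ValidationError("lesion does not fit inside the volume")
        for name, box in (("shadow", self.shadow), ("fov", self.fov)):
            if box is None:
                continue
            if len(box) != 3 or any(
                not (0 <= lo < hi <= n) for (lo, hi), n in zip(box, shape)
            ):
                raise ValidationError(f"{name} box {box} is empty or outside the volume")

    def resolved_lesion_center(self) -> tuple:
        if self.lesion_center is not None:
            return tuple(float(c) for c in self.lesion_center)
        extent = (np.array(self.shape) - 1) * np.array(self.spacing)
        # off-center placement scaled to the volume (≈ (+8, -6, +5) mm at 64³/1 mm)
        return tuple(extent / 2.0 + np.array([0.125, -0.094, 0.078]) * extent)


@dataclass
class PhantomTruth:
    """Ground-truth masks and transform accompanying a generated phantom."""

    valley_mask: BinaryMask  # sulci centerlines + falx mid-plane
    lesion_mask: BinaryMask
    shadow_mask: BinaryMask
    fov_mask: BinaryMask
    transform: RigidTransform = field(default_factory=RigidTransform.identity)

    def masks(self):
        return (self.valley_mask, self.lesion_mask, self.shadow_mask, self.fov_mask)


def _box_mask(shape, box: Box | None, default: bool) -> np.ndarray:
    m = np.full(shape, default, dtype=bool) if box is None else np.zeros(shape, dtype=bool)
    if box is not None:
        (i0, i1), (j0, j1), (k0, k1) = box
        m[i0:i1, j0:j1, k0:k1] = True
    return m


def _rasterize_sulci(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smoothly curved tubes: one axis runs the volume, the others undulate."""
    mask = np.zeros(spec.shape, dtype=bool)
    shape = np.array(spec.shape)
    for _ in range(spec.n_sulci):
        axis = int(rng.integers(0, 3))
        others = [a for a in range(3) if a != axis]
        n = shape[axis]
        t = np.linspace(0, n - 1, 4 * n)
        coords = np.empty((3, t.size))
        coords[axis] = t
        for o in others:
            base = rng.uniform(0.2, 0.8) * (shape[o] - 1)
            amp = rng.uniform(2.0, 6.0)
            freq = rng.uniform(0.5, 1.5)
            phase = rng.uniform(0, 2 * np.pi)
            coords[o] = base + amp * np.sin(2 * np.pi * freq * t / n + phase)
        idx = np.round(coords).astype(int)
        inside = np.all((idx >= 0) & (idx < shape[:, None]), axis=0)
        mask[tuple(idx[:, inside])] = True
    return mask


def generate_mr_phantom(spec: PhantomSpec) -> tuple[Volume3D, PhantomTruth]:
    """Generate the MR-like phantom volume and its ground-truth masks."""
    rng = np.random.default_rng([int(spec.seed), 0])
    shape, spacing = spec.shape, np.array(spec.spacing)

    valley = _rasterize_sulci(spec, rng)
    if spec.falx:
        valley[shape[0] // 2, :, :] = True

    if valley.any():
        dist = ndimage.distance_transform_edt(~valley, sampling=spacing)
        profile = np.exp(-(dist**2) / (2.0 * spec.valley_radius_mm**2))
    else:
        profile = np.zeros(shape)
    v = spec.background - spec.valley_depth * profile

    lesion = np.zeros(shape, dtype=bool)
    if spec.lesion:
        center = np.asarray(spec.resolved_lesion_center())
        grids = np.meshgrid(
            *(np.arange(n) * s for n, s in zip(shape, spacing)), indexing="ij"
        )
        r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
        lesion = r2 < spec.lesion_radius**2
        v[lesion] = spec.lesion_mr_level

    v = ndimage.gaussian_filter(v, sigma=0.6, mode="nearest")
    if spec.mr_noise_sigma > 0:
        v = v + rng.normal(0.0, spec.mr_noise_sigma, shape)

    geom = dict(spacing=spacing.copy(), origin=np.zeros(3))
    truth = PhantomTruth(
        valley_mask=BinaryMask(data=valley.astype(float), **geom),
        lesion_mask=BinaryMask(data=lesion.astype(float), **geom),
        shadow_mask=BinaryMask(data=_box_mask(shape, spec.shadow, False).astype(float), **geom),
        fov_mask=BinaryMask(data=_box_mask(shape, spec.fov, True).astype(float), **geom),
    )
    return Volume3D(data=v, **geom), truth


def simulate_us_from_mr(
    mr_truth: PhantomTruth, spec: PhantomSpec, T_true: RigidTransform | None = None
) -> Volume3D:
    """Simulate the US-like volume from ground-truth geometry.

    The echogenicity field is bright at dilated valley centerlines and inside
    the lesion; it is placed in the (possibly misaligned) US frame via
    ``T_true`` (US voxel X shows tissue at T_true(X) in MR space), multiplied
    by unit-mean gamma speckle, zeroed in the shadow region, and cropped to
    the field-of-view box.
    """
    T_true = T_true or RigidTransform.identity()
    rng = np.random.default_rng([int(spec.seed), 1])
    valley = mr_truth.valley_mask.bool_data
    lesion = mr_truth.lesion_mask.bool_data

    interfaces = valley
    if spec.interface_dilation > 0:
        interfaces = ndimage.binary_dilation(valley, iterations=spec.interface_dilation)
    echo = np.full(spec.shape, spec.us_background_echo)
    echo[interfaces] = 1.0
    echo[lesion] = np.maximum(echo[lesion], spec.lesion_echo)
    echo = ndimage.gaussian_filter(echo, sigma=0.7, mode="nearest")

    geom = mr_truth.valley_mask
    echo_vol = Volume3D(data=echo, spacing=geom.spacing.copy(), origin=geom.origin.copy())
    us = resample(echo_vol, T_true, reference=geom, fill=0.0)

    data = us.data
    if spec.us_speckle_var > 0:
        k = 1.0 / spec.us_speckle_var  # gamma(k, 1/k): mean 1, variance 1/k
        data = data * rng.gamma(k, 1.0 / k, spec.shape)
    data = data * _box_mask(spec.shape, spec.fov, True)
    data[_box_mask(spec.shape, spec.shadow, False)] = 0.0
    return Volume3D(data=data, spacing=geom.spacing.copy(), origin=geom.origin.copy())


def artifact_boxes(shape=(64, 64, 64)) -> dict:
    """Canonical artifact settings: an acoustic-shadow slab inside a cropped
    field of view.

    The field-of-view box trims every face (strongest along +z), keeping
    roughly 57% of the volume; the shadow slab zeroes roughly 8% of the
    remaining field of view.
    """
    s0, s1, s2 = (int(n) for n in shape)
    fov = ((4, s0 - 4), (4, s1 - 4), (4, s2 - 12))
    shadow = ((s0 // 4, 3 * s0 // 4), (s1 // 4, 3 * s1 // 4), (int(0.62 * s2), s2 - 12))
    return {"fov": fov, "shadow": shadow}


@dataclass
class RegistrationFixture:
    """Everything needed to run the full pipeline and score recovery."""

    mr: Volume3D
    us: Volume3D
    lesion_mask: BinaryMask
    brain_mask: BinaryMask
    truth: PhantomTruth
    spec: PhantomSpec

    @property
    def t_true(self) -> RigidTransform:
        return self.truth.transform


def make_registration_fixture(
    seed: int,
    t_true: RigidTransform | None = None,
    **spec_overrides,
) -> RegistrationFixture:
    """One call yields a full phantom bundle (default 64³ voxels at 1 mm)."""
    spec = PhantomSpec(seed=int(seed), **spec_overrides)
    mr, truth = generate_mr_phantom(spec)
    t_true = t_true or RigidTransform.identity(center=mr.center_world)
    us = simulate_us_from_mr(truth, spec, t_true)
    truth.transform = t_true
    brain = BinaryMask(
        data=np.ones(spec.shape), spacing=mr.spacing.copy(), origin=mr.origin.copy()
    )
    return RegistrationFixture(
        mr=mr, us=us, lesion_mask=truth.lesion_mask, brain_mask=brain, truth=truth, spec=spec
    )
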