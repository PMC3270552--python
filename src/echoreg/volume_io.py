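"""3D scalar volumes with physical geometry: NIfTI I/O, rescaling, resampling.

Conventions
-----------
* A :class:`Volume3D` carries a 3D ``data`` array indexed ``[i, j, k]`` along
  the world x, y, z axes, voxel ``spacing`` in mm, and the world ``origin``:
  the position (mm) of the *center* of voxel (0, 0, 0).  World coordinate of
  index ``(i, j, k)`` is ``origin + index * spacing``.  Grids are axis-aligned
  and right-handed; oblique orientations are not supported.
* All resampling is trilinear with fill value 0 outside the source support
  (probability zero outside the field of view).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, ValidationError
from .geometry import RigidTransform

__all__ = [
    "Volume3D",
    "BinaryMask",
    "ProbabilityMap",
    "read_volume",
    "write_volume",
    "minmax_rescale",
    "downsample",
    "resample",
]


@dataclass
class Volume3D:
    """A 3D scalar grid with physical spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: np.ndarray = field(default=(1.0, 1.0, 1.0))
    origin: np.ndarray = field(default=(0.0, 0.0, 0.0))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(
                f"data must be 3D with each dimension >= 1, got shape {self.data.shape}"
            )
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not np.all(self.spacing > 0):
            raise ValidationError(f"spacing must be strictly positive, got {self.spacing}")
        if not np.all(np.isfinite(self.spacing)) or not np.all(np.isfinite(self.origin)):
            raise ValidationError("spacing and origin must be finite")

    # ------------------------------------------------------------------ #
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def center_world(self) -> np.ndarray:
        """World position of the volume's physical center."""
        return self.origin + (np.array(self.shape) - 1) / 2.0 * self.spacing

    def index_to_world(self, idx) -> np.ndarray:
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, pts) -> np.ndarray:
        return (np.asarray(pts, dtype=float) - self.origin) / self.spacing

    def grid_world_points(self) -> np.ndarray:
        """World coordinates of all voxel centers, as an (N, 3) array."""
        grids = np.meshgrid(
            *(np.arange(n) * s + o for n, s, o in zip(self.shape, self.spacing, self.origin)),
            indexing="ij",
        )
        return np.stack([g.ravel() for g in grids], axis=1)

    def same_geometry(self, other: "Volume3D", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
        )

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """New volume on the same grid with different voxel values."""
        return type(self)(data=data, spacing=self.spacing.copy(), origin=self.origin.copy())


@dataclass
class BinaryMask(Volume3D):
    """A Volume3D whose values are exactly 0 or 1."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.unique(self.data)
        if not np.all(np.isin(vals, (0.0, 1.0))):
            raise ValidationError("mask values must be exactly 0 or 1")

    @property
    def bool_data(self) -> np.ndarray:
        return self.data > 0.5


@dataclass
class ProbabilityMap(Volume3D):
    """A Volume3D constrained to [0, 1]: per-voxel hyperechogenicity probability."""

    def __post_init__(self):
        super().__post_init__()
        if np.nanmin(self.data) < -1e-9 or np.nanmax(self.data) > 1.0 + 1e-9:
            raise ValidationError("probability map values must lie in [0, 1]")
        np.clip(self.data, 0.0, 1.0, out=self.data)


# ---------------------------------------------------------------------- #
# NIfTI I/O
# ---------------------------------------------------------------------- #
def _affine(v: Volume3D) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(v.spacing)
    aff[:3, 3] = v.origin
    return aff


def read_volume(path) -> Volume3D:
    """Read a NIfTI-1 volume.

    A 4D image whose 4th dimension has length 1 is squeezed to 3D; any other
    non-3D image is rejected.  The grid must be axis-aligned (diagonal affine
    with positive voxel sizes).
    """
    try:
        img = nib.load(str(path))
    except FileNotFoundError:
        raise ValidationError(f"no such file: {path}") from None
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"expected a 3D image, got {data.ndim}D with shape {data.shape}")
    aff = img.affine
    rot = aff[:3, :3]
    diag = np.diag(rot)
    if np.max(np.abs(rot - np.diag(diag))) > 1e-4 * max(np.max(np.abs(diag)), 1.0):
        raise GeometryError("oblique orientations are not supported (non-diagonal affine)")
    if np.any(diag <= 0):
        raise GeometryError("affine must have positive voxel sizes on the diagonal")
    return Volume3D(data=data.astype(float), spacing=diag, origin=aff[:3, 3])


def write_volume(v: Volume3D, path) -> None:
    """Write a volume as NIfTI-1 (float32 data, diagonal affine)."""
    img = nib.Nifti1Image(v.data.astype(np.float32), _affine(v))
    img.header.set_zooms(tuple(float(s) for s in v.spacing))
    nib.save(img, str(path))


# ---------------------------------------------------------------------- #
# Intensity and geometry operations
# ---------------------------------------------------------------------- #
def minmax_rescale(v: Volume3D, support: BinaryMask | None = None) -> Volume3D:
    """Linearly rescale to [0, 1] over the support (whole volume if absent).

    A constant volume maps to all zeros; results are clipped to [0, 1].
    """
    if not np.all(np.isfinite(v.data)):
        raise ValidationError("minmax_rescale requires finite-valued input")
    if support is not None:
        if not v.same_geometry(support):
            raise GeometryError("support mask geometry does not match volume")
        vals = v.data[support.bool_data]
        if vals.size == 0:
            raise ValidationError("support mask is empty")
    else:
        vals = v.data
    mn, mx = float(vals.min()), float(vals.max())
    if mx == mn:
        return v.with_data(np.zeros(v.shape))
    return v.with_data(np.clip((v.data - mn) / (mx - mn), 0.0, 1.0))


def downsample(v: Volume3D, factor: int) -> Volume3D:
    """Anti-aliased decimation by an integer factor.

    Gaussian pre-smoothing with sigma = 0.5 * factor voxels, then decimation
    starting at index 0.  Output spacing = spacing * factor; the origin is
    unchanged (voxel (0,0,0) is retained), preserving the field of view.
    """
    if int(factor) != factor or factor < 1:
        raise ParameterError(f"downsample factor must be a positive integer, got {factor}")
    factor = int(factor)
    if factor == 1:
        return v.with_data(v.data.copy())
    smoothed = ndimage.gaussian_filter(v.data, sigma=0.5 * factor, mode="nearest")
    out = smoothed[::factor, ::factor, ::factor]
    return Volume3D(data=out.copy(), spacing=v.spacing * factor, origin=v.origin.copy())


def resample(
    moving: Volume3D,
    T: RigidTransform,
    reference: Volume3D,
    fill: float = 0.0,
) -> Volume3D:
    """Resample ``moving`` onto the ``reference`` grid through ``T``.

    Each reference world point X is mapped to T(X) in moving space and
    trilinearly interpolated; points outside the moving support take ``fill``.
    """
    pts = reference.grid_world_points()
    mapped = T.apply(pts)
    idx = moving.world_to_index(mapped)
    out = ndimage.map_coordinates(
        moving.data, idx.T, order=1, mode="constant", cval=fill
    ).reshape(reference.shape)
    return Volume3D(data=out, spacing=reference.spacing.copy(), origin=reference.origin.copy())
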