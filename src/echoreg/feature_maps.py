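"""Scale-space valley detection and hyperechogenicity probability maps.

The MLvv operator is a second-order curvature detector built from Gaussian
first and second derivatives of the image.  In T1-weighted MR, sulci and the
cerebral falx are valleys (negative ridges) of the intensity field; in B-mode
ultrasound the same liquid interfaces appear bright.  The operator is defined
here with the *valley-positive* convention: dark tubular/planar valleys give
positive responses, bright crests negative ones.  Only the positive part is
kept and rescaled to [0, 1]; voxels of a segmented hyperechogenic lesion are
merged in at probability psi (1 for homogeneous hyperechogenic lesions such
as cavernomas and low-grade gliomas).

For the ultrasound volume the intensity itself (rescaled to [0, 1]) is the
probability of hyperechogenic structure: no segmentation is required.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import GeometryError, ParameterError, ValidationError
from .volume_io import BinaryMask, ProbabilityMap, Volume3D, minmax_rescale

__all__ = [
    "ScaleParam",
    "gaussian_derivative",
    "compute_mlvv",
    "scaled_positive_mlvv",
    "mr_probability_map",
    "us_probability_map",
]

#: relative degeneracy floor on the squared gradient magnitude
GRADIENT_FLOOR_REL = 1e-12


@dataclass(frozen=True)
class ScaleParam:
    """Image scale: Gaussian standard deviation, in voxels, for derivatives."""

    sigma: float = 2.0

    def __post_init__(self):
        if not (np.isscalar(self.sigma) and self.sigma > 0):
            raise ParameterError(f"sigma must be positive, got {self.sigma!r}")


def _sigma(scale) -> float:
    if isinstance(scale, ScaleParam):
        return float(scale.sigma)
    s = float(scale)
    if s <= 0:
        raise ParameterError(f"sigma must be positive, got {scale!r}")
    return s


def _derivative_kernel(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel with moment normalisation.

    The kernel weights w(i), i = -r..r (r = 4 sigma), satisfy the exactness
    conditions of the corresponding derivative: order 0 sums to 1; order 1
    has zero sum and unit first moment; order 2 has zero sum and second
    moment 2.  This makes the operators exact on polynomials up to their
    order — in particular, constants are annihilated exactly, which the
    additive-shift invariance of the valley operator depends on.
    """
    r = max(int(4.0 * sigma + 0.5), 1)
    x = np.arange(-r, r + 1, dtype=float)
    phi = np.exp(-(x**2) / (2.0 * sigma**2))
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        w = -x / sigma**2 * phi
        return w / np.dot(w, x)  # unit first moment (zero sum by oddness)
    w = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
    w -= w.mean()  # zero sum
    return w * (2.0 / np.dot(w, x**2))  # second moment 2


def _separable_derivative(data: np.ndarray, sigma: float, orders) -> np.ndarray:
    out = data
    for axis, order in enumerate(orders):
        kernel = _derivative_kernel(sigma, order)
        out = ndimage.correlate1d(out, kernel, axis=axis, mode="nearest")
    return out


def gaussian_derivative(v: Volume3D, sigma, orders) -> Volume3D:
    """Separable Gaussian-derivative filtering, derivatives per voxel unit.

    ``orders`` gives the per-axis derivative order (each in {0, 1, 2}, total
    order at most 2).  Spacing is not folded into the kernels: the image
    scale is expressed in voxels.
    """
    orders = tuple(int(o) for o in orders)
    if len(orders) != 3 or any(o not in (0, 1, 2) for o in orders) or sum(orders) > 2:
        raise ParameterError(f"unsupported derivative orders {orders}")
    return v.with_data(_separable_derivative(v.data, _sigma(sigma), orders))


def compute_mlvv(v: Volume3D, sigma=ScaleParam()) -> Volume3D:
    """Signed MLvv valley field at the given image scale.

    With V's Gaussian derivatives (subscripts denote differentiation axes)

        MLvv = [ Vx²(Vyy+Vzz) + Vy²(Vxx+Vzz) + Vz²(Vxx+Vyy)
                 − 2(Vy·Vz·Vyz + Vx·Vz·Vxz + Vx·Vy·Vxy) ] / (2‖∇V‖²),

    positive in intensity valleys (sulci, falx), negative on crests.  Voxels
    whose squared gradient magnitude falls below a relative floor are set to
    0 (flat regions carry no ridge information).  The 1/‖∇V‖² normalisation
    makes the operator linear in intensity scalings, MLvv(cV) = c·MLvv(V),
    and invariant to additive shifts.
    """
    if not np.all(np.isfinite(v.data)):
        raise ValidationError("compute_mlvv requires finite-valued input")
    s = _sigma(sigma)
    d = lambda o: _separable_derivative(v.data, s, o)
    Vx, Vy, Vz = d((1, 0, 0)), d((0, 1, 0)), d((0, 0, 1))
    Vxx, Vyy, Vzz = d((2, 0, 0)), d((0, 2, 0)), d((0, 0, 2))
    Vxy, Vxz, Vyz = d((1, 1, 0)), d((1, 0, 1)), d((0, 1, 1))

    bracket = (
        Vx**2 * (Vyy + Vzz)
        + Vy**2 * (Vxx + Vzz)
        + Vz**2 * (Vxx + Vyy)
        - 2.0 * (Vy * Vz * Vyz + Vx * Vz * Vxz + Vx * Vy * Vxy)
    )
    w2 = Vx**2 + Vy**2 + Vz**2
    dyn = float(v.data.max() - v.data.min())
    floor = GRADIENT_FLOOR_REL * dyn**2
    out = np.zeros(v.shape)
    ok = w2 >= max(floor, np.finfo(float).tiny)
    out[ok] = bracket[ok] / (2.0 * w2[ok])
    return v.with_data(out)


def scaled_positive_mlvv(mlvv: Volume3D) -> Volume3D:
    """Positive MLvv part rescaled to [0, 1] over its strictly-positive support.

    Non-positive voxels stay exactly 0 (background keeps probability 0).
    """
    pos = np.clip(mlvv.data, 0.0, None)
    mask = pos > 0
    out = np.zeros(mlvv.shape)
    if np.any(mask):
        mn, mx = float(pos[mask].min()), float(pos[mask].max())
        if mx > mn:
            out[mask] = (pos[mask] - mn) / (mx - mn)
        else:
            out[mask] = 1.0
    return mlvv.with_data(out)


def mr_probability_map(
    denoised_mr: Volume3D,
    lesion: BinaryMask | None = None,
    psi: float = 1.0,
    sigma=ScaleParam(),
) -> ProbabilityMap:
    """Probability of hyperechogenic structure from a denoised T1-w MR volume.

    The positive MLvv part (sulci, falx) is min-max scaled to [0, 1] over its
    positive support, then merged with the lesion term by taking the
    voxel-wise max with psi·lesion (max keeps the probability semantics when
    the two supports overlap).
    """
    if not (0.0 <= psi <= 1.0):
        raise ParameterError(f"psi must lie in [0, 1], got {psi}")
    if lesion is not None and not denoised_mr.same_geometry(lesion):
        raise GeometryError("lesion mask geometry does not match the MR volume")
    scaled = scaled_positive_mlvv(compute_mlvv(denoised_mr, sigma))
    out = scaled.data
    if lesion is not None:
        out = np.maximum(out, psi * lesion.bool_data)
    return ProbabilityMap(
        data=np.clip(out, 0.0, 1.0),
        spacing=denoised_mr.spacing.copy(),
        origin=denoised_mr.origin.copy(),
    )


def us_probability_map(us: Volume3D) -> ProbabilityMap:
    """Probability map from an ultrasound volume: intensities rescaled to [0, 1].

    No other processing — high B-mode intensity *is* the evidence of
    hyperechogenic structure.  Acoustic-shadow zeros map to probability 0.
    """
    scaled = minmax_rescale(us)
    return ProbabilityMap(data=scaled.data, spacing=us.spacing.copy(), origin=us.origin.copy())
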