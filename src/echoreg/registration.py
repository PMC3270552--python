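"""Rigid registration by maximising the joint hyperechogenicity probability.

The objective is the discretised correlation integral

    S(T) = (1/|Ω|) Σ_{X ∈ US grid}  p_US(X) · p_MR(T(X)),

with p_MR trilinearly interpolated and 0 outside the MR support, so missing
information (limited field of view, acoustic shadows) simply contributes
nothing.  T maps US (fixed) world coordinates into MR (moving) space.  The
mean (rather than the sum) makes scores comparable across pyramid levels.

Maximisation uses a Nelder-Mead simplex over the 6 rigid parameters inside a
two-level multiresolution pyramid (downsampling factor 3, then the original
resolution).  The simplex is deterministic: identical inputs and settings
give identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .errors import ParameterError, ValidationError
from .geometry import RigidTransform
from .volume_io import ProbabilityMap, Volume3D, downsample

__all__ = [
    "OptimizerConfig",
    "LevelResult",
    "RegistrationResult",
    "objective",
    "simplex_optimize",
    "register",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Simplex and pyramid settings.

    tolerance : simplex convergence tolerance; interpreted as a *relative*
        function-value spread: a level stops when the spread across the
        simplex falls below ``tolerance * 1e-3 * |score at the level's
        start|``.  The relative form keeps the criterion invariant to the
        overall magnitude of the correlation score, which depends on map
        sparsity (a raw spread of 0.1 would stop immediately on scores of
        order 1e-2).  Set ``absolute_tolerance`` to use a literal absolute
        spread instead.
    stepsize : initial simplex perturbation — mm for translations, degrees
        for rotations.
    max_iterations : Nelder-Mead iteration cap per pyramid level.
    pyramid_factors : ordered downsampling factors; the last level should be
        1 (original resolution).
    """

    tolerance: float = 0.1
    stepsize: float = 1.5
    max_iterations: int = 100
    pyramid_factors: tuple = (3, 1)
    absolute_tolerance: float | None = None

    def fatol(self, f0: float = 1.0) -> float:
        """Absolute function-spread stop criterion for a level starting at f0."""
        if self.absolute_tolerance is not None:
            return float(self.absolute_tolerance)
        return float(self.tolerance) * 1e-3 * max(abs(float(f0)), np.finfo(float).tiny)


@dataclass
class LevelResult:
    factor: int
    iterations: int
    n_evaluations: int
    initial_score: float
    final_score: float
    converged: bool


@dataclass
class RegistrationResult:
    transform: RigidTransform
    objective_trace: list = field(default_factory=list)
    level_results: list = field(default_factory=list)
    converged: bool = False

    @property
    def final_score(self) -> float:
        return self.level_results[-1].final_score if self.level_results else float("nan")


class _MapCorrelation:
    """Precomputed evaluator of the correlation score on a fixed map pair.

    Only US voxels with non-zero probability contribute to the sum (zero
    terms vanish), which makes each evaluation cheap on sparse maps; the
    divisor remains the full US voxel count.
    """

    def __init__(self, us_map: Volume3D, mr_map: Volume3D):
        self.n_total = int(np.prod(us_map.shape))
        nz = us_map.data > 0
        idx = np.argwhere(nz)
        self.us_values = us_map.data[nz]
        self.us_points = us_map.index_to_world(idx)
        self.mr = mr_map

    def score(self, T: RigidTransform) -> float:
        if self.us_values.size == 0:
            return 0.0
        from scipy.ndimage import map_coordinates

        mapped = T.apply(self.us_points)
        idx = self.mr.world_to_index(mapped)
        p_mr = map_coordinates(self.mr.data, idx.T, order=1, mode="constant", cval=0.0)
        return float(np.dot(self.us_values, p_mr) / self.n_total)


def objective(us_map: ProbabilityMap, mr_map: ProbabilityMap, T: RigidTransform) -> float:
    """Correlation score of the two probability maps under transform T.

    Mean over US-grid voxels of p_US(X) · p_MR(T(X)); lies in [0, 1].
    """
    return _MapCorrelation(us_map, mr_map).score(T)


def simplex_optimize(
    f,
    x0: RigidTransform,
    cfg: OptimizerConfig | None = None,
) -> RegistrationResult:
    """Nelder-Mead maximisation of ``f`` over the 6 rigid parameters.

    ``f`` takes a length-6 parameter vector (tx, ty, tz in mm, rx, ry, rz in
    degrees; rotation center fixed to ``x0.center``).  The initial simplex is
    x0 plus 6 vertices each perturbing one parameter by ``cfg.stepsize``.
    Stops when the function-value spread across the simplex falls below
    ``cfg.fatol`` or the iteration cap is reached.
    """
    cfg = cfg or OptimizerConfig()
    p0 = x0.params
    f0 = float(f(p0))
    if not np.isfinite(f0):
        raise ValidationError("objective is non-finite at the initial transform")

    if cfg.max_iterations <= 0:
        res = RegistrationResult(transform=x0, objective_trace=[f0], converged=False)
        res.level_results.append(
            LevelResult(1, 0, 1, initial_score=f0, final_score=f0, converged=False)
        )
        return res

    trace: list = []

    def neg(p):
        val = float(f(p))
        trace.append(val)
        return -val

    simplex = np.tile(p0, (7, 1))
    for i in range(6):
        simplex[i + 1, i] += cfg.stepsize

    opt = optimize.minimize(
        neg,
        p0,
        method="Nelder-Mead",
        options={
            "initial_simplex": simplex,
            "maxiter": cfg.max_iterations,
            "maxfev": 100 * cfg.max_iterations + 7,
            "fatol": cfg.fatol(f0),
            "xatol": float("inf"),  # the function-spread criterion governs
        },
    )
    best = RigidTransform.from_params(opt.x, center=x0.center)
    result = RegistrationResult(
        transform=best, objective_trace=trace, converged=bool(opt.status == 0)
    )
    result.level_results.append(
        LevelResult(
            1,
            int(opt.nit),
            int(opt.nfev),
            initial_score=f0,
            final_score=float(-opt.fun),
            converged=bool(opt.status == 0),
        )
    )
    return result


def _as_probability(v: Volume3D) -> ProbabilityMap:
    return ProbabilityMap(
        data=np.clip(v.data, 0.0, 1.0), spacing=v.spacing.copy(), origin=v.origin.copy()
    )


def register(
    us_map: ProbabilityMap,
    mr_map: ProbabilityMap,
    cfg: OptimizerConfig | None = None,
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Multiresolution rigid registration of the two probability maps.

    For each pyramid factor in order, both maps are downsampled and the
    simplex is run from the previous level's result (``init`` at the
    coarsest level; identity if omitted).  Rotations are parameterised about
    the US volume's physical center.
    """
    cfg = cfg or OptimizerConfig()
    if not cfg.pyramid_factors:
        raise ParameterError("pyramid_factors must contain at least one level")
    center = us_map.center_world
    current = (init or RigidTransform.identity(center)).with_center(center)

    result = RegistrationResult(transform=current)
    for factor in cfg.pyramid_factors:
        us_l = _as_probability(downsample(us_map, factor))
        mr_l = _as_probability(downsample(mr_map, factor))
        corr = _MapCorrelation(us_l, mr_l)
        level = simplex_optimize(
            lambda p: corr.score(RigidTransform.from_params(p, center=center)),
            current,
            cfg,
        )
        current = level.transform
        result.objective_trace.extend(level.objective_trace)
        lr = level.level_results[0]
        lr.factor = int(factor)
        result.level_results.append(lr)
        result.converged = lr.converged
    result.transform = current
    return result
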