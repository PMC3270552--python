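"""Validation machinery: landmark errors, leave-one-out TRE, warping index,
and the randomized robustness study.

The quantitative framework mirrors clinical practice for image-guided
neurosurgery: homologous expert landmarks give the initial (neuronavigation)
error and a leave-one-out target registration error (TRE); the warping index
ω summarises the distance between two rigid transforms as the mean voxel
displacement over a volume domain; robustness is assessed by perturbing a
reference alignment with random rigid transforms and counting recoveries
with ω below a success threshold (3.5 mm by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, ParameterError, ValidationError
from .geometry import RigidTransform
from .registration import OptimizerConfig, register
from .volume_io import BinaryMask, ProbabilityMap, Volume3D, resample

__all__ = [
    "LandmarkPairs",
    "DistanceStats",
    "RobustnessReport",
    "fit_rigid_landmarks",
    "initial_error",
    "tre_leave_one_out",
    "warping_index",
    "random_rigid_transform",
    "robustness_study",
]

_SOURCE_NAMES = {"source", "us"}
_TARGET_NAMES = {"target", "mr"}


@dataclass
class LandmarkPairs:
    """Ordered homologous 3D point pairs in world mm (source=US, target=MR)."""

    source: np.ndarray
    target: np.ndarray

    def __post_init__(self):
        self.source = np.asarray(self.source, dtype=float).reshape(-1, 3)
        self.target = np.asarray(self.target, dtype=float).reshape(-1, 3)
        if self.source.shape != self.target.shape:
            raise ValidationError("source and target must contain the same number of points")
        if not (np.all(np.isfinite(self.source)) and np.all(np.isfinite(self.target))):
            raise ValidationError("landmark coordinates must be finite")

    def __len__(self) -> int:
        return self.source.shape[0]

    @classmethod
    def from_csv(cls, path) -> "LandmarkPairs":
        """Read a landmark table with columns set, point_id, x, y, z (mm).

        ``set`` is "source"/"us" or "target"/"mr"; points are paired by
        ``point_id`` order.
        """
        df = pd.read_csv(path)
        missing = {"set", "point_id", "x", "y", "z"} - set(df.columns)
        if missing:
            raise ValidationError(f"landmark CSV missing columns: {sorted(missing)}")
        sets = df["set"].str.lower()
        src = df[sets.isin(_SOURCE_NAMES)].sort_values("point_id")
        tgt = df[sets.isin(_TARGET_NAMES)].sort_values("point_id")
        if len(src) != len(tgt) or not np.array_equal(
            src["point_id"].to_numpy(), tgt["point_id"].to_numpy()
        ):
            raise ValidationError("landmark CSV source/target point_ids do not pair up")
        return cls(src[["x", "y", "z"]].to_numpy(), tgt[["x", "y", "z"]].to_numpy())

    def to_csv(self, path) -> None:
        rows = []
        for name, pts in (("source", self.source), ("target", self.target)):
            for i, p in enumerate(pts):
                rows.append({"set": name, "point_id": i, "x": p[0], "y": p[1], "z": p[2]})
        pd.DataFrame(rows).to_csv(path, index=False)

    def drop(self, i: int) -> "LandmarkPairs":
        keep = np.arange(len(self)) != i
        return LandmarkPairs(self.source[keep], self.target[keep])


@dataclass
class DistanceStats:
    """Per-point distances (mm) with their mean and sample std (n-1)."""

    distances: np.ndarray
    mean: float
    std: float

    @classmethod
    def from_distances(cls, d: np.ndarray) -> "DistanceStats":
        d = np.asarray(d, dtype=float)
        std = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
        return cls(distances=d, mean=float(np.mean(d)), std=std)


# ---------------------------------------------------------------------- #
# Point-based rigid fitting and errors
# ---------------------------------------------------------------------- #
def fit_rigid_landmarks(pairs: LandmarkPairs) -> RigidTransform:
    """Closed-form least-squares rigid fit T minimising Σ‖T(aᵢ) − bᵢ‖².

    Centroid alignment plus the Kabsch rotation from the cross-covariance
    decomposition; reflections are excluded (det R = +1).  Requires at least
    3 non-collinear source points.
    """
    if len(pairs) < 3:
        raise GeometryError("rigid fit requires at least 3 point pairs")
    a, b = pairs.source, pairs.target
    ac, bc = a.mean(axis=0), b.mean(axis=0)
    A, B = a - ac, b - bc
    sv = np.linalg.svd(A, compute_uv=False)
    if sv[1] <= 1e-9 * max(sv[0], 1.0):
        raise GeometryError("source points are collinear or degenerate")
    from scipy.spatial.transform import Rotation

    rot, _ = Rotation.align_vectors(B, A)  # proper rotation minimising Σ|B - R A|²
    m = np.eye(4)
    m[:3, :3] = rot.as_matrix()
    m[:3, 3] = bc - rot.as_matrix() @ ac
    return RigidTransform.from_matrix(m, center=ac)


def initial_error(pairs: LandmarkPairs) -> DistanceStats:
    """Per-point Euclidean distances between homologous landmarks (mm)."""
    d = np.linalg.norm(pairs.target - pairs.source, axis=1)
    return DistanceStats.from_distances(d)


def tre_leave_one_out(pairs: LandmarkPairs) -> DistanceStats:
    """Leave-one-out target registration error over all landmark pairs.

    For each point i, a rigid transform is fitted to the remaining pairs and
    applied to source point i; TRE_i is its distance to target point i.
    """
    n = len(pairs)
    if n < 4:
        raise GeometryError("leave-one-out TRE requires at least 4 point pairs")
    tre = np.empty(n)
    for i in range(n):
        try:
            T = fit_rigid_landmarks(pairs.drop(i))
        except GeometryError as e:
            raise GeometryError(f"degenerate fit when leaving out point {i}: {e}") from e
        tre[i] = np.linalg.norm(T.apply(pairs.source[i]) - pairs.target[i])
    return DistanceStats.from_distances(tre)


# ---------------------------------------------------------------------- #
# Warping index and robustness study
# ---------------------------------------------------------------------- #
def _domain_points(domain) -> np.ndarray:
    if isinstance(domain, BinaryMask):
        idx = np.argwhere(domain.bool_data)
        if idx.size == 0:
            raise ValidationError("warping-index domain mask is empty")
        return domain.index_to_world(idx)
    if isinstance(domain, Volume3D):
        return domain.grid_world_points()
    raise ValidationError("domain must be a Volume3D or BinaryMask")


def warping_index(T_true: RigidTransform, T_est: RigidTransform, domain) -> float:
    """Mean displacement ω (mm) between two transforms over a voxel domain.

    ω = mean over domain voxel world positions X of ‖T_true(X) − T_est(X)‖₂.
    A pseudo-metric on transforms: symmetric, zero iff the transforms agree
    on the domain, and satisfying the triangle inequality.
    """
    pts = _domain_points(domain)
    return float(np.mean(np.linalg.norm(T_true.apply(pts) - T_est.apply(pts), axis=1)))


def random_rigid_transform(
    rng: np.random.Generator,
    t_max: float,
    r_max: float,
    center=(0.0, 0.0, 0.0),
    symmetric: bool = False,
) -> RigidTransform:
    """Random rigid perturbation with uniform translations and rotations.

    Each translation component ~ Uniform[0, t_max] mm and each rotation
    angle ~ Uniform[0, r_max] degrees (the literal protocol); with
    ``symmetric=True`` the ranges become [-t_max, t_max] / [-r_max, r_max].
    Translations are drawn before rotations, so results are reproducible
    from the generator state alone.
    """
    if t_max < 0 or r_max < 0:
        raise ParameterError("t_max and r_max must be non-negative")
    lo_t = -t_max if symmetric else 0.0
    lo_r = -r_max if symmetric else 0.0
    t = rng.uniform(lo_t, t_max, size=3)
    r = rng.uniform(lo_r, r_max, size=3)
    return RigidTransform(translation=t, rotation_deg=r, center=center)


@dataclass
class RobustnessReport:
    """Per-trial outcomes of the randomized robustness study."""

    omegas: list = field(default_factory=list)
    true_transforms: list = field(default_factory=list)
    est_transforms: list = field(default_factory=list)
    successes: list = field(default_factory=list)
    threshold: float = 3.5

    @property
    def n_trials(self) -> int:
        return len(self.omegas)

    @property
    def success_rate(self) -> float:
        """Percentage of trials with ω below the threshold (NaN if no trials)."""
        if self.n_trials == 0:
            return float("nan")
        return 100.0 * sum(self.successes) / self.n_trials

    def _finite_omegas(self) -> np.ndarray:
        return np.array([w for w in self.omegas if np.isfinite(w)])

    @property
    def mean_omega(self) -> float:
        w = self._finite_omegas()
        return float(np.mean(w)) if w.size else float("nan")

    @property
    def std_omega(self) -> float:
        w = self._finite_omegas()
        return float(np.std(w, ddof=1)) if w.size > 1 else (0.0 if w.size else float("nan"))

    def extend(self, other: "RobustnessReport") -> None:
        if other.threshold != self.threshold:
            raise ParameterError("cannot merge reports with different thresholds")
        self.omegas.extend(other.omegas)
        self.true_transforms.extend(other.true_transforms)
        self.est_transforms.extend(other.est_transforms)
        self.successes.extend(other.successes)

    def to_dict(self) -> dict:
        return {
            "threshold_mm": self.threshold,
            "n_trials": self.n_trials,
            "success_rate_percent": self.success_rate,
            "mean_omega_mm": self.mean_omega,
            "std_omega_mm": self.std_omega,
            "omegas_mm": [float(w) for w in self.omegas],
            "successes": [bool(s) for s in self.successes],
            "true_transforms": [t.to_dict() for t in self.true_transforms],
            "estimated_transforms": [t.to_dict() for t in self.est_transforms],
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"omega_mm": self.omegas, "success": self.successes})


def robustness_study(
    us_map: ProbabilityMap,
    mr_map: ProbabilityMap,
    reference: RigidTransform,
    n_trials: int,
    cfg: OptimizerConfig | None = None,
    threshold: float = 3.5,
    rng: np.random.Generator | None = None,
    t_max: float = 5.0,
    r_max: float = 5.0,
    symmetric: bool = False,
) -> RobustnessReport:
    """Randomized robustness protocol on a pre-aligned map pair.

    Per trial: a random rigid perturbation P is applied to the MR map
    (resampled through P on its own grid), registration is run from the
    reference alignment, and ω is computed over the US domain against the
    composed ground truth P⁻¹ ∘ reference.  Registration failures are
    recorded as non-successes (ω = inf), never raised.
    """
    if n_trials < 0:
        raise ParameterError("n_trials must be non-negative")
    cfg = cfg or OptimizerConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    center = us_map.center_world
    report = RobustnessReport(threshold=float(threshold))
    for _ in range(n_trials):
        P = random_rigid_transform(rng, t_max, r_max, center=center, symmetric=symmetric)
        truth = P.inverse().compose(reference)
        moved = resample(mr_map, P, reference=mr_map)
        mr_pert = ProbabilityMap(
            data=np.clip(moved.data, 0.0, 1.0),
            spacing=moved.spacing,
            origin=moved.origin,
        )
        try:
            res = register(us_map, mr_pert, cfg, init=reference)
            omega = warping_index(truth, res.transform, us_map)
            est = res.transform
        except Exception:
            omega, est = float("inf"), reference
        report.omegas.append(omega)
        report.true_transforms.append(truth)
        report.est_transforms.append(est)
        report.successes.append(bool(omega < threshold))
    return report
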