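"""Functional PCA of f0 contours: decomposition, projection, restyling.

A set of f0 trajectories (semitones over milliseconds) is brought onto a
common duration-normalized grid, decomposed into a mean curve plus up to
three orthonormal principal-component curves,

    F0(t) ≈ mu(t) + s1*FPC1(t) + s2*FPC2(t) + s3*FPC3(t),

and any contour is then represented by its weight triple (s1, s2, s3).
Restyling a contour means replacing s2 and s3 with condition-typical
targets and solving the equation above on a fresh 5-ms time lattice.

The estimator is a plain eigendecomposition of the centered sample
covariance on the grid (equivalently an SVD of the centered data matrix);
no roughness penalty is applied.  Component signs are fixed by requiring a
non-negative grid integral, with ties broken by the first nonzero value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ContourError, GridError, OrderingError, RankError
from .specs import ProsodySpec, default_spec

__all__ = [
    "Contour",
    "NormalizedContour",
    "FPCAModel",
    "ScoreSet",
    "hz_to_semitones",
    "normalize_time",
    "fit_fpca",
    "project",
    "restyle_scores",
    "reconstruct",
]

_GRID_ATOL = 1e-10


def hz_to_semitones(hz: np.ndarray, reference_hz: float | None = None) -> np.ndarray:
    """Convert f0 in Hz to semitones relative to ``reference_hz``.

    The reference defaults to the median of the (positive, finite) input,
    the usual per-speaker normalization.  12 semitones = one octave.
    """
    hz = np.asarray(hz, dtype=float)
    if reference_hz is None:
        valid = hz[np.isfinite(hz) & (hz > 0)]
        if valid.size == 0:
            raise ContourError("no positive finite f0 values to take a reference from")
        reference_hz = float(np.median(valid))
    if reference_hz <= 0:
        raise ValueError("reference_hz must be positive")
    return 12.0 * np.log2(hz / reference_hz)


@dataclass(frozen=True)
class Contour:
    """A sampled f0 trajectory: times in ms, values in semitones."""

    times: np.ndarray
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.shape != v.shape:
            raise ContourError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ContourError("a contour needs at least 2 samples")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ContourError("contour contains non-finite entries")
        if np.any(np.diff(t) <= 0):
            raise OrderingError("contour times must be strictly increasing")

    @property
    def duration_ms(self) -> float:
        return float(self.times[-1] - self.times[0])

    def shifted(self, offset_ms: float) -> "Contour":
        return replace(self, times=self.times + offset_ms)


@dataclass(frozen=True)
class NormalizedContour:
    """A contour resampled onto ``grid_size`` equal steps of unit time."""

    grid: np.ndarray          # equally spaced points on [0, 1]
    values: np.ndarray
    label: str = ""
    source_duration_ms: float = float("nan")

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)
        if g.size < 10:
            raise GridError("normalized grid must have at least 10 points")
        if g.shape != v.shape:
            raise GridError("grid and values must have matching shapes")


@dataclass(frozen=True)
class FPCAModel:
    """Mean curve plus K <= 3 orthonormal component curves on a shared grid.

    ``components`` has shape (K, G); orthonormality is with respect to the
    plain grid inner product.  ``score_sds`` are the standard deviations of
    the training scores, non-increasing in component index.
    """

    grid: np.ndarray
    mean_curve: np.ndarray
    components: np.ndarray
    score_sds: np.ndarray

    @property
    def n_components(self) -> int:
        return int(self.components.shape[0])

    def __post_init__(self) -> None:
        for name in ("grid", "mean_curve", "components", "score_sds"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class ScoreSet:
    """Component weights (s1, s2, s3) of one contour; s_k is None when K < k."""

    s1: float
    s2: float | None = None
    s3: float | None = None

    def as_array(self) -> np.ndarray:
        vals = [self.s1] + [s for s in (self.s2, self.s3) if s is not None]
        return np.asarray(vals, dtype=float)

    @staticmethod
    def from_array(arr: Sequence[float]) -> "ScoreSet":
        arr = list(float(a) for a in arr)
        if not 1 <= len(arr) <= 3:
            raise ValueError("a ScoreSet holds 1 to 3 weights")
        return ScoreSet(*arr)


def normalize_time(contour: Contour, grid_size: int = 101) -> NormalizedContour:
    """Resample a contour onto ``grid_size`` equally spaced points of [0, 1].

    Time is mapped affinely from the contour's extent to the unit interval
    and values are linearly interpolated; both endpoints are preserved
    exactly.
    """
    if grid_size < 10:
        raise GridError("grid_size must be at least 10")
    grid = np.linspace(0.0, 1.0, grid_size)
    t0, t1 = contour.times[0], contour.times[-1]
    unit_times = (contour.times - t0) / (t1 - t0)
    values = np.interp(grid, unit_times, contour.values)
    # guard against interp rounding at the endpoints
    values[0] = contour.values[0]
    values[-1] = contour.values[-1]
    return NormalizedContour(grid=grid, values=values, label=contour.label,
                             source_duration_ms=contour.duration_ms)


def _check_same_grid(grid: np.ndarray, other: np.ndarray) -> None:
    if grid.shape != other.shape or not np.allclose(grid, other, atol=_GRID_ATOL):
        raise GridError("contours are not on the same grid")


def _fix_sign(component: np.ndarray) -> np.ndarray:
    """Deterministic sign: grid integral >= 0, ties by first nonzero > 0."""
    integral = component.sum()
    if abs(integral) > 1e-12:
        return component if integral > 0 else -component
    nonzero = np.nonzero(np.abs(component) > 1e-15)[0]
    if nonzero.size and component[nonzero[0]] < 0:
        return -component
    return component


def fit_fpca(
    contours: Sequence[NormalizedContour], n_components: int = 3
) -> tuple[FPCAModel, list[ScoreSet]]:
    """Fit the mean curve and leading component curves of a contour set.

    The components are the leading eigenvectors of the centered sample
    covariance on the grid; scores are inner products of the centered
    contours with the components, so each score has zero mean over the
    training set by construction.
    """
    if not 1 <= n_components <= 3:
        raise RankError("n_components must be 1, 2, or 3")
    if len(contours) < n_components + 1:
        raise RankError(
            f"need at least {n_components + 1} contours for {n_components} components"
        )
    grid = contours[0].grid
    for c in contours[1:]:
        _check_same_grid(grid, c.grid)
    X = np.stack([c.values for c in contours])       # (n, G)
    mean_curve = X.mean(axis=0)
    Xc = X - mean_curve
    # SVD of the centered matrix == eigendecomposition of the covariance
    _, svals, vt = np.linalg.svd(Xc, full_matrices=False)
    if svals.size == 0 or svals[0] < 1e-12:
        # zero-variance set: every contour equals the mean; scores are all 0
        # and the component curves are an arbitrary (canonical) orthonormal set
        vt = np.eye(grid.size)[: len(contours)]
    else:
        rank = int(np.sum(svals > svals[0] * 1e-10))
        if n_components > rank:
            raise RankError(
                f"requested {n_components} components but centered data "
                f"have rank {rank}"
            )
    components = np.stack([_fix_sign(vt[k]) for k in range(n_components)])
    scores = Xc @ components.T                        # (n, K)
    score_sds = scores.std(axis=0)
    model = FPCAModel(grid=grid, mean_curve=mean_curve,
                      components=components, score_sds=score_sds)
    return model, [ScoreSet.from_array(row) for row in scores]


def project(model: FPCAModel, contour: NormalizedContour) -> ScoreSet:
    """Weights of a contour under the model: inner products of the centered
    contour with each component (the least-squares solution under
    orthonormality)."""
    _check_same_grid(model.grid, contour.grid)
    centered = contour.values - model.mean_curve
    return ScoreSet.from_array(model.components @ centered)


def restyle_scores(
    scores: ScoreSet, condition: str, spec: ProsodySpec | None = None
) -> ScoreSet:
    """Impose a prosodic category: keep s1, substitute the condition's
    target weights for s2 and s3."""
    if spec is None:
        spec = default_spec(condition)
    elif spec.condition != condition:
        raise ValueError(
            f"spec is for condition {spec.condition!r}, not {condition!r}"
        )
    return ScoreSet(s1=scores.s1, s2=spec.s2_target, s3=spec.s3_target)


def reconstruct(
    model: FPCAModel,
    scores: ScoreSet,
    duration_ms: float,
    step_ms: float = 5.0,
) -> Contour:
    """Solve mu + sum_k s_k * FPC_k on a fresh time lattice.

    The curve lives on the normalized grid; it is evaluated by linear
    interpolation at t/duration for t = 0, step, 2*step, ... up to and
    including ``duration_ms`` only when the duration is divisible by the
    step (no extrapolated terminal point).
    """
    if duration_ms <= 0 or step_ms <= 0:
        raise ValueError("duration_ms and step_ms must be positive")
    s = scores.as_array()
    if s.size != model.n_components:
        raise RankError(
            f"scores have {s.size} weights but the model has "
            f"{model.n_components} components"
        )
    curve = model.mean_curve + s @ model.components
    n_steps = int(np.floor(duration_ms / step_ms + 1e-9))
    times = step_ms * np.arange(n_steps + 1)
    values = np.interp(times / duration_ms, model.grid, curve)
    return Contour(times=times, values=values)
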