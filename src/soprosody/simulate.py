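"""Synthetic inputs for the whole pipeline, at desk scale.

Three generators, all driven by one root seed with fixed sub-streams:

* ``gen_contours`` — f0 contours built as a mean curve plus three
  orthonormal component curves, where the 2nd/3rd component weights are
  drawn around condition-typical means (s2: +0.335 subjective vs -0.515
  objective; s3: -0.065 vs +0.025) and durations near 285/235 ms.
* ``gen_responses`` — Bernoulli forced-choice trials from the hierarchical
  logistic model with by-participant and by-pair random intercepts and
  prosody slopes, the generative twin of the most complex analysis model.
  Defaults sit at the perception study's reported posterior means
  (intercept -1.06 log-odds, prosody slope 0.39, slope SDs 0.51/0.42).
* ``gen_filler_accuracies`` — a 55-participant attention-check table
  matching the study's printed accuracy distribution band-for-band
  (38 at 100%, 2 above 90%, 3 in 70-89%, 8 in 50-69%, 4 below 50%).

Random-number contract: ``default_rng([seed, STREAM_*])``; the stream ids
are module constants, so each generator is reproducible independently of
the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.special import expit

from .contours import Contour

__all__ = [
    "GenerativeParams",
    "ContourGenParams",
    "gen_contours",
    "gen_responses",
    "gen_filler_accuracies",
    "expected_choice_rate",
    "STREAM_CONTOURS",
    "STREAM_RESPONSES",
    "STREAM_FILLERS",
]

STREAM_CONTOURS = 1
STREAM_RESPONSES = 2
STREAM_FILLERS = 3

N_PAIRS = 15
N_FILLERS = 20


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class GenerativeParams:
    """Parameters of the hierarchical logistic response generator.

    ``beta0`` is the log-odds of choosing the subjective continuation in
    the objective-prosody condition (prosody coded 0) for an average
    participant/pair; ``beta_prosody`` the log-odds shift when prosody is
    subjective (coded 1).  The four SDs govern normal random intercepts
    and prosody slopes by participant and pair.  The intercept SDs were
    not reported by the study and default to 0.5, the same order as the
    reported slope SDs.
    """

    beta0: float = -1.06
    beta_prosody: float = 0.39
    sd_slope_participant: float = 0.51
    sd_slope_pair: float = 0.42
    sd_int_participant: float = 0.5
    sd_int_pair: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_slope_participant", "sd_slope_pair",
                     "sd_int_participant", "sd_int_pair"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def null(self) -> "GenerativeParams":
        """The intercept-only generative twin (no prosody effect, no slopes)."""
        return GenerativeParams(
            beta0=self.beta0, beta_prosody=0.0,
            sd_slope_participant=0.0, sd_slope_pair=0.0,
            sd_int_participant=self.sd_int_participant,
            sd_int_pair=self.sd_int_pair, seed=self.seed,
        )


def _default_mean(t: np.ndarray) -> np.ndarray:
    return 1.0 - 2.0 * t                      # gently falling line (st)


def _default_comp1(t: np.ndarray) -> np.ndarray:
    return 1.0 + 0.5 * t                      # overall level / tilt


def _default_comp2(t: np.ndarray) -> np.ndarray:
    return np.sin(np.pi * t)                  # concave mid-span bulge


def _default_comp3(t: np.ndarray) -> np.ndarray:
    return np.cos(2.0 * np.pi * t) * (t - 0.5)  # end-point tilt


@dataclass(frozen=True)
class ContourGenParams:
    """Shape and score parameters of the contour generator.

    Shapes are callables on normalized time [0, 1]; they are
    orthonormalized (Gram-Schmidt on the evaluation grid) before use, so
    only their spans matter.  ``score_sds`` are within-condition SDs of
    (s1, s2, s3); ``condition_means`` hold the condition-typical means of
    (s2, s3).  Durations are drawn normal around 285 ms (subjective) and
    235 ms (objective) with SD ``duration_sd_ms``.
    """

    mean_shape: Callable[[np.ndarray], np.ndarray] = _default_mean
    comp_shapes: tuple[Callable[[np.ndarray], np.ndarray], ...] = (
        _default_comp1, _default_comp2, _default_comp3)
    score_sds: tuple[float, float, float] = (1.0, 0.3, 0.1)
    condition_means: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"subjective": (0.335, -0.065),
                                 "objective": (-0.515, 0.025)})
    condition_durations_ms: dict[str, float] = field(
        default_factory=lambda: {"subjective": 285.0, "objective": 235.0})
    duration_sd_ms: float = 10.0
    noise_sd: float = 0.1                    # white noise, semitones
    grid_size: int = 101

    def curves(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Evaluate (grid, mean, orthonormal components) on the grid."""
        t = np.linspace(0.0, 1.0, self.grid_size)
        mean = np.asarray(self.mean_shape(t), dtype=float)
        raw = np.stack([np.asarray(f(t), dtype=float) for f in self.comp_shapes])
        if mean.shape != t.shape or raw.shape[1] != t.size:
            raise ValueError("shape callables must return arrays of grid length")
        # Gram-Schmidt under the plain grid inner product
        q, r = np.linalg.qr(raw.T)
        if np.any(np.abs(np.diag(r)) < 1e-10):
            raise ValueError("component shapes are linearly dependent")
        comps = (q * np.sign(np.diag(r))).T   # keep each shape's orientation
        return t, mean, comps


def gen_contours(
    n_per_condition: int, params: ContourGenParams | None = None, seed: int = 0
) -> list[Contour]:
    """Draw ``n_per_condition`` contours per causality condition.

    Each contour is mean + s1*c1 + s2*c2 + s3*c3 + white noise on its own
    5-ms time lattice, with (s2, s3) centered on the condition means.
    Labels are ``"<condition>_<index>"``.
    """
    if n_per_condition < 2:
        raise ValueError("n_per_condition must be >= 2")
    params = params or ContourGenParams()
    rng = _rng(seed, STREAM_CONTOURS)
    grid, mean, comps = params.curves()
    sds = np.asarray(params.score_sds, dtype=float)
    out: list[Contour] = []
    for cond in ("subjective", "objective"):
        m2, m3 = params.condition_means[cond]
        mu_dur = params.condition_durations_ms[cond]
        for i in range(n_per_condition):
            s = rng.normal([0.0, m2, m3], sds)
            dur = max(50.0, rng.normal(mu_dur, params.duration_sd_ms))
            times = 5.0 * np.arange(int(np.floor(dur / 5.0)) + 1)
            shape = mean + s @ comps
            values = np.interp(times / times[-1], grid, shape)
            values = values + rng.normal(0.0, params.noise_sd, size=times.size)
            out.append(Contour(times=times, values=values,
                               label=f"{cond}_{i:03d}"))
    return out


def gen_responses(
    n_participants: int, params: GenerativeParams | None = None
) -> pd.DataFrame:
    """Simulate a complete forced-choice trial table.

    Every participant sees every pair in both prosody conditions exactly
    once (30 target trials per participant).  For each trial,

        P(choice = 1) = inv-logit(beta0 + a_p + b_q
                                  + (beta_prosody + u_p + w_q) * prosody)

    with all random effects drawn independently normal at the stated SDs.
    Columns: participant, pair, prosody (0 objective / 1 subjective),
    choice (1 = subjective continuation).
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    params = params or GenerativeParams()
    rng = _rng(params.seed, STREAM_RESPONSES)
    a = rng.normal(0.0, params.sd_int_participant, n_participants)
    u = rng.normal(0.0, params.sd_slope_participant, n_participants)
    b = rng.normal(0.0, params.sd_int_pair, N_PAIRS)
    w = rng.normal(0.0, params.sd_slope_pair, N_PAIRS)
    p_idx, q_idx, x = np.meshgrid(
        np.arange(n_participants), np.arange(N_PAIRS), np.array([0, 1]),
        indexing="ij")
    p_idx, q_idx, x = p_idx.ravel(), q_idx.ravel(), x.ravel()
    eta = (params.beta0 + a[p_idx] + b[q_idx]
           + (params.beta_prosody + u[p_idx] + w[q_idx]) * x)
    choice = rng.random(eta.size) < expit(eta)
    return pd.DataFrame({
        "participant": p_idx + 1,
        "pair": q_idx + 1,
        "prosody": x.astype(int),
        "choice": choice.astype(int),
    })


def expected_choice_rate(
    params: GenerativeParams, prosody: int, n_draws: int = 100_000,
    seed: int = 12345,
) -> float:
    """Population-average P(choice = subjective) at one prosody level,
    marginalized over the random effects by Monte Carlo."""
    rng = np.random.default_rng(seed)
    eta = params.beta0 + params.beta_prosody * prosody
    spread = np.sqrt(params.sd_int_participant ** 2 + params.sd_int_pair ** 2
                     + (params.sd_slope_participant ** 2
                        + params.sd_slope_pair ** 2) * prosody)
    return float(expit(eta + rng.normal(0.0, 1.0, n_draws) * spread).mean())


# printed filler-accuracy bands: (n participants, lowest correct, highest
# correct) on the 20-filler lattice
_FILLER_BANDS = (
    (38, 20, 20),   # 100%
    (2, 19, 19),    # (90%, 100%): only 19/20 fits the lattice
    (3, 14, 17),    # 70-89%  (18/20 = 90% would leave the band)
    (8, 10, 13),    # 50-69%
    (4, 0, 9),      # below 50%
)


def gen_filler_accuracies(seed: int = 0) -> pd.DataFrame:
    """A 55-row attention-check table matching the printed distribution.

    Within each accuracy band the correct-count is uniform on the 20-filler
    lattice; band membership is shuffled over participant ids.  Columns:
    participant, n_fillers, n_correct, accuracy.
    """
    rng = _rng(seed, STREAM_FILLERS)
    counts: list[int] = []
    for n, lo, hi in _FILLER_BANDS:
        counts.extend(rng.integers(lo, hi + 1, size=n).tolist())
    counts_arr = np.asarray(counts)
    rng.shuffle(counts_arr)
    n_total = counts_arr.size
    return pd.DataFrame({
        "participant": np.arange(1, n_total + 1),
        "n_fillers": N_FILLERS,
        "n_correct": counts_arr,
        "accuracy": counts_arr / N_FILLERS,
    })
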