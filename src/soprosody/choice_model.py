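"""Bayesian hierarchical logistic analysis of forced-choice responses.

The model ladder mirrors the incremental structure of the analysis:

=====  =============================================================
model  formula (logit link, Bernoulli outcome)
=====  =============================================================
m0     ~ 1 + (1 | participant) + (1 | pair)
m1     ~ prosody + (1 | participant) + (1 | pair)
m2     ~ prosody + (1 + prosody | participant) + (1 | pair)
m3     ~ prosody + (1 + prosody | participant) + (1 + prosody | pair)
=====  =============================================================

Priors: normal(0, sd) on the intercept and the prosody coefficient and
half-normal(0, sd) on every random-effect SD, with one ``PriorSpec`` sd
shared by all of them (the sd is screened over {10, 1.5, 1, 0.5, 0.25} by
prior predictive checks and over {1.5, 1, 0.5} for Bayes factors).
Intercept/slope pairs are independent (no correlation parameter).

Sampling uses the package NUTS sampler on a non-centered parameterization
(standard-normal offsets scaled by the SDs, SDs sampled on the log scale
with the change-of-variable Jacobian).  Model evidence for Bayes factors
comes from bridge sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, log_expit

from . import bridge, mcmc
from .errors import CapabilityError, SchemaError

__all__ = [
    "ModelSpec", "PriorSpec", "FitResult", "PosteriorSummary", "BFResult",
    "MODELS", "MODEL_LADDER", "PRIOR_PREDICTIVE_SDS", "BAYES_FACTOR_SDS",
    "REDUCED_SETTINGS", "PAPER_SETTINGS",
    "filter_participants", "prior_predictive", "fit", "bayes_factor",
    "bayes_factor_from_fits", "summarize_effects",
    "reciprocal_odds", "slope_variance", "interpret_bf",
]

PRIOR_PREDICTIVE_SDS = (10.0, 1.5, 1.0, 0.5, 0.25)
BAYES_FACTOR_SDS = (1.5, 1.0, 0.5)

#: sampler configurations: the full configuration used for reported fits
#: (4 chains x 10,000 iterations, 2,000 warmup) and a reduced desk-scale one
PAPER_SETTINGS = {"n_chains": 4, "n_iterations": 10_000, "n_warmup": 2_000}
REDUCED_SETTINGS = {"n_chains": 4, "n_iterations": 2_000, "n_warmup": 500}


@dataclass(frozen=True)
class ModelSpec:
    """One rung of the nested model ladder."""

    name: str
    has_prosody: bool
    slope_participant: bool
    slope_pair: bool

    def __contains__(self, other: "ModelSpec") -> bool:
        """Structural nesting: every term of ``other`` is a term of self."""
        return (
            (self.has_prosody or not other.has_prosody)
            and (self.slope_participant or not other.slope_participant)
            and (self.slope_pair or not other.slope_pair)
        )


MODELS: dict[str, ModelSpec] = {
    "m0": ModelSpec("m0", False, False, False),
    "m1": ModelSpec("m1", True, False, False),
    "m2": ModelSpec("m2", True, True, False),
    "m3": ModelSpec("m3", True, True, True),
}
MODEL_LADDER = ("m0", "m1", "m2", "m3")


@dataclass(frozen=True)
class PriorSpec:
    """Zero-mean normal prior scale shared by the parameters of interest."""

    sd: float
    family: str = "normal"

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")
        if self.family != "normal":
            raise ValueError("only the normal family is supported")


# ---------------------------------------------------------------------------
# data handling

_REQUIRED_COLS = ("participant", "pair", "prosody", "choice")


def _design(data: pd.DataFrame):
    missing = [c for c in _REQUIRED_COLS if c not in data.columns]
    if missing:
        raise SchemaError(f"trial table is missing columns {missing}")
    if len(data) == 0:
        raise ValueError("trial table is empty")
    participants = np.sort(data["participant"].unique())
    pairs = np.sort(data["pair"].unique())
    p_idx = pd.Categorical(data["participant"], categories=participants).codes
    q_idx = pd.Categorical(data["pair"], categories=pairs).codes
    x = data["prosody"].to_numpy(dtype=float)
    y = data["choice"].to_numpy(dtype=float)
    return participants, pairs, p_idx.astype(int), q_idx.astype(int), x, y


class _Layout:
    """Index bookkeeping for the unconstrained parameter vector."""

    def __init__(self, spec: ModelSpec, n_p: int, n_q: int):
        self.spec = spec
        self.n_p, self.n_q = n_p, n_q
        names = ["b_intercept"]
        if spec.has_prosody:
            names.append("b_prosody")
        names += ["log_sd_int_participant", "log_sd_int_pair"]
        if spec.slope_participant:
            names.append("log_sd_slope_participant")
        if spec.slope_pair:
            names.append("log_sd_slope_pair")
        self.scalar_names = list(names)
        self.slices: dict[str, slice] = {}
        pos = len(names)
        for block, size, present in (
            ("z_int_participant", n_p, True),
            ("z_int_pair", n_q, True),
            ("z_slope_participant", n_p, spec.slope_participant),
            ("z_slope_pair", n_q, spec.slope_pair),
        ):
            if present:
                self.slices[block] = slice(pos, pos + size)
                pos += size
        self.dim = pos

    def idx(self, name: str) -> int:
        return self.scalar_names.index(name)


def _make_logp(layout: _Layout, p_idx, q_idx, x, y, prior_sd: float):
    """Return (logp(theta), logp_and_grad(theta), loglik(theta)) closures."""
    spec = layout.spec
    i_b0 = layout.idx("b_intercept")
    i_b1 = layout.idx("b_prosody") if spec.has_prosody else None
    i_la = layout.idx("log_sd_int_participant")
    i_lb = layout.idx("log_sd_int_pair")
    i_lu = layout.idx("log_sd_slope_participant") if spec.slope_participant else None
    i_lw = layout.idx("log_sd_slope_pair") if spec.slope_pair else None
    s_za = layout.slices["z_int_participant"]
    s_zb = layout.slices["z_int_pair"]
    s_zu = layout.slices.get("z_slope_participant")
    s_zw = layout.slices.get("z_slope_pair")
    n_p, n_q = layout.n_p, layout.n_q
    inv_var = 1.0 / prior_sd ** 2
    xy = x * 1.0
    # prior normalization constants: irrelevant for sampling, essential for
    # marginal likelihoods (models differ in dimension)
    n_beta = 2 if spec.has_prosody else 1
    n_sd = 2 + spec.slope_participant + spec.slope_pair
    n_z = n_p + n_q + (n_p if spec.slope_participant else 0) \
        + (n_q if spec.slope_pair else 0)
    log_norm = (
        -0.5 * n_beta * np.log(2 * np.pi * prior_sd ** 2)
        + n_sd * (np.log(2.0) - 0.5 * np.log(2 * np.pi * prior_sd ** 2))
        - 0.5 * n_z * np.log(2 * np.pi)
    )

    def unpack(theta):
        b0 = theta[i_b0]
        b1 = theta[i_b1] if i_b1 is not None else 0.0
        sa, sb = np.exp(theta[i_la]), np.exp(theta[i_lb])
        su = np.exp(theta[i_lu]) if i_lu is not None else 0.0
        sw = np.exp(theta[i_lw]) if i_lw is not None else 0.0
        za, zb = theta[s_za], theta[s_zb]
        zu = theta[s_zu] if s_zu is not None else None
        zw = theta[s_zw] if s_zw is not None else None
        return b0, b1, sa, sb, su, sw, za, zb, zu, zw

    def eta_of(theta):
        b0, b1, sa, sb, su, sw, za, zb, zu, zw = unpack(theta)
        eta = b0 + sa * za[p_idx] + sb * zb[q_idx]
        if spec.has_prosody:
            slope = b1
            if zu is not None:
                slope = slope + su * zu[p_idx]
            if zw is not None:
                slope = slope + sw * zw[q_idx]
            eta = eta + xy * slope
        return eta

    def loglik(theta):
        eta = eta_of(theta)
        return float(np.sum(y * eta + log_expit(-eta)))

    def logp(theta):
        b0, b1, sa, sb, su, sw, za, zb, zu, zw = unpack(theta)
        lp = loglik(theta) + log_norm
        lp -= 0.5 * inv_var * (b0 * b0 + b1 * b1)
        # half-normal(0, prior_sd) on each SD, sampled as log sd (+Jacobian)
        for s, i in ((sa, i_la), (sb, i_lb), (su, i_lu), (sw, i_lw)):
            if i is not None:
                lp += -0.5 * inv_var * s * s + theta[i]
        lp -= 0.5 * float(za @ za + zb @ zb)
        if zu is not None:
            lp -= 0.5 * float(zu @ zu)
        if zw is not None:
            lp -= 0.5 * float(zw @ zw)
        return lp

    def logp_and_grad(theta):
        b0, b1, sa, sb, su, sw, za, zb, zu, zw = unpack(theta)
        eta = b0 + sa * za[p_idx] + sb * zb[q_idx]
        if spec.has_prosody:
            slope = b1
            if zu is not None:
                slope = slope + su * zu[p_idx]
            if zw is not None:
                slope = slope + sw * zw[q_idx]
            eta = eta + xy * slope
        lp = float(np.sum(y * eta + log_expit(-eta))) + log_norm
        lp -= 0.5 * inv_var * (b0 * b0 + b1 * b1)
        lp -= 0.5 * float(za @ za + zb @ zb)
        grad = np.zeros_like(theta)
        r = y - expit(eta)
        grad[i_b0] = np.sum(r) - inv_var * b0
        grad[s_za] = sa * np.bincount(p_idx, weights=r, minlength=n_p) - za
        grad[s_zb] = sb * np.bincount(q_idx, weights=r, minlength=n_q) - zb
        grad[i_la] = sa * float(r @ za[p_idx]) - inv_var * sa * sa + 1.0
        grad[i_lb] = sb * float(r @ zb[q_idx]) - inv_var * sb * sb + 1.0
        lp += -0.5 * inv_var * (sa * sa + sb * sb) + theta[i_la] + theta[i_lb]
        if spec.has_prosody:
            rx = r * xy
            grad[i_b1] = np.sum(rx) - inv_var * b1
            if zu is not None:
                lp += -0.5 * float(zu @ zu)
                lp += -0.5 * inv_var * su * su + theta[i_lu]
                grad[s_zu] = su * np.bincount(p_idx, weights=rx, minlength=n_p) - zu
                grad[i_lu] = su * float(rx @ zu[p_idx]) - inv_var * su * su + 1.0
            if zw is not None:
                lp += -0.5 * float(zw @ zw)
                lp += -0.5 * inv_var * sw * sw + theta[i_lw]
                grad[s_zw] = sw * np.bincount(q_idx, weights=rx, minlength=n_q) - zw
                grad[i_lw] = sw * float(rx @ zw[q_idx]) - inv_var * sw * sw + 1.0
        return lp, grad

    return logp, logp_and_grad, loglik


# ---------------------------------------------------------------------------
# operations


def filter_participants(
    accuracies: pd.DataFrame, fail_fraction: float = 0.10
) -> np.ndarray:
    """Ids of participants who pass the attention check.

    A participant fails when their incorrect-answer fraction over the
    fillers is ``fail_fraction`` *or more* (strictly-below-threshold
    retention), so 2 wrong out of 20 (exactly 10%) is excluded.
    """
    cols = set(accuracies.columns)
    if "participant" not in cols:
        raise SchemaError("accuracy table needs a 'participant' column")
    if {"n_correct", "n_fillers"} <= cols:
        incorrect = 1.0 - accuracies["n_correct"] / accuracies["n_fillers"]
    elif "accuracy" in cols:
        if "n_fillers" not in cols:
            raise SchemaError("accuracy table needs 'n_fillers' alongside 'accuracy'")
        incorrect = 1.0 - accuracies["accuracy"]
    else:
        raise SchemaError("accuracy table needs n_correct/n_fillers or accuracy")
    keep = incorrect.to_numpy() < fail_fraction - 1e-12
    return accuracies.loc[keep, "participant"].to_numpy()


def prior_predictive(
    spec: ModelSpec | str,
    prior: PriorSpec,
    design: pd.DataFrame,
    n_draws: int = 2000,
    seed: int = 0,
    statistic: str = "proportion",
) -> np.ndarray:
    """Datasets implied by the prior before seeing any data.

    For each of ``n_draws`` draws, model parameters are sampled from the
    prior and a full dataset on the design's trials is simulated.  With
    ``statistic="proportion"`` (default) the overall proportion choosing
    the subjective continuation is returned per draw; with
    ``statistic="trial_probability"`` the pooled trial-level choice
    probabilities (inverse-logit of the linear predictor) are returned —
    the scale on which a wide prior shows its never-or-always behaviour,
    since averaging many saturated participants masks it in proportions.
    """
    if statistic not in ("proportion", "trial_probability"):
        raise ValueError("statistic must be 'proportion' or 'trial_probability'")
    if isinstance(spec, str):
        spec = MODELS[spec]
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000")
    _, _, p_idx, q_idx, x, _ = _design(design)
    n_p, n_q, n_t = p_idx.max() + 1, q_idx.max() + 1, x.size
    rng = np.random.default_rng(seed)
    b0 = rng.normal(0.0, prior.sd, n_draws)
    eta = b0[:, None] + np.zeros((n_draws, n_t))
    sa = np.abs(rng.normal(0.0, prior.sd, n_draws))
    sb = np.abs(rng.normal(0.0, prior.sd, n_draws))
    eta += sa[:, None] * rng.normal(size=(n_draws, n_p))[:, p_idx]
    eta += sb[:, None] * rng.normal(size=(n_draws, n_q))[:, q_idx]
    if spec.has_prosody:
        slope = rng.normal(0.0, prior.sd, n_draws)[:, None] + np.zeros(n_t)
        if spec.slope_participant:
            su = np.abs(rng.normal(0.0, prior.sd, n_draws))
            slope += su[:, None] * rng.normal(size=(n_draws, n_p))[:, p_idx]
        if spec.slope_pair:
            sw = np.abs(rng.normal(0.0, prior.sd, n_draws))
            slope += sw[:, None] * rng.normal(size=(n_draws, n_q))[:, q_idx]
        eta += slope * x
    prob = expit(eta)
    if statistic == "trial_probability":
        return prob.ravel()
    y = rng.random(eta.shape) < prob
    return y.mean(axis=1)


@dataclass
class FitResult:
    """A sampled posterior of one model on one trial table."""

    spec: ModelSpec
    prior: PriorSpec
    layout: _Layout = field(repr=False)
    participants: np.ndarray
    pairs: np.ndarray
    result: mcmc.NUTSResult = field(repr=False)
    report: mcmc.ConvergenceReport
    logp_fn: object = field(repr=False)
    seed: int = 0

    @property
    def flat(self) -> np.ndarray:
        return self.result.flat

    def scalar_draws(self, name: str) -> np.ndarray:
        """Flattened draws of a named population-level parameter
        (SD parameters are returned on the SD scale)."""
        i = self.layout.idx(name)
        draws = self.flat[:, i]
        return np.exp(draws) if name.startswith("log_") else draws

    def participant_slope_draws(self) -> np.ndarray:
        """(n_draws, n_participants) draws of beta_prosody + u_p, the
        per-participant prosody slope averaged over pairs."""
        if not self.spec.slope_participant:
            raise CapabilityError(
                f"{self.spec.name} has no by-participant prosody slopes")
        b1 = self.flat[:, self.layout.idx("b_prosody")]
        su = np.exp(self.flat[:, self.layout.idx("log_sd_slope_participant")])
        zu = self.flat[:, self.layout.slices["z_slope_participant"]]
        return b1[:, None] + su[:, None] * zu


def fit(
    spec: ModelSpec | str,
    data: pd.DataFrame,
    prior: PriorSpec,
    n_chains: int = 4,
    n_iterations: int = 10_000,
    n_warmup: int = 2_000,
    seed: int = 0,
    on_fail: str = "warn",
) -> FitResult:
    """Sample the posterior of one ladder model.

    Default sampler configuration is the full one (4 chains, 10,000
    iterations of which 2,000 warmup); pass ``**REDUCED_SETTINGS`` for the
    desk-scale configuration.  The convergence contract (no divergences,
    Rhat within 0.01 of 1, bulk ESS above 90% of post-warmup draws) is
    always evaluated; violations warn (or raise) with the full report.
    """
    if isinstance(spec, str):
        spec = MODELS[spec]
    participants, pairs, p_idx, q_idx, x, y = _design(data)
    if spec.has_prosody and np.unique(x).size < 2:
        raise ValueError(
            f"{spec.name} needs both prosody levels present in the data")
    layout = _Layout(spec, participants.size, pairs.size)
    logp, logp_and_grad, _ = _make_logp(layout, p_idx, q_idx, x, y, prior.sd)
    init = np.zeros(layout.dim)
    rate = float(np.clip(y.mean(), 0.02, 0.98))
    init[layout.idx("b_intercept")] = np.log(rate / (1 - rate))
    for name in layout.scalar_names:
        if name.startswith("log_"):
            init[layout.idx(name)] = np.log(0.3)
    result = mcmc.sample_nuts(
        logp_and_grad, init, n_chains=n_chains, n_iterations=n_iterations,
        n_warmup=n_warmup, seed=seed, init_jitter=0.2)
    report = mcmc.diagnose(result, on_fail=on_fail,
                           context=f"{spec.name}, prior sd {prior.sd}")
    return FitResult(spec=spec, prior=prior, layout=layout,
                     participants=participants, pairs=pairs, result=result,
                     report=report, logp_fn=logp, seed=seed)


# ---------------------------------------------------------------------------
# summaries


def _cri(draws: np.ndarray, level: float) -> tuple[float, float]:
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [tail, 1.0 - tail])
    return float(lo), float(hi)


@dataclass
class PosteriorSummary:
    """Posterior summaries of a fitted model.

    ``table`` has one row per population-level parameter with the mean,
    2.5/25/50/75/97.5 percentiles; ``odds`` and ``odds_ratio`` are the
    exponentiated summaries.  The odds ratio is reported both as the mean
    of the exponentiated draws (``odds_ratio``) and as the exponential of
    the mean coefficient (``odds_ratio_exp_of_mean``); the former is the
    headline convention.
    """

    model: str
    prior_sd: float
    table: pd.DataFrame
    odds: float | None
    odds_cri: tuple[float, float] | None
    odds_ratio: float | None
    odds_ratio_exp_of_mean: float | None
    odds_ratio_cri: tuple[float, float] | None
    participant_slopes: pd.DataFrame | None
    report: mcmc.ConvergenceReport


def summarize_effects(fit_result: FitResult) -> PosteriorSummary:
    """Population-level summaries, exponentiated effects, and (for models
    with by-participant slopes) the per-participant slope table."""
    rows = []
    for name in fit_result.layout.scalar_names:
        label = name.removeprefix("log_")
        draws = fit_result.scalar_draws(name)
        lo95, hi95 = _cri(draws, 0.95)
        lo50, hi50 = _cri(draws, 0.50)
        rows.append({
            "parameter": label, "mean": float(draws.mean()),
            "sd": float(draws.std()), "q2.5": lo95, "q25": lo50,
            "q50": float(np.median(draws)), "q75": hi50, "q97.5": hi95,
        })
    table = pd.DataFrame(rows).set_index("parameter")

    b0 = fit_result.scalar_draws("b_intercept")
    odds_draws = np.exp(b0)
    odds = float(odds_draws.mean())
    odds_cri = _cri(odds_draws, 0.95)
    odds_ratio = odds_ratio_eom = None
    or_cri = None
    if fit_result.spec.has_prosody:
        b1 = fit_result.scalar_draws("b_prosody")
        or_draws = np.exp(b1)
        odds_ratio = float(or_draws.mean())
        odds_ratio_eom = float(np.exp(b1.mean()))
        or_cri = _cri(or_draws, 0.95)

    slopes = None
    if fit_result.spec.slope_participant:
        sl = fit_result.participant_slope_draws()
        rows = []
        for j, pid in enumerate(fit_result.participants):
            lo95, hi95 = _cri(sl[:, j], 0.95)
            lo50, hi50 = _cri(sl[:, j], 0.50)
            rows.append({
                "participant": pid, "mean": float(sl[:, j].mean()),
                "q2.5": lo95, "q25": lo50, "q75": hi50, "q97.5": hi95,
                "cri95_excludes_zero": bool(lo95 > 0 or hi95 < 0),
            })
        slopes = pd.DataFrame(rows).set_index("participant")

    return PosteriorSummary(
        model=fit_result.spec.name, prior_sd=fit_result.prior.sd, table=table,
        odds=odds, odds_cri=odds_cri, odds_ratio=odds_ratio,
        odds_ratio_exp_of_mean=odds_ratio_eom, odds_ratio_cri=or_cri,
        participant_slopes=slopes, report=fit_result.report)


def reciprocal_odds(odds: float) -> float:
    """Odds of the complementary choice: 1 / odds (e.g. 1/0.34 = 2.94)."""
    return 1.0 / odds


def slope_variance(sd: float) -> float:
    """Variance implied by a random-slope SD (e.g. 0.51^2 = 0.26)."""
    return sd ** 2


# ---------------------------------------------------------------------------
# Bayes factors


def interpret_bf(bf10: float) -> str:
    """Conventional evidential band for a BF10 value."""
    if bf10 > 10:
        return "strong support"
    if bf10 > 3:
        return "weak support"
    if bf10 >= 1:
        return "very weak support"
    if bf10 < 0.1:
        return "favors the model without the term"
    return "inconclusive"


@dataclass
class BFResult:
    """Bayes factor for a model with a term over the model without it."""

    bf10: float
    log_bf10: float
    model_with: str
    model_without: str
    prior_sd: float
    band: str = ""
    cv_with: float = float("nan")
    cv_without: float = float("nan")

    def __post_init__(self) -> None:
        if not self.band:
            self.band = interpret_bf(self.bf10)


def bayes_factor_from_fits(
    fit_with: FitResult, fit_without: FitResult, seed: int = 0,
    cv_tol: float = 0.10,
) -> BFResult:
    """BF10 from two already-fitted models via bridge-sampled evidences."""
    if fit_without.spec not in fit_with.spec:
        raise ValueError(
            f"{fit_without.spec.name} is not nested in {fit_with.spec.name}")
    if fit_with.prior != fit_without.prior:
        raise ValueError("both models must use the same prior")
    mls = []
    for fr, sub in ((fit_with, 1), (fit_without, 2)):
        mls.append(bridge.log_marginal_likelihood(
            fr.flat, fr.result.logp.ravel(), fr.logp_fn,
            seed=seed * 1000 + sub, cv_tol=cv_tol))
    log_bf = mls[0].logml - mls[1].logml
    return BFResult(
        bf10=float(np.exp(log_bf)), log_bf10=float(log_bf),
        model_with=fit_with.spec.name, model_without=fit_without.spec.name,
        prior_sd=fit_with.prior.sd, cv_with=mls[0].cv, cv_without=mls[1].cv)


def bayes_factor(
    model_with: ModelSpec | str,
    model_without: ModelSpec | str,
    prior: PriorSpec,
    data: pd.DataFrame,
    seed: int = 0,
    on_fail: str = "warn",
    **sampler_settings,
) -> BFResult:
    """Fit both models on ``data`` under ``prior`` and return BF10."""
    settings = {**REDUCED_SETTINGS, **sampler_settings}
    f1 = fit(model_with, data, prior, seed=seed, on_fail=on_fail, **settings)
    f0 = fit(model_without, data, prior, seed=seed + 1, on_fail=on_fail,
             **settings)
    return bayes_factor_from_fits(f1, f0, seed=seed)
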