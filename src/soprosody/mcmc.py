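"""A compact No-U-Turn Hamiltonian Monte Carlo sampler.

Generic over any differentiable unnormalized log density: the caller
supplies ``logp_and_grad(theta) -> (float, ndarray)`` on an unconstrained
parameter space.  Warmup adapts the step size by dual averaging (target
acceptance 0.8) and a diagonal mass matrix from two variance windows, in
the spirit of Stan's windowed adaptation.  Divergent transitions (energy
error > 1000) are counted and never included in the kept draws' tree
expansion.

Convergence is summarized by :class:`ConvergenceReport` (split-Rhat, bulk
and tail ESS via arviz, divergence counts) against the contract: no
divergences, every Rhat within ``rhat_tol`` of 1, and bulk ESS above a
stated fraction of the post-warmup draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ConvergenceError

__all__ = ["NUTSResult", "ConvergenceReport", "sample_nuts", "diagnose"]

_MAX_ENERGY_ERROR = 1000.0

LogpGrad = Callable[[np.ndarray], tuple[float, np.ndarray]]


@dataclass
class ConvergenceReport:
    """Diagnostics of one sampled posterior against the convergence contract."""

    n_divergent: int
    max_rhat: float
    min_ess_bulk: float
    min_ess_tail: float
    n_kept_draws: int            # total post-warmup draws across chains
    rhat_tol: float = 0.01
    ess_fraction: float = 0.9

    @property
    def ess_target(self) -> float:
        return self.ess_fraction * self.n_kept_draws

    @property
    def passed(self) -> bool:
        return (self.n_divergent == 0
                and abs(self.max_rhat - 1.0) <= self.rhat_tol
                and self.min_ess_bulk > self.ess_target)

    def summary(self) -> str:
        return (
            f"divergences={self.n_divergent}, max Rhat={self.max_rhat:.4f} "
            f"(tol ±{self.rhat_tol}), bulk ESS={self.min_ess_bulk:.0f} "
            f"(target >{self.ess_target:.0f} of {self.n_kept_draws}), "
            f"tail ESS={self.min_ess_tail:.0f}"
        )


@dataclass
class NUTSResult:
    """Raw sampler output: ``draws`` has shape (chains, kept, dim)."""

    draws: np.ndarray
    logp: np.ndarray             # (chains, kept)
    n_divergent: int
    step_sizes: np.ndarray
    mean_accept: float

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])


def _leapfrog(logp_and_grad, x, p, grad, eps, m_inv):
    p = p + 0.5 * eps * grad
    x = x + eps * m_inv * p
    logp, grad = logp_and_grad(x)
    p = p + 0.5 * eps * grad
    return x, p, logp, grad


class _Tree:
    """Recursive NUTS trajectory-tree builder (slice-sampling variant)."""

    __slots__ = ("f", "eps", "m_inv", "logu", "h0", "rng", "n_alpha", "alpha",
                 "divergent")

    def __init__(self, f, eps, m_inv, logu, h0, rng):
        self.f = f
        self.eps = eps
        self.m_inv = m_inv
        self.logu = logu
        self.h0 = h0
        self.rng = rng
        self.alpha = 0.0
        self.n_alpha = 0
        self.divergent = False

    def _hamiltonian(self, logp, p):
        return -logp + 0.5 * np.dot(p, self.m_inv * p)

    def build(self, x, p, grad, logp, v, j):
        """Return (x-, p-, g-, lp-, x+, p+, g+, lp+, x', lp', n', s')."""
        if j == 0:
            x1, p1, lp1, g1 = _leapfrog(self.f, x, p, grad, v * self.eps,
                                        self.m_inv)
            h1 = self._hamiltonian(lp1, p1)
            if not np.isfinite(h1):
                h1 = np.inf
            n1 = int(self.logu <= -h1)
            diverged = (-h1) - self.logu < -_MAX_ENERGY_ERROR
            if diverged:
                self.divergent = True
            s1 = int(not diverged)
            self.alpha += min(1.0, np.exp(min(0.0, self.h0 - h1)))
            self.n_alpha += 1
            return (x1, p1, g1, lp1, x1, p1, g1, lp1, x1, lp1, n1, s1)
        (xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, n1, s1) = self.build(
            x, p, grad, logp, v, j - 1)
        if s1:
            if v == -1:
                (xm, pm, gm, lpm, _, _, _, _, xc2, lpc2, n2, s2) = self.build(
                    xm, pm, gm, lpm, v, j - 1)
            else:
                (_, _, _, _, xp, pp, gp, lpp, xc2, lpc2, n2, s2) = self.build(
                    xp, pp, gp, lpp, v, j - 1)
            if n2 and self.rng.random() < n2 / max(n1 + n2, 1):
                xc, lpc = xc2, lpc2
            dx = xp - xm
            s1 = int(s2
                     and np.dot(dx, self.m_inv * pm) >= 0
                     and np.dot(dx, self.m_inv * pp) >= 0)
            n1 = n1 + n2
        return (xm, pm, gm, lpm, xp, pp, gp, lpp, xc, lpc, n1, s1)


def _nuts_step(f, x, logp, grad, eps, m_inv, rng, max_treedepth):
    m_sd = 1.0 / np.sqrt(m_inv)
    p0 = rng.normal(size=x.size) * m_sd
    h0 = -logp + 0.5 * np.dot(p0, m_inv * p0)
    logu = -h0 + np.log(rng.random())
    tree = _Tree(f, eps, m_inv, logu, h0, rng)
    xm = xp = xc = x
    pm = pp = p0
    gm = gp = grad
    lpm = lpp = lpc = logp
    n, s, j = 1, 1, 0
    while s and j < max_treedepth:
        v = 1 if rng.random() < 0.5 else -1
        if v == -1:
            (xm, pm, gm, lpm, _, _, _, _, xc2, lpc2, n2, s2) = tree.build(
                xm, pm, gm, lpm, v, j)
        else:
            (_, _, _, _, xp, pp, gp, lpp, xc2, lpc2, n2, s2) = tree.build(
                xp, pp, gp, lpp, v, j)
        if s2 and rng.random() < min(1.0, n2 / max(n, 1)):
            xc, lpc = xc2, lpc2
        n += n2
        dx = xp - xm
        s = int(s2 and np.dot(dx, m_inv * pm) >= 0
                and np.dot(dx, m_inv * pp) >= 0)
        j += 1
    accept_stat = tree.alpha / max(tree.n_alpha, 1)
    return xc, lpc, accept_stat, tree.divergent


def _run_chain(f, init, n_iterations, n_warmup, rng, max_treedepth,
               target_accept, init_step):
    dim = init.size
    x = init.copy()
    logp, grad = f(x)
    if not np.isfinite(logp):
        raise ValueError("initial point has non-finite log density")
    m_inv = np.ones(dim)
    eps = init_step

    # dual-averaging state
    def fresh_da(eps0):
        return {"mu": np.log(10.0 * eps0), "log_eps_bar": 0.0, "h_bar": 0.0,
                "count": 0}

    da = fresh_da(eps)
    gamma, t0, kappa = 0.05, 10.0, 0.75

    w1 = max(int(0.15 * n_warmup), 5)
    w2 = int(0.5 * n_warmup)
    w3 = int(0.9 * n_warmup)
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros(dim)

    kept = np.empty((n_iterations - n_warmup, dim))
    kept_lp = np.empty(n_iterations - n_warmup)
    n_div = 0
    accepts = []

    for it in range(n_iterations):
        x_new, lp_new, a_stat, diverged = _nuts_step(
            f, x, logp, grad, eps, m_inv, rng, max_treedepth)
        if not np.array_equal(x_new, x):
            x = x_new
            logp, grad = f(x)  # refresh gradient at the accepted point
        if it >= n_warmup:
            if diverged:
                n_div += 1
            kept[it - n_warmup] = x
            kept_lp[it - n_warmup] = logp
            accepts.append(a_stat)
            continue
        # --- warmup adaptation ---
        da["count"] += 1
        frac = 1.0 / (da["count"] + t0)
        da["h_bar"] = (1 - frac) * da["h_bar"] + frac * (target_accept - a_stat)
        log_eps = da["mu"] - np.sqrt(da["count"]) / gamma * da["h_bar"]
        pw = da["count"] ** (-kappa)
        da["log_eps_bar"] = pw * log_eps + (1 - pw) * da["log_eps_bar"]
        eps = float(np.exp(log_eps))
        if w1 <= it < w3:
            welford_n += 1
            delta = x - welford_mean
            welford_mean += delta / welford_n
            welford_m2 += delta * (x - welford_mean)
        if it in (w2 - 1, w3 - 1) and welford_n > 10:
            var = welford_m2 / (welford_n - 1)
            m_inv = (welford_n / (welford_n + 5.0)) * var \
                + (5.0 / (welford_n + 5.0)) * 1e-3
            welford_n = 0
            welford_mean[:] = 0.0
            welford_m2[:] = 0.0
            eps = float(np.exp(da["log_eps_bar"]))
            da = fresh_da(eps)
        if it == n_warmup - 1:
            eps = float(np.exp(da["log_eps_bar"]))
    return kept, kept_lp, n_div, eps, float(np.mean(accepts)) if accepts else 0.0


def sample_nuts(
    logp_and_grad: LogpGrad,
    init: np.ndarray,
    n_chains: int = 4,
    n_iterations: int = 2000,
    n_warmup: int = 500,
    seed: int | Sequence[int] = 0,
    max_treedepth: int = 10,
    target_accept: float = 0.8,
    init_step: float = 0.1,
    init_jitter: float = 0.5,
) -> NUTSResult:
    """Sample a log density with NUTS.

    ``init`` is a starting point on the unconstrained space; each chain
    jitters it with N(0, init_jitter^2) noise.  Returns post-warmup draws
    of shape (n_chains, n_iterations - n_warmup, dim).
    """
    if n_warmup >= n_iterations:
        raise ValueError("n_warmup must be smaller than n_iterations")
    init = np.asarray(init, dtype=float)
    root = np.random.SeedSequence(seed)
    chains, lps, divs, steps, acc = [], [], 0, [], []
    for child in root.spawn(n_chains):
        rng = np.random.default_rng(child)
        start = init + init_jitter * rng.normal(size=init.size)
        kept, kept_lp, n_div, eps, a = _run_chain(
            logp_and_grad, start, n_iterations, n_warmup, rng,
            max_treedepth, target_accept, init_step)
        chains.append(kept)
        lps.append(kept_lp)
        divs += n_div
        steps.append(eps)
        acc.append(a)
    return NUTSResult(
        draws=np.stack(chains),
        logp=np.stack(lps),
        n_divergent=divs,
        step_sizes=np.asarray(steps),
        mean_accept=float(np.mean(acc)),
    )


def diagnose(
    result: NUTSResult,
    rhat_tol: float = 0.01,
    ess_fraction: float = 0.9,
    on_fail: str = "warn",
    context: str = "",
) -> ConvergenceReport:
    """Compute the convergence report and enforce the contract.

    ``on_fail`` is ``"warn"`` (emit a warning carrying the report),
    ``"raise"`` (raise :class:`ConvergenceError`), or ``"ignore"``.
    """
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(result.draws)
        rhat = float(az.rhat(ds)["x"].values.max())
        ess_bulk = float(az.ess(ds, method="bulk")["x"].values.min())
        ess_tail = float(az.ess(ds, method="tail")["x"].values.min())
    report = ConvergenceReport(
        n_divergent=result.n_divergent,
        max_rhat=rhat,
        min_ess_bulk=ess_bulk,
        min_ess_tail=ess_tail,
        n_kept_draws=result.draws.shape[0] * result.draws.shape[1],
        rhat_tol=rhat_tol,
        ess_fraction=ess_fraction,
    )
    if not report.passed and on_fail != "ignore":
        msg = f"convergence contract violated{f' ({context})' if context else ''}: " \
            + report.summary()
        if on_fail == "raise":
            raise ConvergenceError(msg, report=report)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    return report
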