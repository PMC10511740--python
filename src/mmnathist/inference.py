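"""Posterior sampling and summaries.

The sampler is an adaptive random-walk Metropolis in the spirit of
Haario et al.: a joint multivariate-normal proposal whose covariance is
the running empirical covariance of the chain scaled by 2.38^2/d, with
a global log-scale nudged toward a 0.234 acceptance rate. All
adaptation happens during burn-in and is frozen afterwards, so the
retained draws come from a fixed-kernel Metropolis chain. Chains are
independent, each seeded from the master seed, and runs are exactly
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .likelihood import ModelContext

__all__ = [
    "McmcSettings",
    "ChainSet",
    "run_mcmc",
    "gelman_rubin",
    "dic",
    "DicResult",
    "posterior_summary",
    "posterior_predictive",
    "PredictiveBands",
]


@dataclass
class McmcSettings:
    """Protocol: 1,000,000 iterations, half discarded as burn-in,
    thinning every 50, five parallel chains."""

    n_iterations: int = 1_000_000
    burn_in: int = 500_000
    thin: int = 50
    n_chains: int = 5
    seed: int = 0
    adapt_interval: int = 500
    target_accept: float = 0.234
    scale_gain: float = 0.1
    initial_scale: float = 0.1  # absolute, for generic (boxless) targets
    #: "map": overdispersed starts around an optimizer-located mode with
    #: the inverse numerical Hessian as initial proposal covariance;
    #: "prior": independent uniform prior draws (needs long chains).
    init_strategy: str = "map"

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if (self.n_iterations - self.burn_in) % self.thin != 0:
            raise ValueError("(n_iterations - burn_in) must be a multiple of thin")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


@dataclass
class ChainSet:
    """Retained MCMC draws: (n_chains, n_retained, d) plus traces."""

    draws: np.ndarray
    log_posterior: np.ndarray
    acceptance: np.ndarray
    param_names: list[str]
    settings: McmcSettings
    seeds: list[int] = field(default_factory=list)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def pooled(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[2])

    def to_dataframe(self) -> pd.DataFrame:
        n_c, n_r, d = self.draws.shape
        df = pd.DataFrame(self.pooled(), columns=self.param_names)
        df.insert(0, "chain", np.repeat(np.arange(n_c), n_r))
        df.insert(1, "iteration", np.tile(np.arange(n_r), n_c))
        df["log_posterior"] = self.log_posterior.reshape(-1)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, settings: McmcSettings | None = None) -> "ChainSet":
        names = [c for c in df.columns if c not in ("chain", "iteration", "log_posterior")]
        chains = sorted(df["chain"].unique())
        draws = np.stack([df[df["chain"] == c][names].to_numpy() for c in chains])
        lp = np.stack([df[df["chain"] == c]["log_posterior"].to_numpy() for c in chains])
        if settings is None:
            settings = McmcSettings(n_iterations=draws.shape[1] * 2,
                                    burn_in=draws.shape[1], thin=1,
                                    n_chains=draws.shape[0])
        return cls(draws=draws, log_posterior=lp,
                   acceptance=np.full(draws.shape[0], np.nan),
                   param_names=names, settings=settings)


def _safe_cholesky(cov: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, v = np.linalg.eigh(0.5 * (cov + cov.T))
        floor = max(1e-14, 1e-10 * float(np.max(np.abs(w))))
        w = np.maximum(w, floor)
        return np.linalg.cholesky((v * w) @ v.T)


def _adapt_cov(sum_x: np.ndarray, sum_xx: np.ndarray, n: int, d: int,
               log_scale: float, cov0: np.ndarray) -> np.ndarray:
    """Scaled proposal Cholesky from running first/second moments.

    Until enough history accumulates the initial covariance cov0 is
    used; afterwards the empirical chain covariance, regularized by a
    jitter proportional to cov0's diagonal so a barely-moving chain
    still yields a positive-definite proposal.
    """
    s_d = 2.38 ** 2 / d
    if n >= 10 * d:
        mean = sum_x / n
        cov = sum_xx / n - np.outer(mean, mean)
        cov = cov * (n / max(n - 1, 1))
        cov = s_d * (cov + 1e-6 * np.diag(np.diag(cov0)))
    else:
        cov = s_d * cov0
    return _safe_cholesky(np.exp(log_scale) * cov)


def find_map(context: ModelContext, seed: int = 0, n_prior_draws: int = 200,
             n_starts: int = 3, maxiter: int = 6000) -> tuple[np.ndarray, np.ndarray]:
    """Locate a posterior mode and its local covariance.

    The noise variance tau^2 is profiled out analytically — its
    conditional mode is the mean squared log-incidence residual — and
    Nelder-Mead runs on the profiled surface over the hazard
    parameters, restarted from the best of a batch of prior draws and
    re-seeded at its own endpoint until it stalls (profiling removes
    the flat plateau where an inflated tau^2 absorbs incidence misfit,
    which traps a naive joint optimization). The covariance is the
    pseudo-inverse of a finite-difference Hessian of -log posterior at
    the mode, projected to positive definite. Returns (mode in active
    space, covariance).
    """
    from scipy.optimize import minimize

    rng = np.random.default_rng(seed)
    cands = []
    for _ in range(n_prior_draws):
        full = context.draw_initial(rng)
        cands.append((context.log_posterior(full), context.active_vector(full)))
    cands.sort(key=lambda t: -t[0])

    big = 1e12  # finite sentinel; keeps Nelder-Mead ordering without overflow
    t_idx = context.active_names.index("tau2")
    tau2_hi = context.prior.bounds["tau2"][1]
    logx = np.array([np.log(o.x) for o in context.inc_obs])

    def profile_tau2(x_red: np.ndarray) -> float:
        a = np.insert(x_red, t_idx, 1.0)
        try:
            _, ibar = context.predicted_bins(context.full_vector(a))
        except ValueError:
            return np.nan
        if np.any(ibar <= 0):
            return np.nan
        ssr = float(np.mean((logx - np.log(ibar)) ** 2))
        return min(max(ssr, 1e-10), tau2_hi * (1 - 1e-12))

    def neg_lp_prof(x_red: np.ndarray) -> float:
        t2 = profile_tau2(x_red)
        if not np.isfinite(t2):
            return big
        a = np.insert(x_red, t_idx, t2)
        lp = context.log_posterior(context.full_vector(a))
        return -lp if np.isfinite(lp) else big

    best_x, best_f = None, np.inf
    for _, x0 in cands[:n_starts]:
        x = np.delete(x0, t_idx)
        f_prev = np.inf
        # re-seed Nelder-Mead at its own endpoint until it stalls
        for _ in range(6):
            res = minimize(neg_lp_prof, x, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-8,
                                    "fatol": 1e-8, "adaptive": True})
            x = np.asarray(res.x)
            if f_prev - res.fun < 0.01:
                break
            f_prev = float(res.fun)
        if res.fun < best_f:
            best_x, best_f = x, float(res.fun)

    best_x = np.insert(best_x, t_idx, profile_tau2(best_x))

    def neg_lp(a: np.ndarray) -> float:
        lp = context.log_posterior(context.full_vector(a))
        return -lp if np.isfinite(lp) else big

    d = best_x.size
    lo = context.prior.lower()[context.active]
    hi = context.prior.upper()[context.active]
    widths = hi - lo
    # central-difference steps shrunk near prior bounds so the stencil
    # stays strictly inside the box (a mode can sit on a boundary)
    h = np.maximum(1e-5 * widths, 1e-6 * np.maximum(np.abs(best_x), 1.0))
    h = np.minimum(h, np.maximum(0.45 * (best_x - lo), 1e-12))
    h = np.minimum(h, np.maximum(0.45 * (hi - best_x), 1e-12))
    H = np.empty((d, d))
    f0 = neg_lp(best_x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        H[i, i] = (neg_lp(best_x + ei) - 2 * f0 + neg_lp(best_x - ei)) / h[i] ** 2
        for j in range(i):
            ej = np.zeros(d)
            ej[j] = h[j]
            H[i, j] = H[j, i] = (
                neg_lp(best_x + ei + ej) - neg_lp(best_x + ei - ej)
                - neg_lp(best_x - ei + ej) + neg_lp(best_x - ei - ej)
            ) / (4 * h[i] * h[j])
    # Curvatures span many orders of magnitude (the quadratic age
    # coefficient is ~10^7 times stiffer than the multipliers), so the
    # matrix is repaired and inverted in correlation scale: divide out
    # sqrt(diag), zero entries poisoned by stencil points that fell in
    # the -inf region, floor the eigenvalues, and scale back.
    diag_h = np.diag(H).copy()
    fallback_diag = 1.0 / (1e-3 * widths) ** 2
    for i in range(d):
        if not np.isfinite(diag_h[i]) or diag_h[i] <= 0 or diag_h[i] >= big:
            diag_h[i] = fallback_diag[i]
    d_inv = 1.0 / np.sqrt(diag_h)
    Ht = H * np.outer(d_inv, d_inv)
    Ht[~np.isfinite(Ht) | (np.abs(Ht) > 1e6)] = 0.0
    np.fill_diagonal(Ht, 1.0)
    w, v = np.linalg.eigh(0.5 * (Ht + Ht.T))
    w = np.maximum(w, 1e-4)
    cov = ((v / w) @ v.T) * np.outer(d_inv, d_inv)
    return best_x, cov


def run_mcmc(target: ModelContext | Callable[[np.ndarray], float],
             settings: McmcSettings,
             init: Sequence[np.ndarray] | None = None) -> ChainSet:
    """Sample the posterior with adaptive random-walk Metropolis.

    ``target`` is either a :class:`ModelContext` (compiled fast path;
    draws live in its active-parameter space) or any callable mapping a
    parameter vector to a log-density (generic path, used with mock
    targets). ``init`` optionally gives one start vector per chain;
    otherwise a ModelContext initializes per ``settings.init_strategy``
    (mode-centered overdispersed starts by default, uniform prior
    draws with "prior"). Identical settings and inputs give
    bit-identical output.
    """
    is_context = isinstance(target, ModelContext)
    seed_seq = np.random.SeedSequence(settings.seed)
    child_seqs = seed_seq.spawn(settings.n_chains)

    mode = cov0_map = None
    if is_context and init is None and settings.init_strategy == "map":
        mode, cov0_map = find_map(target, seed=settings.seed)

    all_draws = []
    all_lp = []
    acc_frac = []
    names = None
    for c in range(settings.n_chains):
        rng = np.random.default_rng(child_seqs[c])
        if is_context:
            ctx: ModelContext = target
            names = ctx.active_names
            if init is not None:
                theta_full = ctx._sanitize(np.asarray(init[c], dtype=float))
            elif mode is not None:
                theta_full = _overdispersed_start(ctx, mode, cov0_map, rng)
            else:
                theta_full = ctx.draw_initial(rng)
            lp0 = ctx.log_posterior(theta_full)
            if not np.isfinite(lp0):
                raise ValueError(f"chain {c}: initial point has non-finite posterior")
            if cov0_map is not None:
                cov0 = cov0_map
            else:
                widths = (ctx.prior.upper() - ctx.prior.lower())[ctx.active]
                cov0 = np.diag((1e-3 * widths) ** 2)
            draws_c, lp_c, acc = _run_chain_context(ctx, theta_full, lp0, rng, settings,
                                                    cov0)
        else:
            if init is None:
                raise ValueError("generic targets require explicit per-chain init points")
            theta = np.asarray(init[c], dtype=float).copy()
            lp0 = float(target(theta))
            if not np.isfinite(lp0):
                raise ValueError(f"chain {c}: initial point has non-finite log-density")
            d = theta.size
            names = [f"x{i}" for i in range(d)]
            cov0 = np.diag(np.full(d, settings.initial_scale ** 2))
            draws_c, lp_c, acc = _run_chain_generic(target, theta, lp0, rng, settings,
                                                    cov0)
        all_draws.append(draws_c)
        all_lp.append(lp_c)
        acc_frac.append(acc)

    return ChainSet(draws=np.stack(all_draws), log_posterior=np.stack(all_lp),
                    acceptance=np.array(acc_frac), param_names=list(names),
                    settings=settings,
                    seeds=[int(s.generate_state(1)[0] % (2 ** 31)) for s in child_seqs])


def _overdispersed_start(ctx: ModelContext, mode: np.ndarray, cov0: np.ndarray,
                         rng: np.random.Generator, spread: float = 2.0,
                         max_tries: int = 200) -> np.ndarray:
    """Mode plus a widened draw from the local covariance, redrawn
    until the posterior is finite (falls back to the mode itself)."""
    L = _safe_cholesky(cov0)
    for _ in range(max_tries):
        cand = ctx.full_vector(mode + spread * (L @ rng.standard_normal(mode.size)))
        if np.isfinite(ctx.log_posterior(cand)):
            return cand
    return ctx.full_vector(mode)


def _retained_slots(settings: McmcSettings, start: int, stop: int):
    """Global iteration indices in (start, stop] that are retained, and
    their target rows. Iterations are 1-based; iteration i is retained
    when i > burn_in and (i - burn_in) % thin == 0."""
    for i in range(start + 1, stop + 1):
        k = i - settings.burn_in
        if k > 0 and k % settings.thin == 0:
            yield i, k // settings.thin - 1


def _run_chain_context(ctx: ModelContext, theta_full, lp0, rng, settings, cov0):
    d = ctx.n_active
    n_ret = settings.n_retained_per_chain
    draws = np.empty((n_ret, d))
    lps = np.empty(n_ret)
    sum_x = np.zeros(d)
    sum_xx = np.zeros((d, d))
    n_hist = 0
    log_scale = 0.0
    L = _adapt_cov(sum_x, sum_xx, 0, d, log_scale, cov0)

    theta = theta_full.copy()
    lp = lp0
    done = 0
    accepted_total = 0
    B_max = settings.adapt_interval
    while done < settings.n_iterations:
        B = min(B_max, settings.n_iterations - done)
        z = rng.standard_normal((B, d))
        logu = np.log(rng.random(B))
        chain_out = np.empty((B, theta.size))
        lp_out = np.empty(B)
        lp, acc = _kernels.metropolis_block(theta, lp, ctx.active, L, z, logu,
                                            chain_out, lp_out, *ctx.packed,
                                            ctx._pbar_buf, ctx._ibar_buf)
        accepted_total += acc
        active_block = chain_out[:, ctx.active]
        for i, row in _retained_slots(settings, done, done + B):
            draws[row] = active_block[i - done - 1]
            lps[row] = lp_out[i - done - 1]
        if done + B <= settings.burn_in:
            sum_x += active_block.sum(axis=0)
            sum_xx += active_block.T @ active_block
            n_hist += B
            log_scale += settings.scale_gain * (acc / B - settings.target_accept)
            L = _adapt_cov(sum_x, sum_xx, n_hist, d, log_scale, cov0)
        done += B
    return draws, lps, accepted_total / settings.n_iterations


def _run_chain_generic(target, theta, lp, rng, settings, cov0):
    d = theta.size
    n_ret = settings.n_retained_per_chain
    draws = np.empty((n_ret, d))
    lps = np.empty(n_ret)
    sum_x = np.zeros(d)
    sum_xx = np.zeros((d, d))
    n_hist = 0
    log_scale = 0.0
    L = _adapt_cov(sum_x, sum_xx, 0, d, log_scale, cov0)

    acc_interval = 0
    accepted_total = 0
    for it in range(1, settings.n_iterations + 1):
        prop = theta + L @ rng.standard_normal(d)
        lpp = float(target(prop))
        if lpp - lp > np.log(rng.random()):
            theta = prop
            lp = lpp
            acc_interval += 1
            accepted_total += 1
        k = it - settings.burn_in
        if k > 0 and k % settings.thin == 0:
            draws[k // settings.thin - 1] = theta
            lps[k // settings.thin - 1] = lp
        if it <= settings.burn_in:
            sum_x += theta
            sum_xx += np.outer(theta, theta)
            n_hist += 1
            if it % settings.adapt_interval == 0:
                rate = acc_interval / settings.adapt_interval
                log_scale += settings.scale_gain * (rate - settings.target_accept)
                L = _adapt_cov(sum_x, sum_xx, n_hist, d, log_scale, cov0)
                acc_interval = 0
    return draws, lps, accepted_total / settings.n_iterations


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------


def gelman_rubin(chains: np.ndarray | ChainSet) -> np.ndarray:
    """Potential scale reduction factor per parameter.

    Input: (m_chains, n_draws) or (m_chains, n_draws, d). Computes
    sqrt(((n-1)/n W + B/n) / W) with W the mean within-chain variance
    and B the between-chain variance of chain means (times n).
    """
    if isinstance(chains, ChainSet):
        chains = chains.draws
    x = np.asarray(chains, dtype=float)
    squeeze = x.ndim == 2
    if squeeze:
        x = x[:, :, None]
    m, n, d = x.shape
    if m < 2:
        raise ValueError("Gelman-Rubin needs at least two chains")
    if n < 2:
        raise ValueError("Gelman-Rubin needs chains of length >= 2")
    means = x.mean(axis=1)                      # (m, d)
    W = x.var(axis=1, ddof=1).mean(axis=0)      # (d,)
    B = n * means.var(axis=0, ddof=1)           # (d,)
    var_hat = (n - 1) / n * W + B / n
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_hat / W)
    rhat = np.where(W <= 0, 1.0, rhat)          # degenerate chains count as converged
    return float(rhat[0]) if squeeze else rhat


class DicResult(NamedTuple):
    dic: float
    p_d: float
    mean_deviance: float


def dic(chains: ChainSet, log_lik: Callable[[np.ndarray], float],
        max_draws: int | None = None) -> DicResult:
    """Deviance information criterion from retained draws.

    DIC = Dbar + p_D with D(theta) = -2 log-likelihood, Dbar its
    posterior mean, and p_D = Dbar - D(posterior mean). max_draws
    optionally thins the pooled draws (evenly) before the averaging.
    """
    pooled = chains.pooled()
    if max_draws is not None and pooled.shape[0] > max_draws:
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).astype(int)
        pooled = pooled[idx]
    dev = np.array([-2.0 * log_lik(t) for t in pooled])
    dbar = float(dev.mean())
    d_at_mean = -2.0 * log_lik(pooled.mean(axis=0))
    p_d = dbar - d_at_mean
    return DicResult(dic=dbar + p_d, p_d=p_d, mean_deviance=dbar)


def posterior_summary(chains: ChainSet,
                      quantity: Callable[[np.ndarray], float] | int | str,
                      ) -> tuple[float, float, float]:
    """Median and central 95% credible interval of a derived quantity.

    ``quantity`` is a function of one draw (active-parameter vector), a
    column index, or a parameter name. Chains are pooled; returns
    (median, lower 2.5%, upper 97.5%) empirical quantiles.
    """
    pooled = chains.pooled()
    if pooled.shape[0] < 2:
        raise ValueError("need at least two retained draws")
    if isinstance(quantity, str):
        quantity = chains.param_names.index(quantity)
    if isinstance(quantity, int):
        vals = pooled[:, quantity]
    else:
        vals = np.array([quantity(t) for t in pooled])
    med, lo, hi = np.quantile(vals, [0.5, 0.025, 0.975])
    return float(med), float(lo), float(hi)


@dataclass
class PredictiveBands:
    """Per-bin posterior prediction intervals (model + observation
    noise): columns q2.5, q25, q50, q75, q97.5."""

    prevalence: np.ndarray  # (n_prev_rows, 5), on the y/n proportion scale
    incidence: np.ndarray   # (n_inc_rows, 5), per person-year

    def coverage_95(self, observed_prev: np.ndarray, observed_inc: np.ndarray) -> float:
        """Fraction of observed bins inside their 95% band."""
        ok_p = ((observed_prev >= self.prevalence[:, 0])
                & (observed_prev <= self.prevalence[:, 4]))
        ok_i = ((observed_inc >= self.incidence[:, 0])
                & (observed_inc <= self.incidence[:, 4]))
        return float(np.concatenate([ok_p, ok_i]).mean())


def posterior_predictive(chains: ChainSet, context: ModelContext,
                         seed: int = 0, max_draws: int = 2000,
                         require_converged: bool = True) -> PredictiveBands:
    """Quantile bands of replicated observations across posterior draws.

    For each draw: binomial prevalence counts with the observed n, and
    lognormal incidence with the draw's tau^2, around the model-predicted
    bin values. Unless ``require_converged=False``, demands max
    Gelman-Rubin < 1.1 across sampled parameters.
    """
    if require_converged and chains.n_chains >= 2:
        rhat = gelman_rubin(chains)
        if np.max(rhat) >= 1.1:
            raise RuntimeError(
                f"chains not converged (max Gelman-Rubin {np.max(rhat):.3f}); "
                "pass require_converged=False to force")
    pooled = chains.pooled()
    if pooled.shape[0] > max_draws:
        idx = np.linspace(0, pooled.shape[0] - 1, max_draws).astype(int)
        pooled = pooled[idx]
    rng = np.random.default_rng(seed)
    n_vec = np.array([o.n for o in context.prev_obs])
    prev_rep = np.empty((pooled.shape[0], len(context.prev_obs)))
    inc_rep = np.empty((pooled.shape[0], len(context.inc_obs)))
    tau2_col = context.active_names.index("tau2")
    for k, t in enumerate(pooled):
        pbar, ibar = context.predicted_bins(t)
        prev_rep[k] = rng.binomial(n_vec, np.clip(pbar, 0.0, 1.0)) / n_vec
        inc_rep[k] = np.exp(rng.normal(np.log(ibar), np.sqrt(t[tau2_col])))
    qs = [0.025, 0.25, 0.5, 0.75, 0.975]
    return PredictiveBands(
        prevalence=np.quantile(prev_rep, qs, axis=0).T,
        incidence=np.quantile(inc_rep, qs, axis=0).T,
    )
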