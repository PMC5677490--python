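"""Unconstrained OU: reversible-jump MCMC over regime shifts.

The trait follows an OU process whose optimum θ changes at an unknown number
of shift points placed along branches (at most one per branch); α and σ² are
shared across regimes.  A reversible-jump Metropolis–Hastings sampler moves
between shift configurations of different dimension (birth/death with the
Green acceptance ratio), slides shift locations, and updates α, σ² and the
optima.  Per-branch posterior shift probabilities are read off the thinned
post-burn-in samples; shifts at or above a posterior-probability threshold
(0.20 by default) are deemed significant and can be frozen into a fixed
regime painting for downstream AICc comparison.

Priors (all overridable): a truncated Poisson on the shift count, uniform
locations, half-Cauchy on α and on √σ² (scales in data-SD units), and a
Normal(data mean, k·data SD) on each optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from . import models
from .phylo import DatedTree, RegimePainting

__all__ = [
    "ShiftConfig",
    "ShiftSample",
    "ChainResult",
    "ShiftPosterior",
    "run_chain",
    "shift_posterior",
    "to_painting",
    "converted_model",
]

DEFAULT_THRESHOLD = 0.20


@dataclass(frozen=True)
class ShiftConfig:
    """Sampler settings and priors.

    ``n_iter`` of 1,500,000 matches a production unconstrained-OU run; tests
    use much shorter chains.  ``lam`` is the mean of the truncated-Poisson
    prior on the shift count (max ``k_max``, at most one shift per branch).
    ``alpha_scale`` and ``sigma_scale_sd`` are half-Cauchy scales for α
    (1/My) and √σ² (in units of the data SD); optima are a priori
    Normal(data mean, ``theta_sd_mult`` × data SD).
    """

    n_iter: int = 1_500_000
    burnin: float = 0.3
    thin: int = 10
    lam: float = 1.0
    k_max: int | None = None  # default: n_tips // 2
    alpha_scale: float = 1.0
    sigma_scale_sd: float = 1.0
    theta_sd_mult: float = 2.0
    move_probs: tuple[tuple[str, float], ...] = (
        ("birth", 0.2),
        ("death", 0.2),
        ("slide", 0.1),
        ("alpha", 0.15),
        ("sigma2", 0.15),
        ("theta", 0.2),
    )
    slide_sd: float = 0.15
    log_step: float = 0.4
    theta_step_sd: float = 0.5  # × data SD
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.move_probs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("move probabilities must sum to 1")
        if not (0.0 <= self.burnin < 1.0):
            raise ValueError("burn-in fraction must be in [0, 1)")


@dataclass(frozen=True)
class ShiftSample:
    """One recorded chain state: shift set plus process parameters."""

    shifts: tuple[tuple[int, float, float], ...]  # (edge id, pos in [0,1), theta)
    alpha: float
    sigma2: float
    theta_root: float
    lnL: float
    iteration: int


@dataclass
class ChainResult:
    samples: list[ShiftSample]
    acceptance: dict[str, float]
    config: ShiftConfig
    n_tips: int


def _half_cauchy_logpdf(x: float, scale: float) -> float:
    if x <= 0:
        return -math.inf
    return math.log(2.0 / (math.pi * scale * (1.0 + (x / scale) ** 2)))


class _OUShiftLikelihood:
    """Cached OU likelihood for shift configurations on a fixed tree.

    The covariance depends only on (α, σ²); shifts and optima enter the mean
    alone, so the Cholesky factor is reused across mean-only moves.
    """

    def __init__(self, tree: DatedTree, x: np.ndarray):
        self.tree = tree
        self.x = x
        self.n = tree.n_tips
        self.T = tree.height
        self.D = tree.tip_distances()
        self.Ts = tree.shared_times()
        self.edges = list(tree.edges)
        self.t0 = {e: float(tree.depth[int(tree.parent[e])]) for e in self.edges}
        self.elen = {e: float(tree.length[e]) for e in self.edges}
        self.lineages = {i: tree.lineage(t) for i, t in enumerate(tree.tips)}
        self._chol_key: tuple[float, float] | None = None
        self._chol = None
        self._logdet = 0.0

    def mean(self, shifts: dict[int, tuple[float, float]],
             alpha: float, theta_root: float) -> np.ndarray:
        a = alpha
        T = self.T
        mu = np.empty(self.n)
        for i in range(self.n):
            events = []
            for e in self.lineages[i]:
                if e in shifts:
                    pos, th = shifts[e]
                    events.append((self.t0[e] + pos * self.elen[e], th))
            events.sort()
            m = theta_root * math.exp(-a * T)
            prev_t, prev_th = 0.0, theta_root
            for t_ev, th in events:
                m += prev_th * (math.exp(-a * (T - t_ev)) - math.exp(-a * (T - prev_t)))
                prev_t, prev_th = t_ev, th
            m += prev_th * (1.0 - math.exp(-a * (T - prev_t)))
            mu[i] = m
        return mu

    def _ensure_chol(self, alpha: float, sigma2: float) -> bool:
        key = (alpha, sigma2)
        if self._chol_key == key:
            return True
        V = sigma2 / (2.0 * alpha) * np.exp(-alpha * self.D) * -np.expm1(-2.0 * alpha * self.Ts)
        try:
            c = linalg.cho_factor(V, lower=True)
        except linalg.LinAlgError:
            return False
        self._chol = c
        self._logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
        self._chol_key = key
        return True

    def loglik(self, shifts, alpha, sigma2, theta_root) -> float:
        if not self._ensure_chol(alpha, sigma2):
            return -math.inf
        r = self.x - self.mean(shifts, alpha, theta_root)
        z = linalg.cho_solve(self._chol, r)
        return float(-0.5 * (self.n * models.LOG2PI + self._logdet + r @ z))


def run_chain(
    tree: DatedTree,
    x,
    cfg: ShiftConfig,
    use_likelihood: bool = True,
) -> ChainResult:
    """Run one reversible-jump chain; deterministic under ``cfg.seed``.

    ``use_likelihood=False`` samples from the prior alone (the likelihood is
    treated as constant) — useful for validating the shift-count prior.
    """
    if cfg.n_iter < 1000:
        raise ValueError("chain length < 1000 cannot burn in; refuse to run")
    xv = models._as_vector(tree, x)
    lik = _OUShiftLikelihood(tree, xv)
    rng = np.random.default_rng(cfg.seed)

    n_tips = tree.n_tips
    k_max = cfg.k_max if cfg.k_max is not None else n_tips // 2
    edges = lik.edges
    nB = len(edges)
    data_mean = float(xv.mean())
    data_sd = float(xv.std()) or 1.0
    theta_sd = cfg.theta_sd_mult * data_sd
    sigma_scale = cfg.sigma_scale_sd * data_sd

    move_names = [m for m, _ in cfg.move_probs]
    move_p = np.array([p for _, p in cfg.move_probs])
    p_birth = dict(cfg.move_probs)["birth"]
    p_death = dict(cfg.move_probs)["death"]

    def lp_theta(th: float) -> float:
        z = (th - data_mean) / theta_sd
        return -0.5 * (z * z + math.log(2.0 * math.pi) + 2.0 * math.log(theta_sd))

    def lp_alpha(a: float) -> float:
        return _half_cauchy_logpdf(a, cfg.alpha_scale)

    def lp_sigma2(s2: float) -> float:
        s = math.sqrt(s2)
        return _half_cauchy_logpdf(s, sigma_scale) - math.log(2.0 * s)

    # initial state
    shifts: dict[int, tuple[float, float]] = {}
    alpha = 2.0 / lik.T
    sigma2 = max(float(xv.var()), 1e-8) * 2.0 * alpha
    theta_root = data_mean

    def cur_lnl() -> float:
        if not use_likelihood:
            return 0.0
        return lik.loglik(shifts, alpha, sigma2, theta_root)

    lnl = cur_lnl()
    burn_end = int(cfg.burnin * cfg.n_iter)
    samples: list[ShiftSample] = []
    proposed = {m: 0 for m in move_names}
    accepted = {m: 0 for m in move_names}

    for it in range(cfg.n_iter):
        move = move_names[rng.choice(len(move_names), p=move_p)]
        proposed[move] += 1
        k = len(shifts)
        accept = False
        if move == "birth":
            if k < min(k_max, nB):
                free = [e for e in edges if e not in shifts]
                e = free[rng.integers(len(free))]
                pos = float(rng.random())
                th = float(rng.normal(data_mean, theta_sd))
                new_lnl = (lik.loglik({**shifts, e: (pos, th)}, alpha, sigma2, theta_root)
                           if use_likelihood else 0.0)
                # θ prior cancels the prior-proposal; the uniform branch-subset
                # prior cancels the edge choice; what is left:
                log_acc = (new_lnl - lnl + math.log(cfg.lam) - math.log(k + 1)
                           + math.log(p_death / p_birth))
                if math.log(rng.random()) < log_acc:
                    shifts[e] = (pos, th)
                    lnl = new_lnl
                    accept = True
        elif move == "death":
            if k > 0:
                keys = list(shifts)
                e = keys[rng.integers(len(keys))]
                trial = {k2: v for k2, v in shifts.items() if k2 != e}
                new_lnl = (lik.loglik(trial, alpha, sigma2, theta_root)
                           if use_likelihood else 0.0)
                log_acc = (new_lnl - lnl - math.log(cfg.lam) + math.log(k)
                           + math.log(p_birth / p_death))
                if math.log(rng.random()) < log_acc:
                    shifts = trial
                    lnl = new_lnl
                    accept = True
        elif move == "slide":
            if k > 0:
                keys = list(shifts)
                e = keys[rng.integers(len(keys))]
                pos, th = shifts[e]
                newpos = pos + rng.normal(0.0, cfg.slide_sd)
                newpos = newpos % 2.0
                if newpos >= 1.0:  # reflect
                    newpos = 2.0 - newpos - 1e-12
                trial = {**shifts, e: (newpos, th)}
                new_lnl = (lik.loglik(trial, alpha, sigma2, theta_root)
                           if use_likelihood else 0.0)
                if math.log(rng.random()) < new_lnl - lnl:
                    shifts = trial
                    lnl = new_lnl
                    accept = True
        elif move == "alpha":
            a_new = alpha * math.exp(rng.normal(0.0, cfg.log_step))
            new_lnl = (lik.loglik(shifts, a_new, sigma2, theta_root)
                       if use_likelihood else 0.0)
            log_acc = (new_lnl - lnl + lp_alpha(a_new) - lp_alpha(alpha)
                       + math.log(a_new) - math.log(alpha))
            if math.log(rng.random()) < log_acc:
                alpha, lnl = a_new, new_lnl
                accept = True
        elif move == "sigma2":
            s_new = sigma2 * math.exp(rng.normal(0.0, cfg.log_step))
            new_lnl = (lik.loglik(shifts, alpha, s_new, theta_root)
                       if use_likelihood else 0.0)
            log_acc = (new_lnl - lnl + lp_sigma2(s_new) - lp_sigma2(sigma2)
                       + math.log(s_new) - math.log(sigma2))
            if math.log(rng.random()) < log_acc:
                sigma2, lnl = s_new, new_lnl
                accept = True
        else:  # theta
            targets = [None] + list(shifts)
            pick = targets[rng.integers(len(targets))]
            step = rng.normal(0.0, cfg.theta_step_sd * data_sd)
            if pick is None:
                th_new = theta_root + step
                new_lnl = (lik.loglik(shifts, alpha, sigma2, th_new)
                           if use_likelihood else 0.0)
                log_acc = new_lnl - lnl + lp_theta(th_new) - lp_theta(theta_root)
                if math.log(rng.random()) < log_acc:
                    theta_root, lnl = th_new, new_lnl
                    accept = True
            else:
                pos, th = shifts[pick]
                th_new = th + step
                trial = {**shifts, pick: (pos, th_new)}
                new_lnl = (lik.loglik(trial, alpha, sigma2, theta_root)
                           if use_likelihood else 0.0)
                log_acc = new_lnl - lnl + lp_theta(th_new) - lp_theta(th)
                if math.log(rng.random()) < log_acc:
                    shifts, lnl = trial, new_lnl
                    accept = True
        if accept:
            accepted[move] += 1
        if it >= burn_end and (it - burn_end) % cfg.thin == 0:
            samples.append(ShiftSample(
                shifts=tuple(sorted((e, p, t) for e, (p, t) in shifts.items())),
                alpha=alpha, sigma2=sigma2, theta_root=theta_root,
                lnL=lnl, iteration=it,
            ))

    rates = {m: (accepted[m] / proposed[m] if proposed[m] else math.nan)
             for m in move_names}
    return ChainResult(samples=samples, acceptance=rates, config=cfg, n_tips=n_tips)


# ---------------------------------------------------------------------------
# posterior summaries


@dataclass
class ShiftPosterior:
    """Per-branch posterior shift summaries from a thinned chain."""

    per_branch: pd.DataFrame  # index: edge id; prob, mean_pos, mean_theta
    significant: list[int]
    threshold: float
    mean_alpha: float
    mean_sigma2: float
    mean_theta_root: float
    acceptance: dict[str, float]
    ess_lnl: float
    n_samples: int


def _ess(x: np.ndarray) -> float:
    """Effective sample size via initial-positive-sequence autocorrelation."""
    n = x.size
    if n < 4 or np.allclose(x, x[0]):
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1:] / (np.arange(n, 0, -1) * xc.var())
    s = 0.0
    for t in range(1, n):
        if acf[t] <= 0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def shift_posterior(chain: ChainResult, threshold: float = DEFAULT_THRESHOLD) -> ShiftPosterior:
    """Per-branch shift probabilities and significance at ``threshold``.

    The probability for a branch is simply the fraction of post-burn-in
    samples containing a shift on it; mean position and optimum are averaged
    over those samples.
    """
    samples = chain.samples
    if not samples:
        raise ValueError("no post-burn-in samples")
    counts: dict[int, int] = {}
    pos_sum: dict[int, float] = {}
    th_sum: dict[int, float] = {}
    for s in samples:
        for e, p, t in s.shifts:
            counts[e] = counts.get(e, 0) + 1
            pos_sum[e] = pos_sum.get(e, 0.0) + p
            th_sum[e] = th_sum.get(e, 0.0) + t
    ns = len(samples)
    rows = {e: (c / ns, pos_sum[e] / c, th_sum[e] / c) for e, c in counts.items()}
    df = pd.DataFrame.from_dict(rows, orient="index",
                                columns=["prob", "mean_pos", "mean_theta"])
    df.index.name = "edge"
    df = df.sort_values("prob", ascending=False)
    sig = [int(e) for e in df.index[df["prob"] >= threshold]]
    lnls = np.array([s.lnL for s in samples])
    return ShiftPosterior(
        per_branch=df,
        significant=sig,
        threshold=threshold,
        mean_alpha=float(np.mean([s.alpha for s in samples])),
        mean_sigma2=float(np.mean([s.sigma2 for s in samples])),
        mean_theta_root=float(np.mean([s.theta_root for s in samples])),
        acceptance=chain.acceptance,
        ess_lnl=_ess(lnls),
        n_samples=ns,
    )


def to_painting(
    tree: DatedTree,
    posterior: ShiftPosterior,
    threshold: float | None = None,
) -> RegimePainting:
    """Freeze significant shifts into a fixed regime painting.

    Each significant branch starts a new regime at its posterior-mean shift
    position; descendants inherit it until a nested significant shift.  With
    no significant branch the painting is single-regime.
    """
    thr = posterior.threshold if threshold is None else threshold
    df = posterior.per_branch
    sig = {int(e): float(df.loc[e, "mean_pos"]) for e in df.index
           if df.loc[e, "prob"] >= thr}
    root_label = "root"
    # regime in force at each node, walking preorder
    regime_at: dict[int, str] = {tree.root: root_label}
    segs: dict[int, tuple[tuple[str, float], ...]] = {}
    for v in tree.preorder:
        if v == tree.root:
            continue
        parent_regime = regime_at[int(tree.parent[v])]
        L = float(tree.length[v])
        if v in sig:
            pos = min(max(sig[v], 0.0), 1.0 - 1e-9)
            new = f"shift_{v}"
            if pos <= 0.0:
                segs[v] = ((new, L),)
            else:
                segs[v] = ((parent_regime, pos * L), (new, (1.0 - pos) * L))
            regime_at[v] = new
        else:
            segs[v] = ((parent_regime, L),)
            regime_at[v] = parent_regime
    return RegimePainting(root_regime=root_label, segments=segs)


def converted_model(
    tree: DatedTree,
    posterior: ShiftPosterior,
    threshold: float | None = None,
) -> tuple[RegimePainting, models.ModelParams]:
    """Painting plus posterior-mean OU parameters for the converted model.

    The optimum of each shift regime is its posterior-mean θ; the root regime
    takes the posterior-mean root optimum; α and σ² are posterior means.
    """
    painting = to_painting(tree, posterior, threshold)
    theta = {"root": posterior.mean_theta_root}
    for reg in painting.regimes:
        if reg.startswith("shift_"):
            e = int(reg.split("_", 1)[1])
            theta[reg] = float(posterior.per_branch.loc[e, "mean_theta"])
    params = models.ModelParams(
        sigma2=posterior.mean_sigma2,
        alpha=posterior.mean_alpha,
        theta=theta,
    )
    return painting, params
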