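"""Gaussian models of continuous trait evolution on dated trees.

Six model kinds over a (possibly regime-painted) ultrametric phylogeny:

``BM1``
    single-rate Brownian motion (σ², root state);
``BMS``
    Brownian motion with a regime-specific rate σ²_r along painted branches;
``OU1``
    single-optimum Ornstein–Uhlenbeck, dX = α(θ − X)dt + σ dB;
``OUM``
    multi-optimum OU: one θ per painted regime, shared α and σ²;
``EB``
    early burst — BM whose rate decays as σ² e^{r t} with r ≤ 0;
``WN``
    white noise — tip values iid Normal, no phylogenetic signal.

All are multivariate normal at the tips; fitting profiles the linear mean
parameters and the overall scale analytically and optimises the remaining
one or few parameters (α, the EB rate, or the BMS rate ratios) numerically.
OU models use the root-at-root-regime-optimum convention by default, which
keeps the parameter counts at BM1 k=2, OU1 k=3, EB k=3, WN k=2, OUM k=2+m,
BMS k=1+m for m regimes.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .phylo import DatedTree, RegimePainting

__all__ = [
    "MODEL_KINDS",
    "ModelParams",
    "ModelFit",
    "FitConfig",
    "model_moments",
    "loglik",
    "fit",
    "simulate",
    "half_life",
    "n_parameters",
]

MODEL_KINDS = ("BM1", "BMS", "OU1", "OUM", "EB", "WN")

LOG2PI = math.log(2.0 * math.pi)


@dataclass
class ModelParams:
    """Parameters of a trait-diversification model.

    ``sigma2`` is a float (trait²/My) or, for BMS, a regime→float mapping;
    ``theta`` is a float (OU1) or regime→float mapping (OUM), in trait units;
    ``alpha`` (1/My) applies to OU kinds, ``eb_rate`` (≤ 0, 1/My) to EB;
    ``wn_mean``/``wn_var`` to WN; ``root_value`` is the ancestral state for
    BM/EB (and for OU when the root is estimated separately).
    """

    sigma2: float | Mapping[str, float] | None = None
    root_value: float = 0.0
    alpha: float | None = None
    theta: float | Mapping[str, float] | None = None
    eb_rate: float | None = None
    wn_mean: float | None = None
    wn_var: float | None = None

    def as_dict(self) -> dict:
        out: dict = {}
        for k in ("sigma2", "root_value", "alpha", "theta", "eb_rate", "wn_mean", "wn_var"):
            v = getattr(self, k)
            if v is None:
                continue
            out[k] = dict(v) if isinstance(v, Mapping) else float(v)
        return out


@dataclass
class ModelFit:
    """Result of a maximum-likelihood fit."""

    kind: str
    params: ModelParams
    lnL: float
    k: int
    n: int
    converged: bool
    data_hash: str
    painting: RegimePainting | None = None
    trace: dict = field(default_factory=dict)


@dataclass
class FitConfig:
    """Optimiser settings.

    ``restarts`` controls the coarse search grid (α / EB rate) and the number
    of multistarts for BMS; α is searched on a log scale within
    ``alpha_bounds`` (default ``(1e-6, 50/height)`` — α is weakly identified
    on 40-tip trees, so the upper bound scales with the tree).
    """

    restarts: int = 8
    alpha_bounds: tuple[float, float] | None = None
    eb_min: float | None = None  # default -10/height
    root_mode: str = "regime_theta"  # or "estimated" (OUM only)
    grid_size: int = 40
    seed: int = 0


def n_parameters(kind: str, n_regimes: int = 1) -> int:
    """Parameter count k entering AICc, per model kind."""
    if kind == "BM1":
        return 2
    if kind == "WN":
        return 2
    if kind == "OU1":
        return 3
    if kind == "EB":
        return 3
    if kind == "OUM":
        return 2 + n_regimes
    if kind == "BMS":
        return 1 + n_regimes
    raise ValueError(f"unknown model kind {kind!r}")


def _data_hash(x: np.ndarray) -> str:
    return hashlib.sha1(np.ascontiguousarray(np.round(x, 12)).tobytes()).hexdigest()[:16]


def _as_vector(tree: DatedTree, x) -> np.ndarray:
    """Align tip data (Series keyed by label, mapping, or array) to tip order."""
    if isinstance(x, pd.Series):
        return x.reindex(tree.tip_labels).to_numpy(dtype=float)
    if isinstance(x, Mapping):
        return np.array([x[lab] for lab in tree.tip_labels], dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.shape != (tree.n_tips,):
        raise ValueError(f"expected {tree.n_tips} tip values, got shape {arr.shape}")
    return arr


# ---------------------------------------------------------------------------
# moments


def _bms_cum_rates(tree: DatedTree, painting: RegimePainting) -> dict[str, np.ndarray]:
    """Per-node cumulative time spent in each regime on the root path."""
    regs = painting.regimes
    cum = {r: np.zeros(tree.n_nodes) for r in regs}
    for v in tree.preorder:
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        for r in regs:
            cum[r][v] = cum[r][p]
        for r, d in painting.segments[v]:
            cum[r][v] += d
    return cum


def _ou_weights(
    tree: DatedTree, painting: RegimePainting, alpha: float
) -> tuple[np.ndarray, list[str]]:
    """Hansen weight matrix W (tips × regimes); rows sum to 1.

    Tip expectation is ``W @ theta`` with the root placed at the root-regime
    optimum: the root contributes ``e^{-αT}`` to its own regime's column.
    """
    regs = list(painting.regimes)
    ridx = {r: j for j, r in enumerate(regs)}
    T = tree.height
    W = np.zeros((tree.n_tips, len(regs)))
    for i, lab in enumerate(tree.tip_labels):
        W[i, ridx[painting.root_regime]] += math.exp(-alpha * T)
        for r, a, b in painting.lineage_segments(tree, lab):
            W[i, ridx[r]] += math.exp(-alpha * (T - b)) - math.exp(-alpha * (T - a))
    return W, regs


def model_moments(
    tree: DatedTree,
    kind: str,
    params: ModelParams,
    painting: RegimePainting | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Tip expectation vector and covariance matrix for a model.

    OU kinds use the stationary-form covariance for ultrametric trees,
    ``σ²/(2α) e^{-α d_ij} (1 - e^{-2α t_ij})`` with ``t_ij`` the shared time
    and ``d_ij`` the patristic distance.
    """
    n = tree.n_tips
    Ts = tree.shared_times()
    if kind == "BM1":
        return np.full(n, params.root_value), float(params.sigma2) * Ts
    if kind == "WN":
        return np.full(n, params.wn_mean), float(params.wn_var) * np.eye(n)
    if kind == "EB":
        r = float(params.eb_rate)
        if r > 0:
            raise ValueError("EB rate must be <= 0")
        V = Ts.copy() if r == 0 else (np.expm1(r * Ts)) / r
        return np.full(n, params.root_value), float(params.sigma2) * V
    if kind == "BMS":
        if painting is None:
            raise ValueError("BMS requires a regime painting")
        cum = _bms_cum_rates(tree, painting)
        M = tree.mrca_matrix()
        V = np.zeros((n, n))
        s2 = dict(params.sigma2)  # type: ignore[arg-type]
        for reg, c in cum.items():
            V += s2[reg] * c[M]
        return np.full(n, params.root_value), V
    if kind in ("OU1", "OUM"):
        a = float(params.alpha)
        if a <= 0:
            raise ValueError("OU requires alpha > 0 (use BM1 for the α→0 limit)")
        s2 = float(params.sigma2)
        D = tree.tip_distances()
        V = s2 / (2.0 * a) * np.exp(-a * D) * -np.expm1(-2.0 * a * Ts)
        if kind == "OU1":
            mu = np.full(n, float(params.theta))
        else:
            if painting is None:
                raise ValueError("OUM requires a regime painting")
            W, regs = _ou_weights(tree, painting, a)
            th = dict(params.theta)  # type: ignore[arg-type]
            mu = W @ np.array([th[r] for r in regs])
        return mu, V
    raise ValueError(f"unknown model kind {kind!r}")


def loglik(x: np.ndarray, mu: np.ndarray, V: np.ndarray) -> float:
    """Multivariate-normal log density of tip values under (mu, V)."""
    x = np.asarray(x, dtype=float)
    try:
        c, low = linalg.cho_factor(V, lower=True)
    except linalg.LinAlgError as exc:
        cond = np.linalg.cond(V)
        raise linalg.LinAlgError(
            f"tip covariance is not positive definite (condition number {cond:.3g})"
        ) from exc
    r = x - mu
    z = linalg.cho_solve((c, low), r)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    return float(-0.5 * (x.size * LOG2PI + logdet + r @ z))


# ---------------------------------------------------------------------------
# fitting


def _profile_lnl(V0: np.ndarray, X: np.ndarray, x: np.ndarray, factor=None):
    """Profile lnL for x ~ N(X β, s V0), maximising β (GLS) and s (MLE).

    ``factor`` may carry a precomputed ``cho_factor(V0)``.  Returns
    (lnL, beta, s_hat); raises LinAlgError on a non-PD V0.
    """
    n = x.size
    c, low = factor if factor is not None else linalg.cho_factor(
        V0, lower=True, check_finite=False)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    B = np.column_stack([X, x])
    Bi = linalg.cho_solve((c, low), B, check_finite=False)
    Xi, xi = Bi[:, :-1], Bi[:, -1]
    A = X.T @ Xi
    b = X.T @ xi
    beta = np.linalg.solve(A, b)
    # r'V0^{-1}r expanded so no further triangular solve is needed
    quad = float(x @ xi - 2.0 * beta @ b + beta @ A @ beta)
    quad = max(quad, 1e-300)
    s = quad / n
    lnl = -0.5 * (n * LOG2PI + n * math.log(s) + logdet + n)
    return lnl, beta, s


def _refine_scalar(f, grid: np.ndarray, n_refine: int = 3):
    """Minimise f over a grid, then polish each grid-local minimum.

    Narrow interior optima can hide between grid points next to a flat
    boundary plateau, so the best few local minima are all refined.
    """
    vals = np.array([f(g) for g in grid])
    m = grid.size
    cand = [i for i in range(m)
            if (i == 0 or vals[i] <= vals[i - 1])
            and (i == m - 1 or vals[i] <= vals[i + 1])]
    cand.sort(key=lambda i: vals[i])
    best_x, best_f, ok = float(grid[np.argmin(vals)]), float(vals.min()), True
    for i in cand[:n_refine]:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, m - 1)]
        if lo == hi:
            continue
        res = optimize.minimize_scalar(f, bounds=(lo, hi), method="bounded",
                                       options={"xatol": 1e-5})
        if res.fun < best_f:
            best_x, best_f, ok = float(res.x), float(res.fun), bool(res.success)
    return best_x, best_f, ok


def fit(
    tree: DatedTree,
    x,
    kind: str,
    painting: RegimePainting | None = None,
    config: FitConfig | None = None,
) -> ModelFit:
    """Maximum-likelihood fit of one model kind to tip data.

    ``x`` may be a pandas Series keyed by tip label, a mapping, or an array
    in the tree's canonical tip order.
    """
    cfg = config or FitConfig()
    xv = _as_vector(tree, x)
    n = tree.n_tips
    if n < 2 or (n < 3 and kind not in ("BM1", "WN")):
        raise ValueError(f"too few tips (n={n}) to fit {kind}")
    T = tree.height
    Ts = tree.shared_times()
    ones = np.ones((n, 1))
    h = _data_hash(xv)

    if kind == "WN":
        m = float(xv.mean())
        v = float(np.mean((xv - m) ** 2))
        lnl = -0.5 * n * (LOG2PI + math.log(v) + 1.0)
        params = ModelParams(wn_mean=m, wn_var=v)
        return ModelFit(kind, params, lnl, n_parameters(kind), n, True, h)

    if kind == "BM1":
        factor = tree._cache.get("chol_Ts")
        if factor is None:
            factor = linalg.cho_factor(Ts, lower=True, check_finite=False)
            tree._cache["chol_Ts"] = factor
        lnl, beta, s = _profile_lnl(Ts, ones, xv, factor=factor)
        params = ModelParams(sigma2=s, root_value=float(beta[0]))
        return ModelFit(kind, params, lnl, n_parameters(kind), n, True, h)

    if kind == "EB":
        rmin = cfg.eb_min if cfg.eb_min is not None else -10.0 / T

        def nll(r: float) -> float:
            V0 = Ts if r == 0 else np.expm1(r * Ts) / r
            try:
                lnl, _, _ = _profile_lnl(V0, ones, xv)
            except linalg.LinAlgError:
                return 1e12
            return -lnl

        grid = np.linspace(rmin, 0.0, max(cfg.grid_size, 8))
        r_hat, nl, ok = _refine_scalar(nll, grid)
        V0 = Ts if r_hat == 0 else np.expm1(r_hat * Ts) / r_hat
        lnl, beta, s = _profile_lnl(V0, ones, xv)
        params = ModelParams(sigma2=s, root_value=float(beta[0]), eb_rate=r_hat)
        return ModelFit(kind, params, lnl, n_parameters(kind), n, ok, h)

    if kind in ("OU1", "OUM"):
        lo, hi = cfg.alpha_bounds if cfg.alpha_bounds else (1e-6, 50.0 / T)
        D = tree.tip_distances()
        if kind == "OUM":
            if painting is None:
                raise ValueError("OUM requires a regime painting")
            regs = list(painting.regimes)

        def design(a: float) -> np.ndarray:
            if kind == "OU1":
                return ones
            W, _ = _ou_weights(tree, painting, a)
            if cfg.root_mode == "estimated":
                W = np.column_stack([W, np.full(n, math.exp(-a * T))])
            return W

        def nll(loga: float) -> float:
            a = math.exp(loga)
            V0 = np.exp(-a * D) * -np.expm1(-2.0 * a * Ts) / (2.0 * a)
            try:
                lnl, _, _ = _profile_lnl(V0, design(a), xv)
            except (linalg.LinAlgError, np.linalg.LinAlgError):
                return 1e12
            return -lnl

        grid = np.linspace(math.log(lo), math.log(hi), max(cfg.grid_size, 8))
        loga, nl, ok = _refine_scalar(nll, grid)
        a = math.exp(loga)
        V0 = np.exp(-a * D) * -np.expm1(-2.0 * a * Ts) / (2.0 * a)
        lnl, beta, s = _profile_lnl(V0, design(a), xv)
        if kind == "OU1":
            params = ModelParams(sigma2=s, alpha=a, theta=float(beta[0]))
            k = n_parameters(kind)
        else:
            th = {r: float(b) for r, b in zip(regs, beta)}
            params = ModelParams(sigma2=s, alpha=a, theta=th)
            if cfg.root_mode == "estimated":
                params.root_value = float(beta[-1])
            k = n_parameters(kind, len(regs))
        at_bound = min(abs(loga - math.log(lo)), abs(loga - math.log(hi))) < 1e-6
        return ModelFit(kind, params, lnl, k, n, ok and not at_bound, h,
                        painting=painting, trace={"alpha_at_bound": at_bound})

    if kind == "BMS":
        if painting is None:
            raise ValueError("BMS requires a regime painting")
        cum = _bms_cum_rates(tree, painting)
        regs = list(painting.regimes)
        M = tree.mrca_matrix()
        comps = [cum[r][M] for r in regs]
        m = len(regs)

        def nll(g: np.ndarray) -> float:
            # sigma2_r proportional to exp(g_r); overall scale profiled
            w = np.exp(g - g.max())
            V0 = sum(wi * C for wi, C in zip(w, comps))
            try:
                lnl, _, _ = _profile_lnl(V0, ones, xv)
            except linalg.LinAlgError:
                return 1e12
            return -lnl

        rng = np.random.default_rng(cfg.seed)
        best = None
        results = []
        starts = [np.zeros(m)] + [rng.normal(0.0, 1.5, size=m) for _ in range(cfg.restarts - 1)]
        for g0 in starts:
            res = optimize.minimize(nll, g0, method="L-BFGS-B")
            results.append(res)
            if best is None or res.fun < best.fun:
                best = res
        assert best is not None
        g = best.x - best.x.max()
        w = np.exp(g)
        V0 = sum(wi * C for wi, C in zip(w, comps))
        lnl, beta, s = _profile_lnl(V0, ones, xv)
        sigma2 = {r: float(s * wi) for r, wi in zip(regs, w)}
        converged = bool(best.success)
        params = ModelParams(sigma2=sigma2, root_value=float(beta[0]))
        return ModelFit(kind, params, lnl, n_parameters(kind, m), n, converged, h,
                        painting=painting)

    raise ValueError(f"unknown model kind {kind!r}")


def simulate(
    tree: DatedTree,
    kind: str,
    params: ModelParams,
    painting: RegimePainting | None = None,
    seed: int | np.random.Generator = 0,
) -> pd.Series:
    """Draw one tip-value vector from a model's exact multivariate normal.

    Returns a Series keyed by tip label; identical seeds give identical draws.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu, V = model_moments(tree, kind, params, painting)
    # jitter-free Cholesky; degenerate (σ²→0) covariances fall back to eigh
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        w, U = np.linalg.eigh(V)
        w = np.clip(w, 0.0, None)
        L = U * np.sqrt(w)
    x = mu + L @ rng.standard_normal(mu.size)
    return pd.Series(x, index=tree.tip_labels, name="trait")


def half_life(alpha: float) -> float:
    """Phylogenetic half-life t½ = ln(2)/α in My.

    Time for the expected trait value to move halfway to the optimum; under
    BM (α = 0) the half-life is infinite and this function refuses rather
    than returning ∞.
    """
    if alpha <= 0:
        raise ValueError("half-life requires alpha > 0 (BM has no finite half-life)")
    return math.log(2.0) / alpha
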