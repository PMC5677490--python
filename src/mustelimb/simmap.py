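"""Mk models for discrete habits and stochastic character mapping.

The locomotor habit (generalized / scansorial / fossorial / natatorial) is a
4-state Markov chain on the tree.  An Mk rate matrix is fitted by maximum
likelihood with Felsenstein pruning, then full character histories are drawn
conditional on the observed tip states: ancestral states are sampled jointly
from the pruning partials and each edge's path is completed by
endpoint-conditioned CTMC simulation (rejection sampling with a
uniformization fallback).  Each sampled history is a
:class:`~mustelimb.phylo.RegimePainting` carrying its own change points.

Regime-dependent trait models (BMS/OUM) are then fitted per mapping and
their parameters averaged across mappings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import linalg, optimize

from . import models
from .phylo import DatedTree, RegimePainting

__all__ = [
    "HABIT_STATES",
    "MkModel",
    "MappingSample",
    "AveragedFit",
    "fit_mk",
    "mk_loglik",
    "sample_mappings",
    "fit_over_mappings",
]

HABIT_STATES = ("generalized", "scansorial", "fossorial", "natatorial")

_MAX_RATE = 1e3  # 1/My; beyond this, path sampling is numerically pointless


@dataclass(frozen=True)
class MkModel:
    """Continuous-time Markov model of a discrete character.

    ``Q`` is the generator (off-diagonals ≥ 0, rows sum to 0, units 1/My)
    over ``states``; ``structure`` is ``"ER"`` (equal rates, one free
    parameter) or ``"ARD"`` (all rates different).
    """

    states: tuple[str, ...]
    Q: np.ndarray
    structure: str = "ER"
    lnL: float = math.nan

    def __post_init__(self) -> None:
        Q = np.asarray(self.Q, dtype=float)
        if Q.shape != (len(self.states),) * 2:
            raise ValueError("Q shape does not match the state set")
        off = Q.copy()
        np.fill_diagonal(off, 0.0)
        if (off < -1e-12).any():
            raise ValueError("off-diagonal Mk rates must be non-negative")
        if np.abs(Q.sum(axis=1)).max() > 1e-9:
            raise ValueError("Mk generator rows must sum to zero")


def _er_generator(rate: float, k: int) -> np.ndarray:
    Q = np.full((k, k), rate)
    np.fill_diagonal(Q, -(k - 1) * rate)
    return Q


def _tip_state_array(tree: DatedTree, tip_states: Mapping[str, str],
                     states: Sequence[str]) -> np.ndarray:
    idx = {s: i for i, s in enumerate(states)}
    out = np.empty(tree.n_tips, dtype=np.int64)
    for i, lab in enumerate(tree.tip_labels):
        if lab not in tip_states:
            raise ValueError(f"tip {lab!r} has no observed state")
        try:
            out[i] = idx[tip_states[lab]]
        except KeyError:
            raise ValueError(f"unknown state {tip_states[lab]!r} for tip {lab!r}") from None
    return out


def _partials(tree: DatedTree, tips_idx: np.ndarray, Q: np.ndarray):
    """Felsenstein pruning: per-node conditional likelihoods and edge P(t)."""
    k = Q.shape[0]
    P = {e: linalg.expm(Q * float(tree.length[e])) for e in tree.edges}
    L = np.zeros((tree.n_nodes, k))
    tip_pos = {node: i for i, node in enumerate(tree.tips)}
    for v in tree.postorder:
        if not tree.children[v]:
            L[v, tips_idx[tip_pos[v]]] = 1.0
        else:
            L[v] = 1.0
            for c in tree.children[v]:
                L[v] *= P[c] @ L[c]
    return L, P


def mk_loglik(tree: DatedTree, tip_states: Mapping[str, str], Q: np.ndarray,
              states: Sequence[str] = HABIT_STATES) -> float:
    """Pruning log-likelihood of tip states under generator Q (uniform root)."""
    tips_idx = _tip_state_array(tree, tip_states, states)
    L, _ = _partials(tree, tips_idx, Q)
    root_mass = L[tree.root].mean()  # uniform prior over states
    if root_mass <= 0:
        return -math.inf
    return float(math.log(root_mass))


def fit_mk(
    tree: DatedTree,
    tip_states: Mapping[str, str],
    structure: str = "ER",
    states: Sequence[str] = HABIT_STATES,
) -> MkModel:
    """ML Mk fit; a state absent from the tips is retained with a warning."""
    import warnings

    observed = set(tip_states.values())
    for s in states:
        if s not in observed:
            warnings.warn(f"state {s!r} is absent from the tips; retained in the model",
                          stacklevel=2)
    k = len(states)
    if structure == "ER":

        def nll(logq: float) -> float:
            return -mk_loglik(tree, tip_states, _er_generator(math.exp(logq), k), states)

        grid = np.linspace(math.log(1e-8), math.log(50.0 / tree.height), 30)
        logq, nl, _ = models._refine_scalar(nll, grid)
        q = math.exp(logq)
        return MkModel(tuple(states), _er_generator(q, k), "ER", lnL=-nl)

    if structure == "ARD":
        npar = k * (k - 1)

        def build(logr: np.ndarray) -> np.ndarray:
            Q = np.zeros((k, k))
            rates = np.exp(logr)
            pos = 0
            for i in range(k):
                for j in range(k):
                    if i != j:
                        Q[i, j] = rates[pos]
                        pos += 1
            np.fill_diagonal(Q, -Q.sum(axis=1))
            return Q

        def nll(logr: np.ndarray) -> float:
            return -mk_loglik(tree, tip_states, build(logr), states)

        x0 = np.full(npar, math.log(0.1 / tree.height * k))
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(math.log(1e-8), math.log(100.0))] * npar)
        return MkModel(tuple(states), build(res.x), "ARD", lnL=-res.fun)

    raise ValueError(f"unknown Mk structure {structure!r}")


# ---------------------------------------------------------------------------
# stochastic mapping


@dataclass(frozen=True)
class MappingSample:
    """One sampled character history: a painting with sampled change points."""

    painting: RegimePainting
    node_states: dict[int, str]
    index: int
    seed: int


def _sample_path_rejection(Q, a, b, t, rng, max_tries=100):
    """Endpoint-conditioned CTMC path by (Nielsen-style) rejection.

    For unequal endpoints the first jump time is drawn from the truncated
    exponential so paths with at least one change are proposed directly.
    Returns a list of (state, duration) or None if all tries fail.
    """
    k = Q.shape[0]
    for _ in range(max_tries):
        path = [(a, 0.0)]
        s, tau = a, 0.0
        if a != b:
            rate = -Q[a, a]
            if rate <= 0:
                return None
            u = rng.random()
            tau = -math.log(1.0 - u * (1.0 - math.exp(-rate * t))) / rate
            probs = Q[a].copy()
            probs[a] = 0.0
            s = rng.choice(k, p=probs / probs.sum())
            path = [(a, tau), (s, 0.0)]
        while True:
            rate = -Q[s, s]
            dt = math.inf if rate <= 0 else rng.exponential(1.0 / rate)
            if tau + dt >= t:
                break
            tau += dt
            probs = Q[s].copy()
            probs[s] = 0.0
            s_new = int(rng.choice(k, p=probs / probs.sum()))
            path[-1] = (path[-1][0], tau - sum(d for _, d in path[:-1]))
            path.append((s_new, 0.0))
            s = s_new
        if s == b:
            path[-1] = (path[-1][0], t - sum(d for _, d in path[:-1]))
            return [(st, d) for st, d in path if d > 0]
    return None


def _sample_path_uniformization(Q, a, b, t, rng, max_jumps=512):
    """Endpoint-conditioned path by uniformization (always succeeds)."""
    k = Q.shape[0]
    mu = max(-Q.diagonal().min(), 1e-12)
    R = np.eye(k) + Q / mu
    Pt = linalg.expm(Q * t)
    pab = Pt[a, b]
    # sample the number of uniformized jumps N | a, b, t
    powers = [np.eye(k)]
    u = rng.random() * pab
    n, acc = 0, 0.0
    log_pois = -mu * t
    while True:
        acc += math.exp(log_pois) * powers[-1][a, b]
        if acc >= u or n >= max_jumps:
            break
        n += 1
        log_pois += math.log(mu * t) - math.log(n)
        powers.append(powers[-1] @ R)
    # sample the uniformized state sequence backwards-consistently
    states = [a]
    for i in range(1, n):
        back = powers[n - i]
        w = R[states[-1]] * back[:, b]
        states.append(int(rng.choice(k, p=w / w.sum())))
    if n >= 1:
        states.append(b)
    times = np.sort(rng.random(n)) * t if n else np.array([])
    # collapse virtual (self) jumps into dwell segments
    segs: list[tuple[int, float]] = []
    prev_t = 0.0
    cur = a
    for s, tt in zip(states[1:], times):
        if s != cur:
            segs.append((cur, tt - prev_t))
            prev_t = tt
            cur = s
    segs.append((cur, t - prev_t))
    return [(s, d) for s, d in segs if d > 0]


def sample_mappings(
    tree: DatedTree,
    tip_states: Mapping[str, str],
    mk: MkModel,
    n_samples: int,
    seed: int = 0,
) -> list[MappingSample]:
    """Draw stochastic character mappings conditional on the tip states.

    Node states are sampled jointly from the pruning partials (uniform root
    prior), then each edge's history is completed by endpoint-conditioned
    path sampling.  Reproducible under ``seed``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if (-np.diag(mk.Q)).max() > _MAX_RATE:
        raise ValueError(f"Mk rates exceed {_MAX_RATE}/My; mapping is ill-posed")
    states = mk.states
    k = len(states)
    tips_idx = _tip_state_array(tree, tip_states, states)
    L, P = _partials(tree, tips_idx, mk.Q)
    rng = np.random.default_rng(seed)
    out: list[MappingSample] = []
    for m in range(n_samples):
        node_state: dict[int, int] = {}
        w = L[tree.root].copy()  # × uniform prior
        node_state[tree.root] = int(rng.choice(k, p=w / w.sum()))
        for v in tree.preorder:
            for c in tree.children[v]:
                w = P[c][node_state[v]] * L[c]
                node_state[c] = int(rng.choice(k, p=w / w.sum()))
        segs: dict[int, tuple[tuple[str, float], ...]] = {}
        for e in tree.edges:
            a, b = node_state[int(tree.parent[e])], node_state[e]
            t = float(tree.length[e])
            path = _sample_path_rejection(mk.Q, a, b, t, rng)
            if path is None:
                path = _sample_path_uniformization(mk.Q, a, b, t, rng)
            segs[e] = tuple((states[s], d) for s, d in path)
        painting = RegimePainting(root_regime=states[node_state[tree.root]],
                                  segments=segs)
        out.append(MappingSample(
            painting=painting,
            node_states={v: states[s] for v, s in node_state.items()},
            index=m,
            seed=seed,
        ))
    return out


# ---------------------------------------------------------------------------
# averaging trait-model fits over mappings


@dataclass
class AveragedFit:
    """BMS/OUM fits averaged over stochastic mappings.

    ``mean_params`` holds the arithmetic mean of each parameter across the
    converged per-mapping fits; ``lnL`` is the mean log-likelihood; the full
    per-mapping fit list is retained for dispersion summaries.
    """

    kind: str
    fits: list[models.ModelFit]
    mean_params: dict
    lnL: float
    k: int
    n: int
    n_mappings: int
    n_excluded: int

    @property
    def converged(self) -> bool:
        return self.n_excluded < self.n_mappings


def _mean_of_params(dicts: list[dict]) -> dict:
    out: dict = {}
    for key in dicts[0]:
        vals = [d[key] for d in dicts if key in d]
        if isinstance(vals[0], Mapping):
            keys2 = set().union(*[v.keys() for v in vals])
            out[key] = {k2: float(np.mean([v[k2] for v in vals if k2 in v]))
                        for k2 in keys2}
        else:
            out[key] = float(np.mean(vals))
    return out


def fit_over_mappings(
    tree: DatedTree,
    samples: Sequence[MappingSample],
    x,
    kind: str,
    config: models.FitConfig | None = None,
) -> AveragedFit:
    """Fit a regime-dependent model per mapping and average the parameters.

    Non-converged per-mapping fits are excluded from the means (their count
    is reported) rather than imputed.
    """
    if kind not in ("BMS", "OUM"):
        raise ValueError("only BMS and OUM are averaged over mappings")
    if not samples:
        raise ValueError("no mapping samples supplied")
    fits = [models.fit(tree, x, kind, painting=s.painting, config=config)
            for s in samples]
    good = [f for f in fits if f.converged]
    used = good if good else fits
    mean_params = _mean_of_params([f.params.as_dict() for f in used])
    return AveragedFit(
        kind=kind,
        fits=fits,
        mean_params=mean_params,
        lnL=float(np.mean([f.lnL for f in used])),
        k=used[0].k,
        n=used[0].n,
        n_mappings=len(samples),
        n_excluded=len(fits) - len(good),
    )
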