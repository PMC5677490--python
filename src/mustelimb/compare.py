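"""AICc model comparison tables.

Small-sample Akaike information criterion, ΔAICc, relative likelihoods and
Akaike weights for a set of fitted trait-diversification models, with
phylogenetic half-life annotations on OU rows.  Internal arithmetic is full
precision; rounding happens only at presentation (AICc and Δ to 1 d.p.,
relative likelihood to 4 d.p., weight as a percentage to 1 d.p.).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import models
from .simmap import AveragedFit

__all__ = ["aicc", "delta_and_weights", "build_table", "ComparisonTable"]


def aicc(lnL: float, k: int, n: int) -> float:
    """AICc = −2 lnL + 2k + 2k(k+1)/(n−k−1); requires n > k + 1."""
    if k < 1:
        raise ValueError("parameter count k must be >= 1")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * lnL + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def delta_and_weights(aiccs: Sequence[float]):
    """ΔAICc, relative likelihoods exp(−Δ/2), and normalised Akaike weights."""
    a = np.asarray(aiccs, dtype=float)
    if a.size < 1:
        raise ValueError("need at least one AICc value")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    return delta, rel, rel / rel.sum()


@dataclass
class ComparisonTable:
    """Assembled model-comparison table (input row order preserved)."""

    table: pd.DataFrame
    best: str
    n: int

    def to_markdown(self) -> str:
        df = self.table.copy()
        out = pd.DataFrame(index=df.index)
        out["L"] = df["lnL"].map(lambda v: f"{v:.1f}")
        out["Rel.L"] = df["rel_likelihood"].map(lambda v: f"{v:.4f}")
        out["AICc"] = df["aicc"].map(lambda v: f"{v:.1f}")
        out["dAICc"] = df["delta"].map(lambda v: f"{v:.1f}")
        out["Weight(%)"] = df["weight"].map(lambda v: f"{100 * v:.1f}")
        out["k"] = df["k"]
        out["t_half(My)"] = df["half_life"].map(
            lambda v: "-" if not np.isfinite(v) else f"{v:.2f}")
        out["best"] = ["*" if i == self.best else "" for i in df.index]
        return out.to_markdown()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)


def build_table(fits: Sequence, labels: Sequence[str] | None = None) -> ComparisonTable:
    """AICc comparison of fitted models (``ModelFit`` or ``AveragedFit``).

    All fits must share the sample size n.  The best model minimises AICc;
    ties break toward smaller k.  OU rows carry the half-life ln2/α̂.
    """
    if not fits:
        raise ValueError("no fits supplied")
    if labels is None:
        labels = [f.kind for f in fits]
    if len(labels) != len(set(labels)):
        raise ValueError("model labels must be unique")
    ns = {f.n for f in fits}
    if len(ns) != 1:
        raise ValueError(f"fits disagree on sample size n: {sorted(ns)}")
    n = ns.pop()
    rows = []
    for lab, f in zip(labels, fits):
        a = aicc(f.lnL, f.k, n)
        if isinstance(f, AveragedFit):
            alpha = f.mean_params.get("alpha")
        else:
            alpha = f.params.alpha
        hl = models.half_life(alpha) if alpha and alpha > 0 else math.inf
        rows.append((lab, f.lnL, f.k, a, hl, f.converged))
    df = pd.DataFrame(rows, columns=["model", "lnL", "k", "aicc", "half_life",
                                     "converged"]).set_index("model")
    delta, rel, w = delta_and_weights(df["aicc"].to_numpy())
    df["delta"], df["rel_likelihood"], df["weight"] = delta, rel, w
    best_aicc = df["aicc"].min()
    cand = df[df["aicc"] == best_aicc]
    best = cand.sort_values("k").index[0]
    return ComparisonTable(table=df, best=str(best), n=n)
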