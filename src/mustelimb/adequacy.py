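"""Phylogenetic Monte-Carlo model-adequacy testing.

Parametric bootstrap of the likelihood-ratio statistic between a best-fit
model and the single-rate Brownian-motion null: data are simulated under each
fitted model, both models are refitted to every simulated dataset, and two
95% percentile confidence intervals of the LR are formed — one per generating
model.  The observed LR acts as a critical value: falling inside the null CI
means the data are indistinguishable from the null; inside the best-fit CI
means the best model is adequate; outside both flags a tree too small (or a
model set too poor) to discriminate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import models
from .models import FitConfig, ModelFit, ModelParams
from .phylo import DatedTree, RegimePainting

__all__ = ["ModelSpec", "AdequacyResult", "lr_statistic", "pmc_test"]


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model: kind plus (for regime kinds) its painting."""

    kind: str
    painting: RegimePainting | None = None


@dataclass
class AdequacyResult:
    observed_lr: float
    null_ci: tuple[float, float]
    alt_ci: tuple[float, float]
    n_iter: int
    lr_null: np.ndarray
    lr_alt: np.ndarray
    verdict: str  # consistent-with-null | consistent-with-best | outside-both
    n_failed: int
    fit_null: ModelFit
    fit_alt: ModelFit


def lr_statistic(fit_alt: ModelFit, fit_null: ModelFit) -> float:
    """LR = 2 (lnL_alt − lnL_null); may be negative for non-nested misfits."""
    if fit_alt.data_hash != fit_null.data_hash:
        raise ValueError("fits were computed on different data")
    return 2.0 * (fit_alt.lnL - fit_null.lnL)


def _verdict(lr: float, null_ci, alt_ci) -> str:
    in_null = null_ci[0] <= lr <= null_ci[1]
    in_alt = alt_ci[0] <= lr <= alt_ci[1]
    if in_null:
        return "consistent-with-null"
    if in_alt:
        return "consistent-with-best"
    return "outside-both"


def pmc_test(
    tree: DatedTree,
    x,
    null_spec: ModelSpec,
    alt_spec: ModelSpec,
    n_iter: int = 10_000,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    max_failed_frac: float = 0.05,
) -> AdequacyResult:
    """Monte-Carlo LR adequacy test of ``alt_spec`` against ``null_spec``.

    Per iteration: simulate under the fitted null, refit both models, record
    the LR; likewise under the fitted alternative.  95% percentile CIs come
    from the two LR vectors.  Refits use a lighter optimiser grid than the
    observed-data fits; iterations whose refits fail are dropped and counted
    (more than ``max_failed_frac`` failing is an error).
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100 for a stable 95% CI")
    cfg = fit_config or FitConfig(restarts=3, grid_size=24)
    f_null = models.fit(tree, x, null_spec.kind, painting=null_spec.painting, config=cfg)
    f_alt = models.fit(tree, x, alt_spec.kind, painting=alt_spec.painting, config=cfg)
    observed = lr_statistic(f_alt, f_null)

    rng = np.random.default_rng(seed)
    lr_vectors: dict[str, list[float]] = {"null": [], "alt": []}
    failed = 0
    for which, gen in (("null", f_null), ("alt", f_alt)):
        mu, V = models.model_moments(tree, gen.kind, gen.params, gen.painting)
        L = np.linalg.cholesky(V)
        for _ in range(n_iter):
            sim = mu + L @ rng.standard_normal(mu.size)
            try:
                r0 = models.fit(tree, sim, null_spec.kind,
                                painting=null_spec.painting, config=cfg)
                r1 = models.fit(tree, sim, alt_spec.kind,
                                painting=alt_spec.painting, config=cfg)
            except Exception:
                failed += 1
                continue
            lr_vectors[which].append(2.0 * (r1.lnL - r0.lnL))
    if failed > max_failed_frac * 2 * n_iter:
        raise RuntimeError(
            f"{failed}/{2 * n_iter} adequacy refits failed; "
            "check the model specifications and optimiser settings"
        )
    lr_null = np.asarray(lr_vectors["null"])
    lr_alt = np.asarray(lr_vectors["alt"])
    null_ci = tuple(np.percentile(lr_null, [2.5, 97.5]))
    alt_ci = tuple(np.percentile(lr_alt, [2.5, 97.5]))
    return AdequacyResult(
        observed_lr=observed,
        null_ci=null_ci,  # type: ignore[arg-type]
        alt_ci=alt_ci,  # type: ignore[arg-type]
        n_iter=n_iter,
        lr_null=lr_null,
        lr_alt=lr_alt,
        verdict=_verdict(observed, null_ci, alt_ci),
        n_failed=failed,
        fit_null=f_null,
        fit_alt=f_alt,
    )
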