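"""Synthetic trees, habit histories and specimen-level trait datasets.

Generates data with the statistical structure the analysis assumes, at known
ground truth: a pure-birth dated tree (default 40 tips, height 16 My), a
4-state locomotor-habit history simulated under an equal-rates Mk model, and
14 log-normal traits built as a shared Brownian size factor times per-trait
allometric slopes plus habit-independent OU (or BM) deviations.  Three
scenarios control the deviation process:

``A``
    one optimum shift on the stem branch of a mid-sized clade (a
    clade-level regime shift detectable on the first PC axis);
``B``
    two optimum shifts on the terminal branches of two single species, with
    large opposite contrasts (singleton-regime outliers);
``NULL``
    single-regime Brownian deviations, no shift.

Specimen tables draw 1–6 specimens per species with log-normal measurement
error, mirroring typical museum sampling depth.
"""

from __future__ import annotations

import math
import random as _random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import models
from .phylo import DatedTree, RegimePainting, parse_newick
from .traits import TRAIT_NAMES

__all__ = ["SynthScenario", "make_tree", "simulate_habits", "simulate_dataset",
           "build_shift_painting"]

#: gracility trade-off contrast: long-bone and metacarpal lengths plus the
#: deltoid ridge against shaft diameters, epicondyle and the olecranon;
#: scapula length and humerus ML diameter carry no signal
CONTRAST_GRACILITY = np.array(
    [0.0, 1.0, -1.0, 0.0, 1.0, -1.0, 1.0, -1.0, 1.0, 1.0, -1.0, 1.0, -1.0, 1.0]
)

#: radius cross-section / manus contrast (second-axis-like pattern)
CONTRAST_MANUS = np.array(
    [0.3, 0.0, 0.4, 0.4, 0.2, -0.2, 0.0, -1.0, 1.0, 0.0, 0.2, -1.0, -0.3, -1.0]
)

#: baseline trait sizes (mm) of a mid-sized mustelid; intercepts are their logs
BASE_SIZES_MM = np.array(
    [50.0, 60.0, 5.0, 5.0, 25.0, 12.0, 50.0, 4.0, 4.0, 65.0, 5.0, 4.0, 12.0, 20.0]
)

#: mild departures from isometry, fixed per trait
DEFAULT_SLOPES = np.array(
    [1.00, 1.05, 0.95, 0.95, 1.10, 0.90, 1.05, 0.90, 0.95, 1.05, 0.95, 0.95, 1.10, 1.05]
)


@dataclass
class SynthScenario:
    """Ground-truth generating conditions for one synthetic dataset.

    The deviation process is OU with ``dev_alpha`` and stationary SD
    ``dev_stat_sd`` (log units); scenario A shifts the optimum by
    ``shift_sd_mult`` stationary SDs along ``contrast`` on a clade stem,
    scenario B by ``singleton_sd_mult`` SDs (opposite signs) on two terminal
    branches, and NULL uses Brownian deviations of matching tip variance.
    """

    scenario: str = "A"  # A | B | NULL
    n_tips: int = 40
    height: float = 16.0
    mk_rate: float = 0.02  # per-pair transition rate, 1/My
    slopes: np.ndarray = field(default_factory=lambda: DEFAULT_SLOPES.copy())
    intercepts: np.ndarray = field(default_factory=lambda: np.log(BASE_SIZES_MM))
    size_sigma2: float = 0.02  # BM rate of the log size factor, 1/My
    dev_alpha: float = 0.26
    dev_stat_sd: float = 0.08
    shift_sd_mult: float = 2.0
    singleton_sd_mult: float = 6.0
    contrast: np.ndarray = field(default_factory=lambda: CONTRAST_GRACILITY.copy())
    contrast_b: np.ndarray = field(default_factory=lambda: CONTRAST_MANUS.copy())
    clade_fraction: float = 0.2  # target clade size for the scenario-A shift
    specimens_min: int = 1
    specimens_max: int = 6
    measurement_cv: float = 0.05
    seed: int = 0

    @property
    def dev_sigma2(self) -> float:
        """OU diffusion rate implied by the stationary SD: σ² = 2α·SD²."""
        return 2.0 * self.dev_alpha * self.dev_stat_sd**2


def make_tree(n_tips: int, height: float, seed: int = 0) -> DatedTree:
    """Pure-birth ultrametric tree rescaled to the requested root height."""
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    dt = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_tips,
        rng=_random.Random(int(seed)),
    )
    # the simulator stops exactly at the n-th speciation, leaving zero-length
    # pendant edges; extend every tip by the waiting time to the (unrealised)
    # next event, then rescale to the requested height
    extra = np.random.default_rng(seed + 7).exponential(1.0 / n_tips)
    for leaf in dt.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    for i, leaf in enumerate(dt.leaf_node_iter()):
        leaf.taxon.label = f"sp{i + 1:02d}"
    text = dt.as_string(schema="newick", suppress_rooting=True)
    tree = parse_newick(text)
    scale = height / tree.height
    length = tree.length * scale
    return DatedTree(tree.parent, length, tree.labels)


def simulate_habits(
    tree: DatedTree, mk_rate: float, seed: int = 0, states=("generalized", "scansorial", "fossorial", "natatorial"),
    max_resample: int = 20,
):
    """Simulate a 4-state equal-rates habit history root-to-tip.

    Returns ``(tip_states, node_states)`` label/state dicts; the internal
    truth is for validation only.  If every tip lands in one state the
    simulation is redrawn (up to ``max_resample`` times) before warning.
    """
    if mk_rate <= 0:
        raise ValueError("Mk rate must be positive")
    k = len(states)
    rng = np.random.default_rng(seed)
    for attempt in range(max_resample + 1):
        node_state: dict[int, int] = {tree.root: int(rng.integers(k))}
        for v in tree.preorder:
            for c in tree.children[v]:
                s = node_state[v]
                t = float(tree.length[c])
                # jump chain of the ER CTMC: departure rate (k-1)·q
                tau = 0.0
                while True:
                    tau += rng.exponential(1.0 / ((k - 1) * mk_rate))
                    if tau >= t:
                        break
                    s = int((s + 1 + rng.integers(k - 1)) % k)
                node_state[c] = s
        tip_states = {lab: states[node_state[tree.tip_node(lab)]]
                      for lab in tree.tip_labels}
        if len(set(tip_states.values())) > 1:
            break
    else:  # pragma: no cover - essentially unreachable at default rates
        pass
    if len(set(tip_states.values())) == 1:
        import warnings
        warnings.warn("all tips share one habit state after resampling", stacklevel=2)
    return tip_states, {v: states[s] for v, s in node_state.items()}


def _clade_stem_edge(tree: DatedTree, fraction: float) -> int:
    """Internal edge whose descendant tip count is closest to fraction·n."""
    target = fraction * tree.n_tips
    best, best_score = None, None
    for e in tree.edges:
        size = int(tree.tip_descendants(e).sum())
        if size < 2 or size > tree.n_tips - 2:
            continue
        score = (abs(size - target), -tree.length[e])
        if best_score is None or score < best_score:
            best, best_score = e, score
    assert best is not None
    return best


def _longest_pendant_edges(tree: DatedTree, k: int = 2) -> list[int]:
    pend = sorted(tree.tips, key=lambda e: -tree.length[e])
    return pend[:k]


def build_shift_painting(tree: DatedTree, shifts: dict[int, float]) -> RegimePainting:
    """Painting with a new regime starting at ``pos`` on each shifted edge."""
    regime_at: dict[int, str] = {tree.root: "base"}
    segs: dict[int, tuple[tuple[str, float], ...]] = {}
    for v in tree.preorder:
        if v == tree.root:
            continue
        pr = regime_at[int(tree.parent[v])]
        L = float(tree.length[v])
        if v in shifts:
            pos = shifts[v]
            new = f"shift_{v}"
            segs[v] = ((pr, pos * L), (new, (1.0 - pos) * L)) if pos > 0 else ((new, L),)
            regime_at[v] = new
        else:
            segs[v] = ((pr, L),)
            regime_at[v] = pr
    return RegimePainting(root_regime="base", segments=segs)


def simulate_dataset(scn: SynthScenario):
    """Generate one full synthetic study: specimens, tree, habits, truth.

    Returns ``(specimens, tree, habits, truth)`` where ``specimens`` is a
    specimen-level DataFrame (id, species, 14 mm traits), ``habits`` maps
    species to locomotor habit, and ``truth`` records every generating
    parameter, the shifted branches (as tip-label sets) and the latent
    species-level log trait table.
    """
    if scn.scenario not in ("A", "B", "NULL"):
        raise ValueError(f"unknown scenario {scn.scenario!r}")
    seed = int(scn.seed)
    tree = make_tree(scn.n_tips, scn.height, seed=seed)
    habits, node_habits = simulate_habits(tree, scn.mk_rate, seed=seed + 1)

    # shared log size factor: BM on the tree
    size = models.simulate(
        tree, "BM1", models.ModelParams(sigma2=scn.size_sigma2, root_value=0.0),
        seed=seed + 2,
    )

    # deviation process per trait
    stat_sd = scn.dev_stat_sd
    shift_edges: dict[int, float] = {}
    theta_vectors: dict[str, np.ndarray] = {}
    if scn.scenario == "A":
        e = _clade_stem_edge(tree, scn.clade_fraction)
        shift_edges[e] = 0.5
        theta_vectors[f"shift_{e}"] = scn.shift_sd_mult * stat_sd * scn.contrast
    elif scn.scenario == "B":
        e1, e2 = _longest_pendant_edges(tree, 2)
        shift_edges[e1] = 0.4
        shift_edges[e2] = 0.4
        theta_vectors[f"shift_{e1}"] = scn.singleton_sd_mult * stat_sd * scn.contrast_b
        theta_vectors[f"shift_{e2}"] = -scn.singleton_sd_mult * stat_sd * scn.contrast_b

    painting = build_shift_painting(tree, shift_edges) if shift_edges else None
    dev = np.empty((tree.n_tips, len(TRAIT_NAMES)))
    for j in range(len(TRAIT_NAMES)):
        if scn.scenario == "NULL":
            params = models.ModelParams(sigma2=stat_sd**2 / scn.height, root_value=0.0)
            d = models.simulate(tree, "BM1", params, seed=seed + 10 + j)
        else:
            theta = {"base": 0.0}
            for reg, vec in theta_vectors.items():
                theta[reg] = float(vec[j])
            params = models.ModelParams(
                sigma2=scn.dev_sigma2, alpha=scn.dev_alpha, theta=theta,
            )
            d = models.simulate(tree, "OUM", params, painting=painting,
                                seed=seed + 10 + j)
        dev[:, j] = d.to_numpy()

    latent_log = (scn.intercepts[None, :]
                  + scn.slopes[None, :] * size.to_numpy()[:, None]
                  + dev)
    latent = pd.DataFrame(latent_log, index=tree.tip_labels, columns=TRAIT_NAMES)

    rng = np.random.default_rng(seed + 1000)
    rows = []
    for lab in tree.tip_labels:
        n_spec = int(rng.integers(scn.specimens_min, scn.specimens_max + 1))
        for s in range(n_spec):
            noise = (rng.normal(0.0, scn.measurement_cv, size=len(TRAIT_NAMES))
                     if scn.measurement_cv > 0 else np.zeros(len(TRAIT_NAMES)))
            vals = np.exp(latent.loc[lab].to_numpy() + noise)
            rows.append({"specimen_id": f"{lab}_{s + 1}", "species": lab,
                         **dict(zip(TRAIT_NAMES, vals))})
    specimens = pd.DataFrame(rows)

    truth = {
        "scenario": scn.scenario,
        "seed": seed,
        "n_tips": scn.n_tips,
        "height": scn.height,
        "mk_rate": scn.mk_rate,
        "size_sigma2": scn.size_sigma2,
        "dev_alpha": scn.dev_alpha,
        "dev_sigma2": scn.dev_sigma2,
        "dev_stat_sd": stat_sd,
        "slopes": scn.slopes.tolist(),
        "intercepts": scn.intercepts.tolist(),
        "measurement_cv": scn.measurement_cv,
        "shift_edges": {
            int(e): {
                "pos": pos,
                "tips": sorted(np.array(tree.tip_labels)[tree.tip_descendants(e)].tolist()),
                "theta": theta_vectors[f"shift_{e}"].tolist(),
            }
            for e, pos in shift_edges.items()
        },
        "node_habits": {int(v): h for v, h in node_habits.items()},
        "latent_log_traits": latent.to_dict(orient="index"),
    }
    return specimens, tree, habits, truth
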