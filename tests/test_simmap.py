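import itertools
import math
import warnings

import numpy as np
import pytest
from scipy import linalg
from scipy.integrate import quad

from mustelimb import models, simmap, synth
from mustelimb.phylo import DatedTree, parse_newick
from mustelimb.simmap import (
    MkModel,
    _er_generator,
    _sample_path_rejection,
    _sample_path_uniformization,
    fit_mk,
    fit_over_mappings,
    mk_loglik,
    sample_mappings,
)

STATES = ("g", "s", "f", "n")


@pytest.fixture
def tips4():
    return {"A": "g", "B": "g", "C": "g", "D": "s"}


class TestMkLikelihood:
    def test_matches_exhaustive_enumeration(self, quartet):
        tips = {"A": "g", "B": "s", "C": "g", "D": "f"}
        Q = _er_generator(0.3, 4)
        ll = mk_loglik(quartet, tips, Q, STATES)
        P = {e: linalg.expm(Q * float(quartet.length[e])) for e in quartet.edges}
        sidx = {s: i for i, s in enumerate(STATES)}
        internal = [v for v in range(quartet.n_nodes) if quartet.children[v]]
        total = 0.0
        for assign in itertools.product(range(4), repeat=len(internal)):
            st = dict(zip(internal, assign))
            for t in quartet.tips:
                st[t] = sidx[tips[quartet.labels[t]]]
            p = 0.25
            for e in quartet.edges:
                p *= P[e][st[int(quartet.parent[e])], st[e]]
            total += p
        assert ll == pytest.approx(math.log(total), abs=1e-10)

    def test_uniform_tips_rate_mle_near_zero(self, quartet):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk = fit_mk(quartet, {k: "g" for k in "ABCD"}, states=STATES)
        assert mk.Q[0, 1] <= 1e-6

    def test_doubling_lengths_halves_rate(self, quartet, tips4):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk1 = fit_mk(quartet, tips4, states=STATES)
            doubled = DatedTree(quartet.parent, quartet.length * 2, quartet.labels)
            mk2 = fit_mk(doubled, tips4, states=STATES)
        assert mk1.Q[0, 1] / mk2.Q[0, 1] == pytest.approx(2.0, rel=1e-3)

    def test_absent_state_warns(self, quartet, tips4):
        with pytest.warns(UserWarning, match="absent"):
            fit_mk(quartet, tips4, states=STATES)

    def test_invalid_generator_rejected(self):
        Q = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError):
            MkModel(("a", "b"), Q)


class TestSampleMappings:
    def test_zero_rate_uniform_tips_single_regime(self, quartet):
        mk = MkModel(STATES, _er_generator(1e-12, 4))
        maps = sample_mappings(quartet, {k: "g" for k in "ABCD"}, mk, 5, seed=1)
        assert all(m.painting.regimes == ("g",) for m in maps)

    def test_tip_states_always_honoured(self, quartet, tips4):
        mk = MkModel(STATES, _er_generator(0.5, 4))
        maps = sample_mappings(quartet, tips4, mk, 100, seed=2)
        for m in maps:
            for lab, st in tips4.items():
                assert m.painting.regime_at_node(
                    quartet, quartet.tip_node(lab)) == st

    def test_segment_conservation(self, quartet, tips4):
        mk = MkModel(STATES, _er_generator(0.5, 4))
        for m in sample_mappings(quartet, tips4, mk, 50, seed=3):
            m.painting.validate(quartet)

    def test_determinism(self, quartet, tips4):
        mk = MkModel(STATES, _er_generator(0.4, 4))
        a = sample_mappings(quartet, tips4, mk, 4, seed=7)
        b = sample_mappings(quartet, tips4, mk, 4, seed=7)
        assert all(x.painting.segments == y.painting.segments
                   for x, y in zip(a, b))

    def test_pathological_rate_rejected(self, quartet, tips4):
        mk = MkModel(STATES, _er_generator(1e4, 4))
        with pytest.raises(ValueError, match="rates"):
            sample_mappings(quartet, tips4, mk, 1, seed=0)


class TestPathSampling:
    @staticmethod
    def _expected_changes(Q, a, b, t):
        """Quadrature oracle for E[#changes | endpoints a, b]."""
        Pt = linalg.expm(Q * t)
        total = 0.0
        for i in range(Q.shape[0]):
            for j in range(Q.shape[0]):
                if i == j:
                    continue
                val, _ = quad(
                    lambda s: linalg.expm(Q * s)[a, i] * Q[i, j]
                    * linalg.expm(Q * (t - s))[j, b], 0, t, limit=100)
                total += val
        return total / Pt[a, b]

    @pytest.mark.parametrize("a,b", [(0, 2), (1, 1)])
    def test_expected_change_count_single_edge(self, a, b):
        Q = _er_generator(0.4, 4)
        t = 2.0
        expected = self._expected_changes(Q, a, b, t)
        rng = np.random.default_rng(42)
        counts = []
        for _ in range(2000):
            path = _sample_path_rejection(Q, a, b, t, rng)
            if path is None:
                path = _sample_path_uniformization(Q, a, b, t, rng)
            assert path[0][0] == a and path[-1][0] == b
            assert sum(d for _, d in path) == pytest.approx(t, rel=1e-9)
            counts.append(len(path) - 1)
        m, se = np.mean(counts), np.std(counts) / math.sqrt(len(counts))
        assert abs(m - expected) < 3 * se

    def test_uniformization_alone_matches_oracle(self):
        Q = _er_generator(0.4, 4)
        a, b, t = 0, 2, 2.0
        expected = self._expected_changes(Q, a, b, t)
        rng = np.random.default_rng(7)
        counts = [len(_sample_path_uniformization(Q, a, b, t, rng)) - 1
                  for _ in range(2000)]
        m, se = np.mean(counts), np.std(counts) / math.sqrt(len(counts))
        assert abs(m - expected) < 3 * se


class TestFitOverMappings:
    def test_identical_mappings_equal_single_fit(self, tree40):
        tips = {lab: ("in" if i < 20 else "out")
                for i, lab in enumerate(tree40.tip_labels)}
        mk = MkModel(("in", "out"), _er_generator(1e-12, 2))
        maps = sample_mappings(tree40, tips, mk, 3, seed=0)
        # zero rate forces all mappings identical apart from impossible data;
        # use a homogeneous map instead
        tips_uniform = {lab: "in" for lab in tree40.tip_labels}
        maps = sample_mappings(tree40, tips_uniform, mk, 3, seed=0)
        x = models.simulate(tree40, "BM1",
                            models.ModelParams(sigma2=1.0, root_value=0.0), seed=1)
        av = fit_over_mappings(tree40, maps, x, "BMS")
        single = models.fit(tree40, x, "BMS", painting=maps[0].painting)
        assert av.lnL == pytest.approx(single.lnL, abs=1e-8)
        assert av.mean_params["sigma2"]["in"] == pytest.approx(
            single.params.sigma2["in"], rel=1e-6)

    def test_means_are_definitional_averages(self, tree40):
        tips = {lab: ("in" if i % 3 == 0 else "out")
                for i, lab in enumerate(tree40.tip_labels)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk = fit_mk(tree40, tips, states=("in", "out"))
        maps = sample_mappings(tree40, tips, mk, 10, seed=4)
        x = models.simulate(tree40, "BM1",
                            models.ModelParams(sigma2=1.0, root_value=0.0), seed=2)
        av = fit_over_mappings(tree40, maps, x, "OUM")
        good = [f for f in av.fits if f.converged]
        manual = np.mean([f.params.theta["in"] for f in good])
        assert av.mean_params["theta"]["in"] == pytest.approx(manual, abs=1e-12)

    def test_clade_shift_theta_recovery(self, tree40):
        """Averaged OUM fits recover a clade-shifted optimum within 0.15."""
        scn = synth.SynthScenario(scenario="A", seed=2)
        e = synth._clade_stem_edge(tree40, scn.clade_fraction)
        paint = synth.build_shift_painting(tree40, {e: 0.5})
        th_true = {"base": 0.0, f"shift_{e}": scn.shift_sd_mult * scn.dev_stat_sd}
        x = models.simulate(
            tree40, "OUM",
            models.ModelParams(sigma2=scn.dev_sigma2, alpha=scn.dev_alpha,
                               theta=th_true),
            painting=paint, seed=9)
        mask = tree40.tip_descendants(e)
        tips2 = {lab: ("in" if m else "out")
                 for lab, m in zip(tree40.tip_labels, mask)}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mk = fit_mk(tree40, tips2, states=("out", "in"))
        maps = sample_mappings(tree40, tips2, mk, 100, seed=11)
        av = fit_over_mappings(tree40, maps, x, "OUM")
        assert av.mean_params["theta"]["in"] == pytest.approx(
            th_true[f"shift_{e}"], abs=0.15)

    def test_requires_regime_kind(self, tree40):
        with pytest.raises(ValueError):
            fit_over_mappings(tree40, [], np.zeros(40), "BM1")
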