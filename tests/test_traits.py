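import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mustelimb import synth, traits
from mustelimb.traits import (
    TRAIT_NAMES,
    broken_stick,
    geometric_mean,
    pca,
    significant_pcs,
    size_residuals,
    species_means,
)


def _specimen_table(rng, n_species=6, max_spec=3):
    rows = []
    for i in range(n_species):
        size = np.exp(rng.normal(3.0, 0.4))
        for s in range(rng.integers(1, max_spec + 1)):
            vals = size * np.exp(rng.normal(0, 0.05, len(TRAIT_NAMES)))
            rows.append({"specimen_id": f"sp{i}_{s}", "species": f"sp{i}",
                         **dict(zip(TRAIT_NAMES, vals))})
    return pd.DataFrame(rows)


class TestSpeciesMeans:
    def test_single_specimen_identity(self, rng):
        df = _specimen_table(rng, max_spec=1)
        means = species_means(df)
        for _, row in df.iterrows():
            np.testing.assert_allclose(
                means.loc[row.species, TRAIT_NAMES].to_numpy(dtype=float),
                row[TRAIT_NAMES].to_numpy(dtype=float))

    def test_two_specimens_average(self):
        rows = []
        for v in (10.0, 20.0):
            rows.append({"specimen_id": f"s{v}", "species": "sp1",
                         **{c: v for c in TRAIT_NAMES}})
        assert species_means(pd.DataFrame(rows)).iloc[0, 0] == pytest.approx(15.0)

    def test_matches_brute_force_group_by(self, rng):
        df = _specimen_table(rng, n_species=12, max_spec=5)
        means = species_means(df)
        for sp in df.species.unique():
            sub = df[df.species == sp]
            for c in TRAIT_NAMES:
                assert means.loc[sp, c] == pytest.approx(sub[c].to_numpy().mean())

    def test_nonpositive_value_errors(self, rng):
        df = _specimen_table(rng)
        df.loc[0, TRAIT_NAMES[3]] = -1.0
        with pytest.raises(ValueError, match="positive"):
            species_means(df)

    def test_missing_cell_errors(self, rng):
        df = _specimen_table(rng)
        df.loc[0, TRAIT_NAMES[0]] = np.nan
        with pytest.raises(ValueError, match="missing"):
            species_means(df)


class TestGeometricMean:
    def test_constant_vector(self):
        assert geometric_mean(np.full(14, 7.3)) == pytest.approx(7.3)

    def test_two_value_closed_form(self):
        assert geometric_mean(np.array([2.0, 8.0])) == pytest.approx(4.0)

    @given(st.lists(st.floats(0.01, 1e4), min_size=14, max_size=14))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_equals_nth_root_of_product(self, vals):
        arr = np.array(vals)
        expected = np.prod(arr ** (1.0 / 14))
        assert geometric_mean(arr) == pytest.approx(expected, rel=1e-9)

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            geometric_mean(np.array([1.0, 0.0]))


class TestSizeResiduals:
    def test_isometric_data_gives_zero_residuals(self):
        gm = np.exp(np.linspace(1, 3, 8))
        tt = pd.DataFrame(
            np.outer(gm, np.linspace(0.5, 2.0, 14)), columns=TRAIT_NAMES,
            index=[f"sp{i}" for i in range(8)])
        rm = size_residuals(tt)
        assert np.abs(rm.residuals.to_numpy()).max() < 1e-12
        np.testing.assert_allclose(rm.slopes.to_numpy(), 1.0, atol=1e-10)

    def test_residual_columns_centered(self, rng):
        tt = species_means(_specimen_table(rng, n_species=10))
        rm = size_residuals(tt)
        np.testing.assert_allclose(rm.residuals.mean(axis=0), 0.0, atol=1e-9)

    def test_matches_normal_equations_oracle(self, rng):
        tt = species_means(_specimen_table(rng, n_species=5, max_spec=1))
        rm = size_residuals(tt)
        X = tt.to_numpy()
        g = np.log(np.exp(np.log(X).mean(axis=1)))
        A = np.column_stack([np.ones_like(g), g])
        for j, c in enumerate(TRAIT_NAMES):
            y = np.log(X[:, j])
            beta = np.linalg.solve(A.T @ A, A.T @ y)
            np.testing.assert_allclose(
                rm.residuals[c].to_numpy(), y - A @ beta, atol=1e-10)

    def test_constant_size_errors(self):
        tt = pd.DataFrame(np.ones((5, 14)) * 3.0, columns=TRAIT_NAMES)
        with pytest.raises(ValueError, match="degenerate"):
            size_residuals(tt)


class TestPCA:
    def test_two_column_closed_form(self):
        rng = np.random.default_rng(0)
        n = 4000
        X = np.column_stack([rng.normal(0, 2.0, n), rng.normal(0, 1.0, n)])
        pr = pca(pd.DataFrame(X, columns=["a", "b"]))
        np.testing.assert_allclose(pr.proportions, [0.8, 0.2], atol=0.02)

    def test_reconstruction(self, rng):
        tt = species_means(_specimen_table(rng, n_species=20))
        rm = size_residuals(tt)
        pr = pca(rm)
        recon = pr.scores.to_numpy() @ pr.loadings.to_numpy().T \
            + pr.column_means.to_numpy()
        np.testing.assert_allclose(recon, rm.residuals.to_numpy(), atol=1e-8)

    def test_loadings_orthonormal_and_proportions_sorted(self, rng):
        pr = pca(size_residuals(species_means(_specimen_table(rng, n_species=20))))
        L = pr.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-8)
        assert (np.diff(pr.proportions) <= 1e-12).all()
        assert pr.proportions.sum() == pytest.approx(1.0, abs=1e-9)

    def test_matches_covariance_eigendecomposition(self, rng):
        tt = species_means(_specimen_table(rng, n_species=25))
        rm = size_residuals(tt)
        pr = pca(rm)
        C = np.cov(rm.residuals.to_numpy(), rowvar=False)
        eig = np.sort(np.linalg.eigvalsh(C))[::-1]
        np.testing.assert_allclose(pr.proportions, eig / eig.sum(), atol=1e-10)

    def test_degenerate_isometric_data_does_not_crash(self):
        gm = np.exp(np.linspace(1, 3, 8))
        tt = pd.DataFrame(np.outer(gm, np.linspace(0.5, 2.0, 14)),
                          columns=TRAIT_NAMES)
        # all-zero residuals: total variance is numerically ~0 but not exactly
        rm = size_residuals(tt)
        perturbed = rm.residuals + 1e-13
        pr = pca(perturbed)
        assert pr.zero_variance.any()


class TestBrokenStick:
    def test_p1(self):
        np.testing.assert_allclose(broken_stick(1), [1.0])

    def test_p2_closed_form(self):
        np.testing.assert_allclose(broken_stick(2), [0.75, 0.25])

    def test_paper_scale_expectations_for_14_components(self):
        bs = broken_stick(14)
        assert round(100 * bs[0], 1) == 23.2
        assert round(100 * bs[1], 1) == 16.1

    @pytest.mark.parametrize("p", list(range(1, 101, 9)))
    def test_sums_to_one(self, p):
        assert broken_stick(p).sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            broken_stick(0)


class TestSignificantPCs:
    def _result(self, proportions):
        p = len(proportions)
        return traits.PCAResult(
            loadings=pd.DataFrame(np.eye(p)),
            scores=pd.DataFrame(np.zeros((3, p))),
            proportions=np.asarray(proportions, dtype=float),
            zero_variance=np.zeros(p, bool),
            column_means=pd.Series(np.zeros(p)),
        )

    def test_dominant_two_axes(self):
        # first two shares exceed the stick; the remaining mass follows a
        # sub-stick decaying tail (rest tiny relative to expectation)
        stick = broken_stick(14)
        tail = 0.39 * stick[2:] / stick[2:].sum()
        props = np.concatenate([[0.44, 0.17], tail])
        assert significant_pcs(self._result(props)) == [1, 2]

    def test_equality_is_not_exceedance(self):
        assert significant_pcs(self._result(broken_stick(5))) == []

    def test_matches_direct_comparison(self, rng):
        props = rng.dirichlet(np.ones(10))
        props = np.sort(props)[::-1]
        expect = broken_stick(10)
        got = significant_pcs(self._result(props))
        assert got == [k + 1 for k in range(10) if props[k] > expect[k]]


class TestScenarioAPipeline:
    def test_pc1_separates_shifted_clade(self):
        """Scenario A produces a dominant habit-contrast axis: PC1 scores
        separate the shifted clade (mean point-biserial |r| > 0.7)."""
        rs = []
        for seed in range(10):
            scn = synth.SynthScenario(scenario="A", seed=seed)
            specimens, tree, habits, truth = synth.simulate_dataset(scn)
            pr = pca(size_residuals(species_means(specimens)))
            x = pr.scores["PC1"]
            e = next(iter(truth["shift_edges"]))
            members = set(truth["shift_edges"][e]["tips"])
            mask = np.array([lab in members for lab in x.index], dtype=float)
            rs.append(abs(np.corrcoef(mask, x.to_numpy())[0, 1]))
        assert np.mean(rs) > 0.7
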