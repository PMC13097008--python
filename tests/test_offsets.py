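import numpy as np
import pandas as pd
import pytest

from adaptscape.offsets import (
    fit_gdm,
    fit_gradient_forest,
    fit_rda_offset,
    genetic_dissimilarity,
    ispline_basis,
    variable_importance,
)


class TestISpline:
    def test_basis_shape_monotone_bounds(self):
        x = np.linspace(-1, 2, 50)
        B = ispline_basis(x, np.array([0.0, 0.5, 1.0]))
        assert B.shape == (50, 3)
        assert np.all(np.diff(B, axis=0) >= -1e-12)
        assert np.allclose(B[x <= 0], 0) and np.allclose(B[x >= 1], 1)

    def test_bad_knots_rejected(self):
        with pytest.raises(ValueError):
            ispline_basis(np.array([0.5]), np.array([1.0, 0.0]))


@pytest.fixture(scope="module")
def single_driver():
    rng = np.random.default_rng(3)
    n = 150
    clim = pd.DataFrame(
        rng.normal(size=(n, 4)), columns=["cwd", "rch", "tmn", "tmx"]
    )
    p = 1 / (1 + np.exp(-2 * clim["tmx"].to_numpy()))
    loci = pd.DataFrame({
        f"L{i}": rng.binomial(2, np.clip(p, 0.01, 0.99)) for i in range(8)
    }).astype(float)
    model = fit_gradient_forest(loci, clim, n_trees=200, seed=1)
    return clim, model


class TestGradientForest:
    def test_driver_dominates_cumulative_importance(self, single_driver):
        _, model = single_driver
        imp = variable_importance(model)
        assert imp.index[0] == "tmx"
        assert imp["tmx"] / imp.sum() > 0.9
        # non-driver curves are nearly flat
        assert all(imp[v] / imp.sum() < 0.05 for v in ("cwd", "rch", "tmn"))

    def test_curves_monotone_zero_at_minimum(self, single_driver):
        clim, model = single_driver
        for v, (bp, cum) in model.curves.items():
            assert np.all(np.diff(cum) >= -1e-12)
        at_min = model.transform(clim.min().to_frame().T)
        assert np.allclose(at_min.to_numpy(), 0)

    def test_importance_conservation(self, single_driver):
        _, model = single_driver
        total_curve = sum(cum[-1] for _, cum in model.curves.values())
        total_r2 = sum(max(r, 0.0) for r in model.locus_r2)
        assert np.isclose(total_curve, total_r2, rtol=1e-8)

    def test_transform_is_left_continuous_step(self, single_driver):
        clim, model = single_driver
        bp, cum = model.curves["tmx"]
        x = np.array([bp[0] - 1, bp[0], (bp[3] + bp[4]) / 2, bp[-1], bp[-1] + 5])
        probe = pd.DataFrame({v: np.zeros(len(x)) for v in model.variables})
        probe["tmx"] = x
        got = model.transform(probe)["tmx"].to_numpy()
        # brute-force: sum of bin masses whose right edge <= x
        masses = np.diff(np.concatenate([[0.0], cum]))
        expected = np.array([
            masses[: np.searchsorted(bp[1:], xi, side="right")].sum() for xi in x
        ])
        assert np.allclose(got, expected)
        assert got[0] == 0.0 and got[-1] == cum[-1]

    def test_monotone_component_in_driver(self, single_driver):
        clim, model = single_driver
        grid = pd.DataFrame({v: np.zeros(30) for v in model.variables})
        grid["tmx"] = np.linspace(clim["tmx"].min(), clim["tmx"].max(), 30)
        comp = model.transform(grid)["tmx"].to_numpy()
        assert np.all(np.diff(comp) >= -1e-12)

    def test_constant_loci_rejected(self):
        rng = np.random.default_rng(4)
        clim = pd.DataFrame(rng.normal(size=(30, 2)), columns=["a", "b"])
        loci = pd.DataFrame({"L0": np.ones(30)})
        with pytest.raises(ValueError, match="no predictive loci"):
            fit_gradient_forest(loci, clim, n_trees=20, seed=0)

    def test_preconditions(self):
        clim1 = pd.DataFrame({"a": np.arange(20.0)})
        loci = pd.DataFrame({"L0": np.arange(20.0) % 3})
        with pytest.raises(ValueError):
            fit_gradient_forest(loci, clim1, n_trees=10)


class TestRDAOffset:
    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(5)
        clim = pd.DataFrame(rng.normal(size=(60, 3)), columns=["a", "b", "c"])
        loci = pd.DataFrame(
            rng.binomial(2, 0.5, size=(60, 10)).astype(float) + clim[["a"]].to_numpy()
        )
        m = fit_rda_offset(loci, clim, n_axes=2)
        assert np.isclose(m.weights.sum(), 1.0)
        assert np.all(m.weights > 0)

    def test_one_axis_one_variable_offset_is_linear_in_delta(self):
        rng = np.random.default_rng(6)
        n = 80
        clim = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        loci = pd.DataFrame({
            f"L{i}": 1.5 * clim["a"].to_numpy() + rng.normal(size=n) * 0.05
            for i in range(5)
        })
        m = fit_rda_offset(loci, clim, n_axes=1)
        coef_a = abs(m.axis_coefs[0, 0])
        c1 = pd.DataFrame({"a": [0.0], "b": [0.0]})
        for delta in (0.5, 1.0, 2.0):
            c2 = pd.DataFrame({"a": [delta], "b": [0.0]})
            off = m.pair_offset(m.embed(c1), m.embed(c2))[0, 0]
            assert np.isclose(off, coef_a * delta, rtol=1e-6)


class TestGDM:
    def _design(self, seed=5, n_sites=50, n_vars=3):
        rng = np.random.default_rng(seed)
        clim = pd.DataFrame(
            rng.uniform(-2, 2, (n_sites, n_vars)),
            columns=[f"v{i}" for i in range(n_vars)],
            index=[f"s{i}" for i in range(n_sites)],
        )
        return rng, clim

    def test_parameter_recovery_from_known_coefficients(self):
        rng, clim = self._design()
        true = {
            "v0": np.array([0.3, 0.2, 0.1]),
            "v1": np.array([0.0, 0.4, 0.0]),
            "v2": np.array([0.5, 0.0, 0.3]),
        }
        knots = {v: np.quantile(clim[v], [0, 0.5, 1]) for v in clim}
        basis = {v: ispline_basis(clim[v].to_numpy(), knots[v]) for v in clim}
        n = len(clim)
        iu, ju = np.triu_indices(n, 1)
        eta = sum(np.abs(basis[v][iu] - basis[v][ju]) @ true[v] for v in clim) + 0.02
        d = np.zeros((n, n))
        d[iu, ju] = d.T[iu, ju] = 1 - np.exp(-eta)
        freqs = pd.DataFrame(np.zeros((n, 2)), index=clim.index)  # response supplied
        model = fit_gdm(freqs, clim, response=d)
        assert model.deviance_explained > 0.99
        for v in clim:
            big = true[v] > 0.05
            assert np.allclose(model.coefs[v][big], true[v][big], rtol=0.2)
            assert np.all(model.coefs[v][~big] < 0.05)

    def test_identity_and_range(self):
        rng, clim = self._design(seed=7, n_sites=12)
        freqs = pd.DataFrame(
            rng.uniform(0, 1, (12, 20)), index=clim.index
        )
        model = fit_gdm(freqs, clim)
        same = model.predict_dissimilarity(clim, clim, include_intercept=False)
        assert np.allclose(same, 0)
        other = model.predict_dissimilarity(clim, clim.iloc[::-1].set_axis(clim.index))
        assert np.all((other >= 0) & (other < 1))

    def test_too_few_sites_rejected(self):
        rng, clim = self._design(n_sites=3)
        freqs = pd.DataFrame(rng.uniform(0, 1, (3, 5)), index=clim.index)
        with pytest.raises(ValueError, match="4 sites"):
            fit_gdm(freqs, clim)

    def test_dissimilarity_rescaled_into_unit_interval(self):
        rng, clim = self._design(seed=8, n_sites=10)
        freqs = pd.DataFrame(rng.uniform(0, 1, (10, 30)), index=clim.index)
        d = genetic_dissimilarity(freqs)
        assert d.max() < 1.0 and d.min() == 0.0 and np.allclose(d, d.T)


class TestSurfacesAndImportance:
    def test_zero_offset_identity_all_engines(self, fitted_engines):
        models, grids_std = fitted_engines
        for name, model in models.items():
            surf = model.offset(grids_std["recent"], grids_std["recent"])
            assert (surf.table["offset"] == 0).all(), name
            assert (surf.table["adaptedness"] == 0).all(), name

    def test_sign_convention(self, fitted_engines):
        models, grids_std = fitted_engines
        fut = "hotdry_rcp8.5_2070-2099"
        for name, model in models.items():
            surf = model.offset(grids_std["recent"], grids_std[fut])
            assert np.allclose(
                surf.table["adaptedness"], -surf.table["offset"], atol=1e-15
            )
            assert (surf.table["offset"] >= 0).all()

    def test_monotone_displacement_every_engine(self, fitted_engines):
        models, grids_std = fitted_engines
        recent = grids_std["recent"].values()
        for name, model in models.items():
            mean_offsets = []
            for delta in np.linspace(0, 3, 20):
                shifted = recent.copy()
                shifted["tmx"] = shifted["tmx"] + delta
                e1, e2 = model.embed(recent), model.embed(shifted)
                if name == "gdm":
                    off = np.diag(model.pair_offset(e1, e2))
                else:
                    off = np.linalg.norm(e1 - e2, axis=1)
                mean_offsets.append(off.mean())
            assert np.all(np.diff(mean_offsets) >= -1e-12), name

    def test_importance_ranks_planted_driver_first(self, fitted_engines):
        models, _ = fitted_engines
        for name, model in models.items():
            assert variable_importance(model).index[0] == "tmx", name

    def test_unknown_engine_type_rejected(self):
        with pytest.raises(TypeError):
            variable_importance(object())
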