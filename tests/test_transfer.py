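import numpy as np
import pandas as pd
import pytest

from adaptscape.transfer import (
    SeedPriorityMap,
    TransferMatrix,
    baseline_adaptedness,
    forward_adaptedness,
    pairwise_transfer,
    radius_donors,
    reverse_adaptedness,
    seed_source_priority,
)


def _tm(offset, method="gf"):
    offset = np.asarray(offset, float)
    return TransferMatrix(
        donors=np.arange(offset.shape[0]), recipients=np.arange(offset.shape[1]),
        offset=offset, method=method, current="recent", future="fut",
    )


class TestSummaries:
    def test_hand_computed_row_and_column_means(self):
        tm = _tm([[0.0, 1.0], [2.0, 4.0], [6.0, 0.0]])
        rev = reverse_adaptedness(tm)
        assert np.allclose(rev.to_numpy(), [-0.5, -3.0, -3.0])
        fwd = forward_adaptedness(tm)
        assert np.allclose(fwd.to_numpy(), [-8 / 3, -5 / 3])

    def test_single_recipient_equals_pairwise_value(self):
        tm = _tm([[0.7], [0.1]])
        rev = reverse_adaptedness(tm)
        assert np.allclose(rev.to_numpy(), [-0.7, -0.1])

    def test_perfect_donor_has_zero_mean_adaptedness(self):
        tm = _tm([[0.0, 0.0, 0.0]])
        assert reverse_adaptedness(tm).iloc[0] == 0.0


class TestSeedSourcePriority:
    def test_exhaustive_enumeration_on_random_matrix(self):
        rng = np.random.default_rng(9)
        off = rng.uniform(0, 2, size=(5, 4))
        tm = _tm(off)
        baseline = pd.Series(rng.uniform(-2, 0, 4), index=tm.recipients)
        result = seed_source_priority(tm, baseline)
        for d in range(5):
            count = sum(
                1 for r in range(4) if -off[d, r] > baseline.iloc[r]
            )
            assert result.priority.iloc[d] == count / 4

    def test_strictly_better_everywhere_gives_one(self):
        tm = _tm(np.zeros((1, 10)))
        baseline = pd.Series(-1.0, index=tm.recipients)
        assert seed_source_priority(tm, baseline).priority.iloc[0] == 1.0

    def test_tie_counts_as_no_improvement(self):
        tm = _tm(np.full((1, 10), 0.5))
        baseline = pd.Series(-0.5, index=tm.recipients)
        assert seed_source_priority(tm, baseline).priority.iloc[0] == 0.0

    def test_missing_recipients_rejected(self):
        tm = _tm(np.zeros((2, 3)))
        with pytest.raises(ValueError, match="baseline"):
            seed_source_priority(tm, pd.Series([0.0], index=[0]))

    def test_priority_bounds_enforced(self):
        with pytest.raises(ValueError):
            SeedPriorityMap(
                priority=pd.Series([1.5]), n_recipients=1,
                mean_reverse_adaptedness=pd.Series([0.0]),
            )


class TestPairwiseTransfer:
    def test_entries_match_per_pair_oracle(self, fitted_engines, small_fixture):
        models, grids_std = fitted_engines
        fut = "hotdry_rcp8.5_2070-2099"
        cells = grids_std["recent"].cell_ids
        donors, recipients = cells[:6], cells[-4:]
        for name, model in models.items():
            tm = pairwise_transfer(model, grids_std["recent"], grids_std[fut],
                                   donors, recipients)
            for i, d in enumerate(donors):
                for j, r in enumerate(recipients):
                    e_d = model.embed(grids_std["recent"].values().loc[[d]])
                    e_r = model.embed(grids_std[fut].values().loc[[r]])
                    single = model.pair_offset(e_d, e_r)[0, 0]
                    assert abs(tm.offset[i, j] - single) < 1e-12, name

    def test_identical_climates_give_zero(self, fitted_engines):
        models, grids_std = fitted_engines
        cells = grids_std["recent"].cell_ids[:5]
        for model in models.values():
            tm = pairwise_transfer(model, grids_std["recent"], grids_std["recent"],
                                   cells, cells)
            assert np.allclose(np.diag(tm.offset), 0)

    def test_forward_reverse_share_pairwise_values(self, fitted_engines):
        models, grids_std = fitted_engines
        fut = "warmwet_rcp4.5_2040-2069"
        cells = grids_std["recent"].cell_ids[:8]
        model = models["rda"]
        tm = pairwise_transfer(model, grids_std["recent"], grids_std[fut],
                               cells[:5], cells[5:])
        # forward and reverse summarize the same matrix, not recomputed values
        assert np.allclose(
            reverse_adaptedness(tm).to_numpy(), tm.adaptedness.mean(axis=1)
        )
        assert np.allclose(
            forward_adaptedness(tm).to_numpy(), tm.adaptedness.mean(axis=0)
        )

    def test_empty_sets_rejected(self, fitted_engines):
        models, grids_std = fitted_engines
        with pytest.raises(ValueError):
            pairwise_transfer(models["gf"], grids_std["recent"],
                              grids_std["recent"], [], [1])


class TestBaseline:
    def test_equals_surface_restricted_to_focal_cells(self, fitted_engines):
        models, grids_std = fitted_engines
        fut = "hotdry_rcp8.5_2070-2099"
        focal = grids_std["recent"].cell_ids[10:20]
        for name, model in models.items():
            base = baseline_adaptedness(model, grids_std["recent"],
                                        grids_std[fut], focal)
            surf = model.offset(grids_std["recent"], grids_std[fut])
            assert np.allclose(
                base.to_numpy(), surf.table.loc[focal, "adaptedness"].to_numpy(),
                atol=1e-12,
            ), name

    def test_future_equals_current_baseline_zero(self, fitted_engines):
        models, grids_std = fitted_engines
        focal = grids_std["recent"].cell_ids[:5]
        base = baseline_adaptedness(models["gf"], grids_std["recent"],
                                    grids_std["recent"], focal)
        assert (base == 0).all()


class TestRadiusDonors:
    def test_radius_zero_returns_focal_cells(self, small_fixture):
        *_, grids = small_fixture
        focal = grids["recent"].cell_ids[:3]
        got = radius_donors(grids["recent"], focal, radius_km=0.0)
        assert set(got) == set(focal)

    def test_huge_radius_returns_all_cells(self, small_fixture):
        *_, grids = small_fixture
        focal = [grids["recent"].cell_ids[0]]
        got = radius_donors(grids["recent"], focal, radius_km=1e6)
        assert np.array_equal(got, np.sort(grids["recent"].cell_ids))

    def test_one_dimensional_landscape_closed_form(self):
        import adaptscape as a

        cfg = a.LandscapeConfig(
            n_cells_x=20, n_cells_y=1, cell_size_km=10.0, n_individuals=10,
            n_sites=2, n_neutral_loci=5, n_adaptive_loci=0, seed=0,
        )
        grids = a.make_climate_grids(cfg)
        focal = [0]  # leftmost cell
        got = radius_donors(grids["recent"], focal, radius_km=35.0)
        # cells are 10 km apart: within 35 km of cell 0 -> cells 0..3
        assert list(got) == [0, 1, 2, 3]

    def test_scope_monotonicity(self, fitted_engines, small_fixture):
        models, grids_std = fitted_engines
        fut = "hotdry_rcp8.5_2070-2099"
        grid = grids_std["recent"]
        focal = grid.cell_ids[:4]
        model = models["rda"]
        best = {}
        for scope in ("site", "radius", "range"):
            donors = radius_donors(grid, focal, radius_km=150.0, scope=scope)
            tm = pairwise_transfer(model, grid, grids_std[fut], donors, focal)
            best[scope] = reverse_adaptedness(tm).max()
        assert best["site"] <= best["radius"] + 1e-12
        assert best["radius"] <= best["range"] + 1e-12

    def test_self_donation_with_no_change_gives_zero_priority(self, fitted_engines):
        models, grids_std = fitted_engines
        grid = grids_std["recent"]
        focal = grid.cell_ids[:6]
        model = models["gf"]
        tm = pairwise_transfer(model, grid, grid, focal, focal)
        baseline = baseline_adaptedness(model, grid, grid, focal)
        prio = seed_source_priority(tm, baseline)
        assert (prio.priority == 0).all()  # nothing strictly beats offset 0
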