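import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from crabmap import sdm
from crabmap.core_io import rasterize
from crabmap.synthetic_landscape import (
    SYNTH_CRS,
    LandscapeConfig,
    generate_covariates,
    generate_landscape,
)
from conftest import km_template, occurrence_frame


def records_at_cells(template, cells, species="sp"):
    r, c = np.unravel_index(cells, template.shape)
    x, y = template.transform.xy(r, c, "center")
    return occurrence_frame([species] * len(cells), x, y)


@pytest.fixture(scope="module")
def niche_world():
    """64x64 landscape with one strongly informative covariate."""
    cfg = LandscapeConfig(shape=(64, 64), n_covariates=3, seed=21)
    covs = {f"cov{k}": g for k, g in enumerate(generate_covariates(cfg))}
    template = covs["cov0"]
    # truth: presence where cov0 is in its top decile
    threshold = np.quantile(template.values, 0.9)
    truth = template.values >= threshold
    rng = np.random.default_rng(0)
    pres_cells = rng.choice(np.flatnonzero(truth.ravel()), 200, replace=True)
    records = records_at_cells(template, pres_cells)
    return covs, template, truth, records


class TestAUC:
    def test_rank_statistic_matches_trapezoid_on_1000_sets(self):
        rng = np.random.default_rng(12)
        for _ in range(1000):
            n1, n0 = rng.integers(3, 30, 2)
            pos = rng.normal(0.5, 1, n1)
            neg = rng.normal(0.0, 1, n0)
            a = sdm.auc_rank(pos, neg)
            b = roc_auc_score(np.r_[np.ones(n1), np.zeros(n0)], np.r_[pos, neg])
            assert a == pytest.approx(b, abs=1e-9)


class TestScreenVariables:
    def test_identical_covariates_collapse_to_one(self, niche_world):
        covs, template, _, records = niche_world
        dup = {"a": covs["cov0"], "b": template.like(covs["cov0"].values.copy()),
               "c": covs["cov1"]}
        report = sdm.screen_variables(dup, records, seed=0)
        assert len({"a", "b"} & set(report.retained)) == 1

    def test_orthogonal_covariates_all_pass_gates(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((500, 4))
        survivors, _, vif = sdm.screen_collinearity(X, list("abcd"), 0.9, 5.0)
        assert survivors == list("abcd")
        assert (vif < 1.1).all()

    def test_linear_combination_eliminated_and_gates_pass(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((500, 4))
        X = np.column_stack([X, X[:, 0] + X[:, 1] + 0.05 * rng.standard_normal(500)])
        survivors, _, _ = sdm.screen_collinearity(X, list("abcde"), 0.9, 5.0)
        idx = [list("abcde").index(s) for s in survivors]
        # brute-force recheck of both gates on the survivor set
        sub = X[:, idx]
        r = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(r, 0)
        assert r.max() < 0.9
        assert sdm._vif(sub).max() < 5.0


class TestSuitabilityModel:
    def test_informative_covariate_gives_high_cv_auc(self, niche_world):
        covs, _, _, records = niche_world
        model = sdm.fit_suitability(records, covs, seed=0)
        assert model.mean_auc > 0.9

    def test_uninformative_records_give_null_auc(self, niche_world):
        covs, template, _, _ = niche_world
        rng = np.random.default_rng(9)
        records = records_at_cells(template, rng.choice(64 * 64, 200))
        model = sdm.fit_suitability(records, covs, seed=0)
        assert model.mean_auc == pytest.approx(0.5, abs=0.07)

    def test_deterministic_under_seed(self, niche_world):
        covs, _, _, records = niche_world
        a = sdm.fit_suitability(records, covs, seed=3)
        b = sdm.fit_suitability(records, covs, seed=3)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert a.mean_auc == b.mean_auc

    def test_single_cell_presences_rejected(self, niche_world):
        covs, template, _, _ = niche_world
        records = records_at_cells(template, [5, 5, 5, 5])
        with pytest.raises(ValueError, match="degenerate"):
            sdm.fit_suitability(records, covs)


class TestThreshold:
    def test_perfect_separation_picks_boundary_score(self):
        scores = np.array([0.9] * 5 + [0.1] * 5)
        labels = np.array([1] * 5 + [0] * 5)
        assert sdm.max_sens_spec_threshold(scores, labels) == 0.9
        assert sdm.max_sens_spec_threshold(scores, labels, tie="min") == 0.9

    def test_tie_rule(self):
        # 0.4 and 0.9 both reach sens+spec = 1.5; tie=max errs toward the
        # smaller predicted range
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert sdm.max_sens_spec_threshold(scores, labels, tie="max") == 0.9
        assert sdm.max_sens_spec_threshold(scores, labels, tie="min") == 0.4


class TestBinarize:
    def test_low_auc_signals_substitution(self, niche_world):
        covs, template, _, _ = niche_world
        rng = np.random.default_rng(10)
        records = records_at_cells(template, rng.choice(64 * 64, 100))
        model = sdm.fit_suitability(records, covs, seed=0)
        assert sdm.binarize(model, covs, replicates=1) is None

    def test_range_confined_to_buffered_mcp(self, niche_world):
        covs, template, _, records = niche_world
        model = sdm.fit_suitability(records, covs, seed=0)
        br = sdm.binarize(model, covs, replicates=2, mcp_buffer_km=5.0)
        hull = sdm.species_mcp(records, buffer_km=5.0)
        from crabmap.core_io import VectorLayer
        clip = rasterize(VectorLayer([hull], crs=template.crs), template).values
        outside = (np.nan_to_num(br.presence.values) == 1) & (clip == 0)
        assert not outside.any()

    def test_recovers_truth_jaccard(self, niche_world):
        covs, _, truth, records = niche_world
        model = sdm.fit_suitability(records, covs, seed=0)
        br = sdm.binarize(model, covs, replicates=3)
        pred = np.nan_to_num(br.presence.values) > 0
        jac = (truth & pred).sum() / (truth | pred).sum()
        assert jac > 0.6


class TestSubstitution:
    def test_single_record_yields_containing_basin(self, small_truth):
        template = small_truth.config.template
        lvl2 = small_truth.basin_labels[1]
        records = records_at_cells(template, [np.ravel_multi_index((10, 10), (64, 64))])
        br = sdm.substitution_range(records, small_truth.subbasins, template,
                                    island=True)
        got = np.nan_to_num(br.presence.values) > 0
        assert got[10, 10]
        # the range is exactly the basin(s) the MCP point touches: one label
        assert len(np.unique(lvl2[got])) == 1

    def test_records_spanning_basins_take_union(self, small_truth):
        template = small_truth.config.template
        lvl2 = small_truth.basin_labels[1]
        # pick two cells in different fine basins
        labs = np.unique(lvl2)
        c1 = np.argwhere(lvl2 == labs[0])[0]
        c2 = np.argwhere(lvl2 == labs[1])[0]
        cells = [np.ravel_multi_index(tuple(c1), (64, 64)),
                 np.ravel_multi_index(tuple(c2), (64, 64))]
        br = sdm.substitution_range(records_at_cells(template, cells),
                                    small_truth.subbasins, template, island=True)
        got = np.nan_to_num(br.presence.values) > 0
        assert got[tuple(c1)] and got[tuple(c2)]
        assert {labs[0], labs[1]} <= set(np.unique(lvl2[got]))

    def test_coarse_level_is_superset_of_fine(self, small_truth):
        template = small_truth.config.template
        records = records_at_cells(template, [np.ravel_multi_index((30, 30), (64, 64))])
        fine = sdm.substitution_range(records, small_truth.subbasins, template,
                                      island=True)
        coarse = sdm.substitution_range(records, small_truth.subbasins, template,
                                        island=False)
        assert coarse.range_cells >= fine.range_cells
        f = np.nan_to_num(fine.presence.values) > 0
        c = np.nan_to_num(coarse.presence.values) > 0
        assert (c | f).sum() == c.sum()  # fine ⊆ coarse


class TestDispatch:
    def test_every_species_gets_one_nonempty_range(self, pipeline_result):
        res = pipeline_result
        species = set(res.clean.retained["species"])
        assert set(res.ranges) == species
        for br in res.ranges.values():
            assert br.range_cells > 0
            assert br.provenance in ("modelled", "substitution")

    def test_sparse_species_are_substituted(self, pipeline_result):
        rep = pipeline_result.sdm_report
        sparse = rep[rep.n_records < 4]
        assert (sparse.provenance == "substitution").all()

    def test_modelled_species_cleared_auc_gate(self, pipeline_result):
        rep = pipeline_result.sdm_report
        modelled = rep[rep.provenance == "modelled"]
        assert (modelled.auc > 0.75).all()
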