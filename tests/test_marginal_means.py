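import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import phyloscreen as ps
from phyloscreen.bayes import (
    GRAND_MEAN_LABEL,
    CellMeansModel,
    HierarchicalActivityModel,
    ModelSpec,
    build_model,
)
from phyloscreen.sampler import MCMCConfig, PosteriorDraws


@pytest.fixture(scope="module")
def hier_fit():
    cfg = ps.SimConfig(
        phyla=("Porifera", "Chordata", "Mollusca", "Cnidaria", "Bryozoa",
               "Annelida"),
        bioregions=("1", "2", "3", "4"),
        categories={"CYTOTOX": ("C1", "C2")},
        cell_n=40,
        phylum_effects={"Porifera": 1.5},
        cell_noise_sd=0.0,
        seed=12,
    )
    records, _ = ps.generate_screen(cfg)
    calls = ps.call_activity(records, ps.compute_thresholds(records))
    calls["taxon"] = calls["phylum"]
    model = build_model(calls, ModelSpec.hierarchical())
    draws = ps.run_mcmc(model, MCMCConfig(n_chains=3, n_iter=2000, burn_in=500,
                                          seed=6))
    return model, draws


def _fake_draws(model, arrays):
    return PosteriorDraws(
        param_names=list(model.param_names),
        array=arrays,
        acceptance=np.full((arrays.shape[0], arrays.shape[2]), 0.4),
        config=MCMCConfig(n_chains=2, n_iter=arrays.shape[1] + 10, burn_in=10,
                          seed=0),
    )


class TestMainEffectsMeans:
    def test_constant_draws_collapse_ci(self):
        cells = pd.DataFrame({"bioregion": ["A", "B"], "pct_active": [10.0, 20.0]})
        model = build_model(cells, ModelSpec.main_effects("bioregion"))
        arr = np.tile(np.array([15.0, -5.0, 2.0]), (2, 200, 1))
        mm = ps.marginal_means(_fake_draws(model, arr), model, "bioregion")
        a = mm.set_index("level")
        assert a.loc["A", ["mean", "ci_lower", "ci_upper"]].tolist() == [
            10.0, 10.0, 10.0,
        ]
        assert a.loc["B", "mean"] == 20.0
        assert a.loc[GRAND_MEAN_LABEL, "mean"] == 15.0

    def test_percentiles_match_sorting_oracle(self):
        cells = pd.DataFrame({"bioregion": ["A", "B"], "pct_active": [10.0, 20.0]})
        model = build_model(cells, ModelSpec.main_effects("bioregion"))
        rng = np.random.default_rng(0)
        arr = rng.normal(10, 4, (2, 500, 3))
        draws = _fake_draws(model, arr)
        mm = ps.marginal_means(draws, model, "bioregion")
        theta_a = (arr[:, :, 0] + arr[:, :, 1]).reshape(-1)
        lo, hi = np.percentile(theta_a, [2.5, 97.5])
        row = mm.set_index("level").loc["A"]
        assert row.ci_lower_raw == pytest.approx(lo)
        assert row.ci_upper_raw == pytest.approx(hi)
        assert row["mean_raw"] == pytest.approx(theta_a.mean())

    def test_truncation_keeps_raw_columns(self):
        cells = pd.DataFrame({"bioregion": ["A", "B"], "pct_active": [1.0, 3.0]})
        model = build_model(cells, ModelSpec.main_effects("bioregion"))
        rng = np.random.default_rng(1)
        arr = rng.normal(0, 6, (2, 400, 3))  # means near 0 -> CIs dip below 0
        mm = ps.marginal_means(_fake_draws(model, arr), model, "bioregion")
        assert (mm["ci_lower"] >= 0).all()
        assert (mm["ci_lower_raw"] < 0).any()

    def test_wrong_factor_rejected(self):
        cells = pd.DataFrame({"bioregion": ["A", "B"], "pct_active": [1.0, 3.0]})
        model = build_model(cells, ModelSpec.main_effects("bioregion"))
        arr = np.zeros((2, 200, 3))
        with pytest.raises(ValueError, match="factor"):
            ps.marginal_means(_fake_draws(model, arr), model, "taxon")


class TestHierarchicalMeans:
    def test_levels_and_grand_mean_schema(self, hier_fit):
        model, draws = hier_fit
        mm = ps.marginal_means(draws, model, "taxon")
        assert list(mm["level"]) == sorted(
            ["Porifera", "Chordata", "Mollusca", "Cnidaria", "Bryozoa",
             "Annelida"]
        ) + [GRAND_MEAN_LABEL]
        assert ((mm["ci_lower"] <= mm["mean"]) & (mm["mean"] <= mm["ci_upper"])).all()
        assert mm["mean"].between(0, 100).all()

    def test_hand_computed_inverse_logit_average(self, hier_fit):
        """Marginal mean per taxon is the draw-wise average of
        expit(mu + a_t + b_r) over observed bioregions, x100."""
        model, draws = hier_fit
        mm = ps.marginal_means(draws, model, "taxon")
        flat = draws.flat()
        mu, a, b, _, _ = model.split(flat)
        t = model.taxon_levels.index("Porifera")
        vals = 100.0 * np.mean(
            [expit(mu + a[:, t] + b[:, r]) for r in range(len(model.region_levels))],
            axis=0,
        )
        row = mm.set_index("level").loc["Porifera"]
        assert row["mean"] == pytest.approx(vals.mean(), rel=1e-10)

    def test_strong_effect_separates_from_grand_mean(self, hier_fit):
        model, draws = hier_fit
        mm = ps.marginal_means(draws, model, "taxon").set_index("level")
        por = mm.loc["Porifera"]
        grand = mm.loc[GRAND_MEAN_LABEL]
        assert por.ci_lower > grand.ci_upper

    def test_noise_integrated_option_widens_low_means(self, hier_fit):
        model, draws = hier_fit
        plain = ps.marginal_means(draws, model, "taxon")
        integ = ps.marginal_means(draws, model, "taxon", integrate_cell_noise=True)
        # integrating symmetric logit noise pulls probabilities toward 50%
        low = plain["mean"] < 50
        assert (integ.loc[low, "mean"].to_numpy()
                >= plain.loc[low, "mean"].to_numpy() - 1e-9).all()

    def test_lineage_rollup_mean_of_phyla(self, hier_fit):
        model, draws = hier_fit
        mm = ps.marginal_means(draws, model, "taxon").set_index("level")
        lm = ps.lineage_marginal_means(draws, model).set_index("level")
        assert set(lm.index) == {
            "EARLY_METAZOAN", "EARLY_EUMETAZOAN", "DEUTEROSTOME",
            "NON_DEUTEROSTOME", GRAND_MEAN_LABEL,
        }
        # singleton lineages equal their phylum's marginal mean
        assert lm.loc["EARLY_METAZOAN", "mean"] == pytest.approx(
            mm.loc["Porifera", "mean"], rel=1e-10
        )

    def test_unknown_factor_rejected(self, hier_fit):
        model, draws = hier_fit
        with pytest.raises(ValueError, match="factor"):
            ps.marginal_means(draws, model, "depth")


class TestEstimators:
    def test_cell_means_estimator_round_trip(self):
        rng = np.random.default_rng(5)
        cells = pd.DataFrame(
            {
                "bioregion": np.repeat(["A", "B", "C"], 5),
                "pct_active": rng.uniform(10, 40, 15),
            }
        )
        est = CellMeansModel(
            factor="bioregion", n_chains=3, n_iter=1500, burn_in=500, random_state=3
        )
        est.fit(cells)
        assert est.draws_.n_params == 1 + 2 + 1
        mm = est.marginal_means(allow_unconverged=True).set_index("level")
        for lv in ("A", "B", "C"):
            observed = cells.loc[cells.bioregion == lv, "pct_active"].mean()
            assert mm.loc[lv, "mean"] == pytest.approx(observed, abs=4.0)
        assert est.get_params()["factor"] == "bioregion"

    def test_hierarchical_estimator_blocks_unconverged_summaries(self):
        cfg = ps.SimConfig(
            phyla=("Porifera", "Chordata"),
            bioregions=("1", "2"),
            categories={"CYTOTOX": ("C1",)},
            cell_n=10,
            seed=2,
        )
        records, _ = ps.generate_screen(cfg)
        calls = ps.call_activity(records, ps.compute_thresholds(records))
        est = HierarchicalActivityModel(
            n_chains=2, n_iter=400, burn_in=200, auto_thin=False, random_state=0
        )
        est.fit(calls)  # far too short to converge
        if not est.diagnostics_.passed:
            with pytest.raises(RuntimeError, match="diagnostics"):
                est.marginal_means("taxon")
        mm = est.marginal_means("taxon", allow_unconverged=True)
        assert GRAND_MEAN_LABEL in set(mm["level"])
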