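import json
import math

import numpy as np
import pandas as pd
import pytest

from osteopem import (
    PhyloTree,
    SimulationConfig,
    TraitTable,
    back_transform,
    fit_pem_regression,
    fit_trait_model,
    gaussian_aicc,
    log_transform,
    loocv,
    predict_fossil,
    predict_targets,
    simulate_dataset,
    training_basis_with_targets,
)
from osteopem.model import AICC_TIE


def make_table(species, density, response, roles=None):
    roles = roles or ["training"] * len(species)
    return TraitTable(
        pd.DataFrame(
            {
                "species": species,
                "density": density,
                "response": response,
                "role": roles,
            }
        )
    )


class TestLogTransform:
    def test_values(self):
        table = make_table(["a", "b"], [0.01, 0.1], [1.0, 100.0])
        logged = log_transform(table)
        np.testing.assert_allclose(logged.data["density"], [-2.0, -1.0])
        np.testing.assert_allclose(logged.data["response"], [0.0, 2.0])
        assert logged.scale == "log10"

    def test_round_trip(self):
        table = make_table(["a", "b", "c"], [0.03, 0.2, 0.4], [2.5, 7.0, 90.0])
        logged = log_transform(table)
        np.testing.assert_allclose(
            back_transform(logged.data["density"]), table.data["density"], rtol=1e-12
        )
        np.testing.assert_allclose(
            back_transform(logged.data["response"]), table.data["response"], rtol=1e-12
        )

    def test_non_positive_named(self):
        table = make_table(["good", "bad"], [0.1, -0.2], [1.0, 1.0])
        with pytest.raises(ValueError, match="bad"):
            log_transform(table)

    def test_idempotent(self):
        table = make_table(["a", "b"], [0.01, 0.1], [1.0, 100.0])
        once = log_transform(table)
        assert log_transform(once) is once


class TestTraitTable:
    def test_target_must_lack_response(self):
        with pytest.raises(ValueError, match="target"):
            make_table(["a", "b"], [0.1, 0.2], [1.0, 2.0], ["training", "target"])

    def test_training_needs_response(self):
        with pytest.raises(ValueError, match="without response"):
            make_table(["a", "b"], [0.1, 0.2], [1.0, np.nan])

    def test_csv_round_trip(self, tmp_path):
        table = make_table(
            ["a", "b", "c"], [0.1, 0.2, 0.3], [1.0, 2.0, np.nan],
            ["training", "training", "target"],
        )
        path = tmp_path / "traits.csv"
        table.to_csv(path)
        again = TraitTable.from_csv(path)
        pd.testing.assert_frame_equal(again.data, table.data)


def independent_aicc(n, rss, n_params_including_sigma2):
    """Second, independent evaluation of the Gaussian AICc formula."""
    k = n_params_including_sigma2
    return n * math.log(rss / n) + 2 * k + (2 * k * (k + 1)) / (n - k - 1)


class TestAICc:
    def test_matches_independent_oracle_intercept_only(self):
        """Intercept-only Gaussian fit on y = 1..10 against a closed form."""
        y = np.arange(1.0, 11.0)
        rss = float(np.sum((y - y.mean()) ** 2))
        ours = gaussian_aicc(10, rss, n_mean_params=1)
        assert ours == pytest.approx(independent_aicc(10, rss, 2), abs=1e-9)

    def test_infinite_when_denominator_non_positive(self):
        assert gaussian_aicc(5, 1.0, n_mean_params=3) == math.inf

    def test_zero_rss_stays_finite(self):
        assert math.isfinite(gaussian_aicc(10, 0.0, n_mean_params=2))


@pytest.fixture
def noiseless():
    config = SimulationConfig(
        n_tips=10, sigma2_bm=0.0, sigma_e=0.0, beta0=0.5, beta1=2.0, seed=3
    )
    return simulate_dataset(config, n_targets=1)


class TestFit:
    def test_noiseless_linear_recovery(self, noiseless):
        tree, table, truth = noiseless
        fit, _ = fit_trait_model(tree, table, steepness=0.0)
        assert fit.slope_density == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(0.5, abs=1e-8)
        assert fit.rss < 1e-10
        assert fit.selected == ()

    def test_orthogonal_eigenvector_not_selected(self):
        """A regressor that leaves RSS unchanged only pays the AICc penalty."""
        n, rss = 12, 0.37
        assert gaussian_aicc(n, rss, 3) > gaussian_aicc(n, rss, 2)
        # and forward selection therefore stops: noiseless data select nothing
        config = SimulationConfig(n_tips=12, sigma2_bm=0.0, sigma_e=0.0, seed=11)
        tree, table, _ = simulate_dataset(config, n_targets=1)
        fit, _ = fit_trait_model(tree, table, steepness=0.0, selection="forward")
        assert fit.selected == ()

    def test_selection_strategies(self, small_dataset):
        tree, table, _ = small_dataset
        none_fit, _ = fit_trait_model(tree, table, steepness=0.0, selection="none")
        assert none_fit.selected == ()
        fwd_fit, _ = fit_trait_model(tree, table, steepness=0.0, selection="forward")
        assert fwd_fit.aicc <= none_fit.aicc + AICC_TIE

    def test_grid_steepness_never_worse_than_fixed(self, small_dataset):
        tree, table, _ = small_dataset
        fixed, _ = fit_trait_model(tree, table, steepness=0.0)
        grid, _ = fit_trait_model(tree, table, steepness="grid")
        assert grid.aicc <= fixed.aicc + AICC_TIE
        assert 0.0 <= grid.a <= 1.0

    def test_too_few_training_species(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table(["A", "B", "C", "D"], [0.1] * 4, [1.0, 2.0, 3.0, np.nan],
                           ["training"] * 3 + ["target"])
        with pytest.raises(ValueError, match=">= 4"):
            fit_trait_model(tree, table, steepness=0.0)

    def test_species_missing_from_tree(self, small_dataset):
        tree, table, _ = small_dataset
        df = table.data.copy()
        df.loc[0, "species"] = "not_in_tree"
        with pytest.raises(ValueError, match="not_in_tree"):
            fit_trait_model(tree, TraitTable(df), steepness=0.0)


class TestPrediction:
    def test_zero_scores_at_mean_density_predicts_mean_response(self, small_dataset):
        """Regression through the mean: a fully average target gets y-bar."""
        tree, table, _ = small_dataset
        fit, _ = fit_trait_model(tree, table, steepness=0.0)
        logged = log_transform(table)
        xbar = logged.training["density"].mean()
        ybar = logged.training["response"].mean()
        res = predict_fossil(fit, np.zeros(fit.basis.rank), xbar, species="avg")
        assert res.log_point == pytest.approx(ybar, abs=1e-10)

    def test_interval_orders_and_back_transform(self, small_dataset):
        tree, table, truth = small_dataset
        fit, scores = fit_trait_model(tree, table, steepness=0.0)
        res = predict_targets(fit, scores, table)[0]
        assert res.log_lower < res.log_point < res.log_upper
        assert res.lower < res.point < res.upper
        assert res.point == pytest.approx(10 ** res.log_point)

    def test_prediction_wider_than_confidence(self, small_dataset):
        tree, table, _ = small_dataset
        fit, scores = fit_trait_model(tree, table, steepness=0.0)
        pi = predict_targets(fit, scores, table, interval="prediction")[0]
        ci = predict_targets(fit, scores, table, interval="confidence")[0]
        assert pi.log_upper - pi.log_lower > ci.log_upper - ci.log_lower

    def test_interval_width_monotone_in_sigma2(self, small_dataset):
        import copy

        tree, table, _ = small_dataset
        fit, scores = fit_trait_model(tree, table, steepness=0.0)
        lab = table.target_labels()[0]
        logged = log_transform(table)
        xd = float(logged.targets.set_index("species").loc[lab, "density"])
        widths = []
        for scale in (1.0, 2.0, 5.0):
            inflated = copy.copy(fit)
            inflated.sigma2 = fit.sigma2 * scale
            res = predict_fossil(inflated, scores[lab], xd)
            widths.append(res.log_upper - res.log_lower)
        assert widths[0] < widths[1] < widths[2]


class TestLoocv:
    def test_noiseless_press_vanishes(self, noiseless):
        tree, table, _ = noiseless
        result = loocv(tree, table, steepness=0.0)
        assert result.press < 1e-16
        assert result.n_folds_completed == len(table.training)

    def test_matches_brute_force_rebuild_from_newick(self, small_dataset, tmp_path):
        """Each fold equals an independent delete-one rebuild from serialized files."""
        tree, table, _ = small_dataset
        fast = loocv(tree, table, steepness=0.0).table.set_index("species")
        path = tmp_path / "tree.nwk"
        tree.write(path, precision=None)
        for lab in fast.index:
            reread = PhyloTree.read(path)
            fold_table = table.as_target(lab)
            fit, scores = fit_trait_model(reread, fold_table, steepness=0.0)
            logged = log_transform(fold_table)
            xd = float(logged.targets.set_index("species").loc[lab, "density"])
            res = predict_fossil(fit, scores[lab], xd)
            assert res.log_point == pytest.approx(
                fast.loc[lab, "predicted"], abs=1e-10
            )

    def test_species_order_invariance(self, small_dataset):
        tree, table, _ = small_dataset
        press1 = loocv(tree, table, steepness=0.0).press
        shuffled = TraitTable(
            table.data.sample(frac=1.0, random_state=5).reset_index(drop=True)
        )
        press2 = loocv(tree, shuffled, steepness=0.0).press
        assert press1 == pytest.approx(press2, abs=1e-12)

    def test_minimum_training_size(self):
        tree = PhyloTree.from_newick("((A:1,B:1):1,(C:1,D:1):1);")
        table = make_table(["A", "B", "C", "D"], [0.1, 0.2, 0.3, 0.2], [1, 2, 3, 4.0])
        with pytest.raises(ValueError, match=">= 5"):
            loocv(tree, table, steepness=0.0)


def test_fit_report_is_deterministic(small_dataset):
    tree, table, _ = small_dataset
    r1 = fit_trait_model(tree, table, steepness="grid")[0].report()
    r2 = fit_trait_model(tree, table, steepness="grid")[0].report()
    assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)
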