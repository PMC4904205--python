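import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import lightresponse as lr
from lightresponse.metrics import (
    UndefinedMetricError,
    aic,
    r_squared,
    rank_models,
    residual_sum_of_squares,
)


def _toy_dataset():
    # 5-point toy curve; residuals against the constant model p=(0, amax, rd)
    # are hand-summable
    return lr.LightResponseDataset(
        "toy", "1", np.array([0.0, 100.0, 300.0, 700.0, 1500.0]),
        np.array([-1.0, 2.0, 5.0, 7.0, 8.0]),
    )


class _ConstantModel:
    """Predicts a constant c everywhere (for hand-checkable residuals)."""

    name = "constant"
    param_names = ("c",)
    n_params = 1

    def predict(self, params, irradiance):
        return np.full(np.asarray(irradiance).shape, float(np.ravel(params)[0]))


def test_rss_matches_hand_summed_value():
    ds = _toy_dataset()
    model = _ConstantModel()
    # residuals: (-1-2, 2-2, 5-2, 7-2, 8-2) -> 9 + 0 + 9 + 25 + 36 = 79
    assert residual_sum_of_squares(model, (2.0,), ds) == pytest.approx(79.0)


def test_rss_zero_for_generating_parameters(clean_rect_dataset):
    ds, truth = clean_rect_dataset
    assert residual_sum_of_squares(lr.get_model("rectangular"), truth, ds) == 0.0


def test_rss_constant_offset_is_n_c_squared(clean_rect_dataset):
    ds, truth = clean_rect_dataset
    m = lr.get_model("rectangular")
    shifted = lr.LightResponseDataset(
        ds.species_id, "2", ds.irradiance, m.predict(truth, ds.irradiance) + 0.5
    )
    assert residual_sum_of_squares(m, truth, shifted) == pytest.approx(
        ds.n_obs * 0.25, rel=1e-12
    )


def test_rss_is_infinite_where_the_model_is_undefined():
    ds = _toy_dataset()
    m = lr.get_model("nonrectangular")
    assert residual_sum_of_squares(m, (2.0, 0.05, 20.0, 1.0), ds) == math.inf


class TestRSquared:
    def test_perfect_fit_gives_one(self, clean_rect_dataset):
        ds, truth = clean_rect_dataset
        assert r_squared(lr.get_model("rectangular"), truth, ds) == pytest.approx(1.0)

    def test_mean_predictor_gives_zero(self):
        ds = _toy_dataset()
        assert r_squared(_ConstantModel(), (float(ds.a_net.mean()),), ds) == pytest.approx(0.0)

    def test_hand_value_on_toy_data(self):
        ds = _toy_dataset()
        # TSS around mean 4.2: 27.04+4.84+0.64+7.84+14.44 = 54.8; RSS(c=2)=79
        assert r_squared(_ConstantModel(), (2.0,), ds) == pytest.approx(1.0 - 79.0 / 54.8)

    def test_invariant_to_row_order(self):
        ds = _toy_dataset()
        perm = np.array([3, 0, 4, 1, 2])
        shuffled = lr.LightResponseDataset(
            "toy", "2", ds.irradiance[perm], ds.a_net[perm]
        )
        m = lr.get_model("exponential")
        p = (0.02, 10.0, 1.0)
        assert r_squared(m, p, ds) == pytest.approx(r_squared(m, p, shuffled), rel=1e-14)

    def test_zero_variance_observations_refused(self):
        ds = lr.LightResponseDataset(
            "flat", "1", np.array([0.0, 1.0, 2.0, 3.0, 4.0]), np.full(5, 3.0)
        )
        with pytest.raises(UndefinedMetricError):
            r_squared(_ConstantModel(), (3.0,), ds)


class TestAIC:
    def test_ls_simple_algebra(self):
        # RSS = n makes the log term vanish: AIC = 2k
        assert aic(rss=7.0, n_obs=7, n_params=3, convention="ls_simple") == pytest.approx(6.0)

    @pytest.mark.parametrize("convention", ["gaussian_full", "ls_simple"])
    def test_doubling_rss_adds_n_log_two(self, convention):
        n = 13
        delta = aic(2.4, n, 3, convention) - aic(1.2, n, 3, convention)
        assert delta == pytest.approx(n * math.log(2.0))

    def test_gaussian_full_matches_r_oracle(self):
        # frozen from R: x <- 1:5; y <- c(2.1,3.9,6.2,7.8,10.1); f <- lm(y~x)
        # sum(resid(f)^2) = 0.107; AIC(f) = 0.96756354727508587
        assert aic(0.10700000000000032, 5, 2, "gaussian_full") == pytest.approx(
            0.96756354727508587, rel=1e-12
        )

    def test_zero_rss_returns_neg_inf_with_warning(self):
        with pytest.warns(RuntimeWarning):
            assert aic(0.0, 13, 3) == -math.inf

    @given(
        rss=st.floats(1e-6, 1e6), factor=st.floats(1.001, 100.0),
        convention=st.sampled_from(["gaussian_full", "ls_simple"]),
    )
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_rss(self, rss, factor, convention):
        assert aic(rss * factor, 13, 3, convention) > aic(rss, 13, 3, convention)

    def test_unknown_convention_refused(self):
        with pytest.raises(ValueError):
            aic(1.0, 10, 3, "bic")


class TestRankModels:
    def test_tie_broken_by_fewer_parameters(self):
        fits = [
            {"model": "m3a", "aic": -10.0, "n_params": 3, "aic_convention": "gaussian_full"},
            {"model": "m4a", "aic": -20.0, "n_params": 4, "aic_convention": "gaussian_full"},
            {"model": "m4b", "aic": -15.0, "n_params": 4, "aic_convention": "gaussian_full"},
            {"model": "m3b", "aic": -20.0, "n_params": 3, "aic_convention": "gaussian_full"},
        ]
        ranked = rank_models(fits)
        assert [f["model"] for f in ranked] == ["m3b", "m4a", "m4b", "m3a"]

    def test_single_model_ranks_itself(self):
        only = [{"model": "solo", "aic": 1.0, "n_params": 3, "aic_convention": "ls_simple"}]
        assert rank_models(only) == only

    def test_output_is_permutation_of_input(self):
        rng = np.random.default_rng(0)
        fits = [
            {"model": f"m{i}", "aic": float(rng.normal()), "n_params": int(rng.integers(3, 5)),
             "aic_convention": "gaussian_full"}
            for i in range(10)
        ]
        ranked = rank_models(fits)
        assert sorted(f["model"] for f in ranked) == sorted(f["model"] for f in fits)
        assert all(ranked[i]["aic"] <= ranked[i + 1]["aic"] for i in range(9))

    def test_pairwise_order_matches_direct_aic_comparison(self, noisy_rect_dataset):
        # a curve generated by the rectangular model should rank it above the
        # exponential model by AIC
        ds, _ = noisy_rect_dataset
        fits = []
        for name in ("exponential", "rectangular"):
            res = lr.fit(ds, name, "de", seed=5)
            fits.append({"model": name, "aic": res.metrics.aic,
                         "n_params": res.metrics.n_params,
                         "aic_convention": "gaussian_full"})
        ranked = rank_models(fits)
        best_direct = min(fits, key=lambda f: f["aic"])
        assert ranked[0]["model"] == best_direct["model"] == "rectangular"

    def test_mixed_conventions_refused(self):
        fits = [
            {"model": "x", "aic": 1.0, "n_params": 3, "aic_convention": "gaussian_full"},
            {"model": "y", "aic": 2.0, "n_params": 3, "aic_convention": "ls_simple"},
        ]
        with pytest.raises(ValueError, match="convention"):
            rank_models(fits)
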