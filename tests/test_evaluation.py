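import numpy as np
import pytest
from scipy import stats

from rnadeg.evaluation import (
    mcrmse,
    motif_aggregate,
    rank_correlation,
    record_sn_ratio,
    score_predictions,
    sn_ratio,
    within_error_fraction,
)
from rnadeg.records import PredictionSet
from rnadeg.synthetic import planted_prediction_set


class TestMcrmse:
    def test_perfect_prediction(self, rng):
        y = {"a": rng.random(50), "b": rng.random(50)}
        rep = mcrmse(y, {c: v.copy() for c, v in y.items()})
        assert rep.mcrmse == 0.0

    def test_hand_evaluated_two_channels(self):
        # residuals uniformly 1 in one channel and 3 in the other
        meas = {"a": np.zeros(10), "b": np.zeros(10)}
        pred = {"a": np.ones(10), "b": np.full(10, 3.0)}
        rep = mcrmse(meas, pred)
        assert rep.per_channel_rmse == {"a": pytest.approx(1.0), "b": pytest.approx(3.0)}
        assert rep.mcrmse == pytest.approx(2.0)

    def test_single_channel_reduces_to_rmse(self, rng):
        y, yhat = rng.random(30), rng.random(30)
        rep = mcrmse({"x": y}, {"x": yhat})
        assert rep.mcrmse == pytest.approx(float(np.sqrt(np.mean((y - yhat) ** 2))))

    def test_pools_across_constructs(self, rng):
        parts_y = [rng.random(10), rng.random(25)]
        parts_p = [rng.random(10), rng.random(25)]
        rep = mcrmse({"x": parts_y}, {"x": parts_p})
        pooled = mcrmse({"x": np.concatenate(parts_y)}, {"x": np.concatenate(parts_p)})
        assert rep.mcrmse == pytest.approx(pooled.mcrmse)
        assert rep.n_scored_nt["x"] == 35

    def test_permutation_and_scaling_invariances(self, rng):
        y, yhat = rng.random(40), rng.random(40)
        perm = rng.permutation(40)
        a = mcrmse({"x": y}, {"x": yhat}).mcrmse
        assert mcrmse({"x": y[perm]}, {"x": yhat[perm]}).mcrmse == pytest.approx(a)
        scaled = mcrmse({"x": 3 * y}, {"x": 3 * yhat}).mcrmse
        assert scaled == pytest.approx(3 * a)

    def test_empty_mask_and_nan_policy(self, rng):
        y = rng.random(5)
        with pytest.raises(ValueError, match="scored"):
            mcrmse({"x": y}, {"x": y}, mask={"x": np.zeros(5, dtype=bool)})
        y2 = y.copy()
        y2[0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            mcrmse({"x": y2}, {"x": y})
        rep = mcrmse({"x": y2}, {"x": y}, nan_policy="omit")
        assert rep.n_scored_nt["x"] == 4


class TestSnRatio:
    def test_constant_ratio(self):
        assert sn_ratio(np.full((2, 5), 2.0), np.ones((2, 5))) == pytest.approx(2.0)

    def test_mu_equals_sigma_boundary(self, rng):
        s = rng.random((3, 7)) + 0.1
        assert sn_ratio(s, s.copy()) == pytest.approx(1.0)

    def test_matches_double_loop_oracle(self, rng):
        mu = rng.random((4, 9)) + 0.5
        sigma = rng.random((4, 9)) + 0.1
        want = np.mean([np.mean([m / s for m, s in zip(mr, sr)])
                        for mr, sr in zip(mu, sigma)])
        assert sn_ratio(mu, sigma) == pytest.approx(float(want))

    def test_zero_sigma_handling(self):
        mu, sigma = np.ones((1, 3)), np.array([[1.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="sigma = 0"):
            sn_ratio(mu, sigma)
        assert sn_ratio(mu, sigma, on_zero="exclude") == pytest.approx(1.0)

    def test_record_level(self, small_dataset):
        _, recs = small_dataset
        rec = recs[0]
        want = float(np.mean(rec.values["reactivity"] / rec.errors["reactivity"]))
        assert record_sn_ratio(rec, ["reactivity"]) == pytest.approx(want)


class TestWithinErrorFraction:
    def test_exact_prediction(self, rng):
        y = rng.random(20)
        assert within_error_fraction(y, y, np.ones(20)) == 1.0

    def test_zero_error_strict(self, rng):
        y = rng.random(20)
        assert within_error_fraction(y + 1e-9, y, np.zeros(20)) == 0.0

    def test_gaussian_perfect_predictor_coverage(self):
        # noise with sd sigma and error bars sigma: expect erf(1/sqrt 2)
        rng = np.random.default_rng(2024)
        n = 100_000
        truth = rng.normal(2.0, 0.5, n)
        sigma = 0.05 + 0.15 * np.sqrt(np.clip(truth, 0, None))
        measured = truth + sigma * rng.standard_normal(n)
        frac = within_error_fraction(truth, measured, sigma)
        expect = 0.682689
        tol = 3 * np.sqrt(expect * (1 - expect) / n)
        assert abs(frac - expect) < tol

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            within_error_fraction([1.0], [1.0, 2.0], [0.1, 0.1])


class TestMotifAggregate:
    def test_uniform_values(self):
        vals = {"c": np.ones(9)}
        structs = {"c": "(((...)))"}
        tab = motif_aggregate(vals, structs)
        present = tab[tab.n > 0]
        assert np.allclose(present["mean"], 1.0)

    def test_triloop_vs_stem_pooling(self):
        db = "(((...)))"
        v = np.zeros(9)
        v[3:6] = 2.0
        tab = motif_aggregate({"c": v}, {"c": db})
        assert tab.loc["triloop", "mean"] == pytest.approx(2.0)
        assert tab.loc["H", "mean"] == pytest.approx(2.0)
        assert tab.loc["S", "mean"] == pytest.approx(0.0)

    def test_symmetric_vs_bulge_partition(self):
        sym = motif_aggregate({"c": np.ones(11)}, {"c": "(.((...)).)"})
        bul = motif_aggregate({"c": np.ones(10)}, {"c": "(.((...)))"})
        assert sym.loc["symmetric_internal", "n"] == 2
        assert sym.loc["B", "n"] == 0
        assert bul.loc["B", "n"] == 1
        assert bul.loc["I", "n"] == 0

    def test_asymmetric_internal(self):
        tab = motif_aggregate({"c": np.ones(12)}, {"c": "(..((...)).)"})
        assert tab.loc["asymmetric_internal", "n"] == 3
        assert tab.loc["symmetric_internal", "n"] == 0

    def test_scored_prefix_only(self):
        vals = {"c": np.ones(4)}  # structure longer than the value array
        tab = motif_aggregate(vals, {"c": "(((...)))"})
        # only positions 0..3 pooled (derived bins overlap the base classes)
        assert tab.loc[list("SHIBMXE"), "n"].sum() == 4

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            motif_aggregate({"c": np.ones(5)}, {"c": "....."}, motifs=("S", "loopy"))

    def test_planted_motif_ordering(self, small_dataset):
        # the generator plants triloop > asymmetric > symmetric offsets;
        # aggregation over the noisy measurements should recover the ranking
        cfg, recs = small_dataset
        vals = {r.id: r.values["deg_Mg_pH10"] for r in recs}
        structs = {r.id: r.structure for r in recs}
        tab = motif_aggregate(vals, structs)
        if tab.loc["triloop", "n"] > 30 and tab.loc["S", "n"] > 30:
            assert tab.loc["triloop", "mean"] > tab.loc["S", "mean"]


class TestRankCorrelation:
    def test_perfect_monotone(self, rng):
        x = rng.random(20)
        rho, p = rank_correlation(x, 2 * x + 1)
        assert rho == pytest.approx(1.0)
        rho, _ = rank_correlation(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_ties_match_exhaustive_rank_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 1.0, 4.0])
        y = np.array([0.5, 0.5, 1.0, 2.0, 0.1, 1.5])
        rho, _ = rank_correlation(x, y)
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        want = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(float(want))

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            rank_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_too_short(self):
        with pytest.raises(ValueError):
            rank_correlation([1.0, 2.0], [2.0, 1.0])


class TestScorePredictions:
    def test_planted_predictions_beat_noise_floor(self, small_dataset):
        cfg, recs = small_dataset
        truth = planted_prediction_set(recs, cfg)
        rep = score_predictions(recs, truth, channels=["reactivity", "deg_Mg_pH10"])
        # residuals are exactly the injected noise, so RMSE ~ mean error bar
        mean_err = float(np.mean(np.concatenate(
            [r.errors["reactivity"] for r in recs]
        )))
        assert rep.per_channel_rmse["reactivity"] == pytest.approx(mean_err, rel=0.2)
        assert 0.5 < rep.within_error_fraction["reactivity"] < 0.8

    def test_counts_scored_positions(self, small_dataset):
        cfg, recs = small_dataset
        truth = planted_prediction_set(recs, cfg)
        rep = score_predictions(recs, truth, channels=["reactivity"])
        assert rep.n_scored_nt["reactivity"] == sum(r.seq_scored for r in recs)

    def test_missing_prediction_channel(self, small_dataset):
        cfg, recs = small_dataset
        truth = planted_prediction_set(recs, cfg, channels=["reactivity"])
        with pytest.raises(KeyError, match="deg_Mg_pH10"):
            score_predictions(recs, truth, channels=["deg_Mg_pH10"])

    def test_unknown_ids_rejected(self, small_dataset):
        cfg, recs = small_dataset
        ps = PredictionSet({"ghost": {"reactivity": np.ones(5)}})
        with pytest.raises(KeyError, match="ghost"):
            score_predictions(recs, ps)
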