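import warnings

import numpy as np
import pytest

from rnadeg.degmodel import (
    DegradationWindowModel,
    LinearDegradationResults,
    WindowFeaturizer,
    count_parameters,
    featurize,
    fit_boosted,
    fit_linear,
    predict_linear,
)
from rnadeg.records import RnaRecord
from rnadeg.synthetic import SyntheticConfig, make_dataset, planted_models


class TestCountParameters:
    @pytest.mark.parametrize("w,expected", [(12, 251), (0, 11), (1, 31)])
    def test_known_values(self, w, expected):
        assert count_parameters(w) == expected

    def test_formula_exact(self):
        for w in range(21):
            assert count_parameters(w) == (2 * w + 1) * 10 + 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_parameters(-1)


class TestFeaturize:
    def test_single_position(self):
        fm = featurize("A", "E", WindowFeaturizer(w=0))
        assert fm.shape == (1, 10)
        assert fm.sum() == 2
        assert fm[0, 0] == 1  # A indicator
        assert fm[0, 4 + 1] == 1  # E indicator (alphabet HEIMBS)

    def test_row_sums_count_in_bounds_offsets(self, rng):
        n = 40
        seq = "".join(rng.choice(list("ACGU"), size=n))
        loops = "E" * n
        fm = featurize(seq, loops, WindowFeaturizer(w=12))
        # interior rows see all 25 offsets; row 0 sees offsets 0..+12
        assert fm[20].sum() == 50
        assert fm[0].sum() == 26
        assert fm[n - 1].sum() == 26

    def test_merge_x_into_e(self):
        fz = WindowFeaturizer(w=0)
        assert np.array_equal(fz.transform("A", "X"), fz.transform("A", "E"))

    def test_alphabet_violations_name_position(self):
        fz = WindowFeaturizer(w=0)
        with pytest.raises(ValueError, match="position 1"):
            fz.transform("AT", "EE")
        with pytest.raises(ValueError, match="position 0"):
            fz.transform("AA", "ZE")

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            featurize("AC", "E")


class TestPredictLinear:
    def test_intercept_only(self):
        fm = np.zeros((4, 10))
        assert np.allclose(predict_linear(np.zeros(10), 0.7, fm), 0.7)

    def test_single_indicator(self):
        fz = WindowFeaturizer(w=0)
        seq, loops = "AUUGU", "EEEEE"
        beta = np.zeros(fz.n_features)
        beta[fz.feature_names().index("+0:U")] = 1.0
        y = predict_linear(beta, 0.0, fz.transform(seq, loops))
        assert np.array_equal(y, [0, 1, 1, 0, 1])

    def test_matches_explicit_double_loop(self, rng):
        """Window prediction equals direct evaluation of the windowed sum."""
        fz = WindowFeaturizer(w=3)
        for _ in range(50):
            n = int(rng.integers(8, 25))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            loops = "".join(rng.choice(list("HEIMBS"), size=n))
            beta = rng.normal(size=fz.n_features)
            beta0 = float(rng.normal())
            y = predict_linear(beta, beta0, fz.transform(seq, loops))
            names = fz.feature_names()
            for i in rng.choice(n, size=3):
                total = beta0
                for k in range(-fz.w, fz.w + 1):
                    if 0 <= i + k < n:
                        total += beta[names.index(f"{k:+d}:{seq[i + k]}")]
                        total += beta[names.index(f"{k:+d}:{loops[i + k]}")]
                assert abs(y[i] - total) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            predict_linear(np.zeros(9), 0.0, np.zeros((3, 10)))


def _records_from_targets(seqs, loopss, targets, channel="deg_Mg_pH10"):
    return [
        RnaRecord(
            id=f"r{i}", sequence=s, structure="." * len(s), predicted_loop_type=lp,
            values={channel: t},
        )
        for i, (s, lp, t) in enumerate(zip(seqs, loopss, targets))
    ]


class TestFitLinear:
    def test_recovers_planted_parameters(self, noiseless_dataset):
        cfg, recs = noiseless_dataset
        true = planted_models(cfg)["reactivity"]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_linear(recs, "reactivity", cfg.featurizer(), ridge_lambda=0.0)
        assert res.nobs >= 5 * cfg.featurizer().n_parameters
        assert np.max(np.abs(res.params - true.params)) < 1e-6
        assert res.training_rmse < 1e-8

    def test_zero_targets_give_zero_model(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=30)) for _ in range(5)]
        loopss = ["E" * 30] * 5
        recs = _records_from_targets(seqs, loopss, [np.zeros(30)] * 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = fit_linear(recs, "deg_Mg_pH10", WindowFeaturizer(w=2), ridge_lambda=0.0)
        assert np.allclose(res.params, 0.0)

    def test_ridge_limit_shrinks_to_intercept(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=30)) for _ in range(5)]
        loopss = ["E" * 30] * 5
        targets = [rng.normal(2.0, 0.5, 30) for _ in range(5)]
        recs = _records_from_targets(seqs, loopss, targets)
        res = fit_linear(recs, "deg_Mg_pH10", WindowFeaturizer(w=2), ridge_lambda=1e9)
        assert np.max(np.abs(res.beta)) < 1e-5
        assert abs(res.beta0 - np.mean(np.concatenate(targets))) < 1e-3

    def test_record_order_invariance(self, small_dataset):
        _, recs = small_dataset
        fz = WindowFeaturizer(w=3)
        a = fit_linear(recs, "deg_Mg_pH10", fz, ridge_lambda=0.1)
        b = fit_linear(recs[::-1], "deg_Mg_pH10", fz, ridge_lambda=0.1)
        assert np.max(np.abs(a.params - b.params)) < 1e-10

    def test_missing_channel_named(self, small_dataset):
        _, recs = small_dataset
        with pytest.raises(KeyError, match="nope"):
            DegradationWindowModel(recs, "nope")

    def test_rank_deficiency_warns(self, noiseless_dataset):
        cfg, recs = noiseless_dataset
        with pytest.warns(RuntimeWarning, match="rank deficient"):
            DegradationWindowModel(recs[:3], "reactivity", cfg.featurizer()).fit(0.0)


class TestSerialization:
    def test_json_roundtrip(self, small_dataset, tmp_path):
        _, recs = small_dataset
        res = fit_linear(recs, "deg_Mg_pH10", WindowFeaturizer(w=4))
        path = tmp_path / "model.json"
        res.to_json(path)
        back = LinearDegradationResults.from_json(path)
        assert np.allclose(back.beta, res.beta)
        assert back.beta0 == pytest.approx(res.beta0)
        assert back.channel == res.channel
        rec = recs[0]
        assert np.allclose(
            back.predict(rec.sequence, loops=rec.predicted_loop_type),
            res.predict(rec.sequence, loops=rec.predicted_loop_type),
        )

    def test_summary_mentions_basics(self, small_dataset):
        _, recs = small_dataset
        res = fit_linear(recs, "deg_Mg_pH10", WindowFeaturizer(w=2))
        s = res.summary()
        assert "deg_Mg_pH10" in s and "RMSE" in s


class TestFitBoosted:
    def test_step_function_beats_linear(self, rng):
        # a sharp threshold on one indicator is easy for trees, hard for a line
        n = 60
        seqs, loopss, targets = [], [], []
        for _ in range(10):
            seq = "".join(rng.choice(list("ACGU"), size=n))
            run = np.array([seq.count("G", max(0, i - 2), i + 3) for i in range(n)])
            targets.append((run >= 2).astype(float) * 5.0)
            seqs.append(seq)
            loopss.append("E" * n)
        recs = _records_from_targets(seqs, loopss, targets)
        fz = WindowFeaturizer(w=2)
        lin = fit_linear(recs, "deg_Mg_pH10", fz, ridge_lambda=0.0)
        boost = fit_boosted(recs, "deg_Mg_pH10", fz, n_estimators=100, max_depth=4, seed=0)
        assert boost.training_rmse < lin.training_rmse

    def test_constant_target_constant_prediction(self, rng):
        seqs = ["".join(rng.choice(list("ACGU"), size=20)) for _ in range(4)]
        recs = _records_from_targets(seqs, ["E" * 20] * 4, [np.full(20, 1.5)] * 4)
        res = fit_boosted(recs, "deg_Mg_pH10", WindowFeaturizer(w=1), n_estimators=20, seed=0)
        y = res.predict(seqs[0], loops="E" * 20)
        assert np.allclose(y, 1.5, atol=1e-3)

    def test_deterministic_given_seed(self, small_dataset):
        _, recs = small_dataset
        fz = WindowFeaturizer(w=2)
        a = fit_boosted(recs[:10], "reactivity", fz, n_estimators=30, seed=5)
        b = fit_boosted(recs[:10], "reactivity", fz, n_estimators=30, seed=5)
        rec = recs[0]
        assert np.array_equal(
            a.predict(rec.sequence, loops=rec.predicted_loop_type),
            b.predict(rec.sequence, loops=rec.predicted_loop_type),
        )

    def test_planted_linear_sanity_bound(self, small_dataset):
        # on noisy planted-linear data the boosted model stays in the same
        # league as the ridge fit on held-out constructs
        cfg, recs = small_dataset
        fz = cfg.featurizer()
        train, held = recs[:22], recs[22:]
        lin = fit_linear(train, "reactivity", fz, ridge_lambda=0.1)
        boost = fit_boosted(train, "reactivity", fz, n_estimators=200, max_depth=5, seed=1)

        def held_rmse(res):
            errs = [
                res.predict(r.sequence, loops=r.predicted_loop_type)[: r.seq_scored]
                - r.values["reactivity"]
                for r in held
            ]
            return float(np.sqrt(np.mean(np.concatenate(errs) ** 2)))

        assert held_rmse(boost) < 2 * held_rmse(lin)
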