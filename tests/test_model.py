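import numpy as np
import pandas as pd
import pytest

from prostacad import (
    CutoffSet,
    SchemaError,
    TableSpec,
    assign_agg_score,
    load_model,
    minmax_fit_apply,
    npv_max_cutoff,
    save_model,
    score,
    simulate_feature_table,
    train_scorer,
    waterfall_data,
    youden_cutoff,
)
from prostacad.stats import delong_auc
import oracles


def trained_on_table(seed=0, n=160, delta=2.0, n_features=8, subset_k=3):
    spec = TableSpec(n_rows=n, n_features=n_features, informative=(0, 1, 2),
                     delta_mu=delta, seed=seed)
    t = simulate_feature_table(spec)
    norm, params = minmax_fit_apply(t)
    subset = list(t.features.columns[:subset_k])
    scorer = train_scorer(norm, subset, C=1, seed=seed, normalization=params)
    return t, scorer


class TestTrainScorer:
    def test_separable_table_perfect_training_accuracy(self):
        x = np.concatenate([np.linspace(0, 0.2, 20), np.linspace(0.8, 1.0, 20)])
        t_df = pd.DataFrame({"x": x})
        from prostacad.selection import FeatureTable

        t = FeatureTable(t_df, np.array([0] * 20 + [1] * 20))
        scorer = train_scorer(t, ["x"], C=1)
        s = scorer.score_frame(t_df)
        assert np.all((s > 0.5) == t.labels.astype(bool))

    def test_score_monotone_in_decision_value(self):
        t, scorer = trained_on_table(seed=1)
        norm = scorer.normalization.apply(t.features[scorer.subset])
        dec = scorer.decision_function(norm.to_numpy(float))
        s = scorer.score_frame(t.features)
        assert np.array_equal(np.argsort(dec), np.argsort(s))

    @pytest.mark.parametrize("seed", range(10))
    def test_heldout_auc_at_least_090(self, seed):
        t, scorer = trained_on_table(seed=seed, n=160, delta=2.0)
        val = simulate_feature_table(
            TableSpec(n_rows=120, n_features=8, informative=(0, 1, 2), delta_mu=2.0,
                      seed=10_000 + seed)
        )
        s = scorer.score_frame(val.features)
        assert delong_auc(s, val.labels) >= 0.90

    def test_single_class_rejected(self):
        from prostacad.selection import FeatureTable
        from prostacad.exceptions import DegenerateDataError

        t = FeatureTable(pd.DataFrame({"x": [0.0, 1.0]}), np.array([1, 1]))
        with pytest.raises(DegenerateDataError):
            train_scorer(t, ["x"], C=1)


class TestScore:
    def test_scoring_is_deterministic_and_bounded(self):
        t, scorer = trained_on_table(seed=2)
        row = t.features.iloc[0].to_dict()
        s1 = score(scorer, row)
        s2 = score(scorer, row)
        assert s1 == s2
        assert 0.0 <= s1 <= 1.0

    def test_missing_feature_named(self):
        t, scorer = trained_on_table(seed=3)
        row = t.features.iloc[0].to_dict()
        missing = scorer.subset[0]
        del row[missing]
        with pytest.raises(SchemaError, match=missing):
            score(scorer, row)

    def test_class_centroids_ordered(self):
        t, scorer = trained_on_table(seed=4)
        pos_c = t.features[t.labels == 1].mean().to_dict()
        neg_c = t.features[t.labels == 0].mean().to_dict()
        assert score(scorer, pos_c) > score(scorer, neg_c)


class TestYoudenCutoff:
    def test_perfect_separation_midpoint(self):
        c = youden_cutoff([0.8, 0.9, 0.1, 0.2], [1, 1, 0, 0])
        assert c == pytest.approx(0.5)

    def test_overlapping_example_bruteforce(self):
        scores = [0.9, 0.4, 0.1, 0.6]
        labels = [1, 1, 0, 0]
        c = youden_cutoff(scores, labels)
        oc, oj = oracles.brute_youden(scores, labels)
        assert c == pytest.approx(oc)
        assert 0.6 < c < 0.9 and oj == pytest.approx(0.5)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(size=30)
        y = rng.integers(0, 2, 30)
        y[:5], y[-5:] = 1, 0
        c1 = youden_cutoff(s, y)
        c2 = youden_cutoff(np.exp(3 * s), y)
        # same induced classification
        assert np.array_equal(s > c1, np.exp(3 * s) > c2)


class TestNpvMaxCutoff:
    def test_enumerated_example(self):
        scores = [0.8, 0.9, 0.1, 0.2, 0.85]
        labels = [1, 1, 0, 0, 0]
        c = npv_max_cutoff(scores, labels)
        neg_called = [s for s in scores if s <= c]
        assert sorted(neg_called) == [0.1, 0.2]

    def test_perfect_separation_full_npv_and_sensitivity(self):
        scores = np.array([0.8, 0.9, 0.1, 0.2])
        labels = np.array([1, 1, 0, 0])
        c = npv_max_cutoff(scores, labels)
        assert c < min(scores[labels == 1])
        assert np.all(scores[labels == 1] > c)  # sensitivity 1
        assert np.all(scores[labels == 0] <= c)  # NPV 1 with max specificity

    def test_zero_false_negatives_on_distinct_scores(self):
        rng = np.random.default_rng(6)
        s = rng.permutation(np.linspace(0, 1, 40))
        y = (s + 0.3 * rng.normal(size=40) > 0.5).astype(int)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        c = npv_max_cutoff(s, y)
        assert ((s <= c) & (y == 1)).sum() == 0


class TestAggScore:
    CUT = CutoffSet(youden=0.42, npv_max=0.39)

    @pytest.mark.parametrize(
        "raw,level",
        [(0.50, "aggressive"), (0.30, "indolent"), (0.40, "indeterminate"),
         (0.42, "indeterminate"), (0.357, "indolent")],
    )
    def test_banding_examples(self, raw, level):
        assert assign_agg_score(raw, self.CUT).level == level

    def test_partition_and_monotonicity(self):
        grid = np.linspace(0, 1, 201)
        levels = [assign_agg_score(r, self.CUT).level for r in grid]
        order = {"indolent": 0, "indeterminate": 1, "aggressive": 2}
        codes = [order[l] for l in levels]
        assert codes == sorted(codes)
        assert set(levels) == {"indolent", "indeterminate", "aggressive"}


class TestWaterfall:
    def test_conservation_and_sign(self):
        scores = [0.1, 0.5, 0.9, 0.42]
        labels = [0, 0, 1, 1]
        cut = 0.42
        df = waterfall_data(scores, labels, cut)
        assert np.allclose(sorted(df["normalized_score"] + cut), sorted(scores))
        for _, row in df.iterrows():
            call_positive = row["normalized_score"] > 0
            assert call_positive == (row["normalized_score"] + cut > cut)

    def test_all_at_cutoff_zero(self):
        df = waterfall_data([0.3, 0.3], [0, 1], 0.3)
        assert np.allclose(df["normalized_score"], 0.0)


class TestModelFile:
    def test_roundtrip_and_integrity(self, tmp_path):
        t, scorer = trained_on_table(seed=7)
        cut = CutoffSet(youden=0.5, npv_max=0.3)
        p = tmp_path / "model.json"
        save_model(p, scorer, cut)
        s2, c2 = load_model(p)
        assert s2.subset == scorer.subset
        assert np.allclose(
            s2.score_frame(t.features), scorer.score_frame(t.features)
        )
        # tamper
        text = p.read_text().replace('"C": 1.0', '"C": 2.0')
        p.write_text(text)
        with pytest.raises(SchemaError, match="integrity"):
            load_model(p)
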