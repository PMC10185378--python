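import numpy as np
import pandas as pd
import pytest

import actionspace as a


@pytest.fixture(scope="module")
def small_matrix():
    """120-action study-like matrix: enough for split halves, fast to fit."""
    cfg = a.default_config(n_actions=120, seed=23)
    return a.aggregate_means(a.simulate_study(cfg).study)


class TestSplitHalf:
    def test_deterministic_under_seed(self, small_matrix):
        r1 = a.split_half_convert(small_matrix, k=4, seed=99)
        r2 = a.split_half_convert(small_matrix, k=4, seed=99)
        assert r1.model_half_ids == r2.model_half_ids
        assert r1.fit.aic == pytest.approx(r2.fit.aic, abs=1e-9)

    def test_halves_partition_the_actions(self, small_matrix):
        rec = a.split_half_convert(small_matrix, k=4, seed=1)
        assert len(rec.model_half_ids) == 60 and len(rec.test_half_ids) == 60
        assert not set(rec.model_half_ids) & set(rec.test_half_ids)
        assert set(rec.model_half_ids) | set(rec.test_half_ids) == set(
            small_matrix.row_ids)

    def test_240_actions_split_120_120(self, default_matrix):
        rec = a.split_half_convert(default_matrix, k=4, seed=0)
        assert len(rec.model_half_ids) == len(rec.test_half_ids) == 120

    def test_spec_recovers_generating_assignment(self, default_matrix):
        cfg = a.default_config(seed=11)   # truth behind default_matrix fixture
        true_factor = np.argmax(np.abs(cfg.lambda_true), axis=1)
        hits = []
        for seed in range(3):
            rec = a.split_half_convert(default_matrix, k=4, seed=seed)
            efa = a.fit_efa(default_matrix.subset(actions=rec.model_half_ids),
                            k=4, seed=0)
            spec = a.build_cfa_spec(efa)
            rep = a.congruence(efa.pattern, cfg.lambda_true)
            mapped = [rep.column_map[spec.assignment[it]] for it in spec.items]
            hits.append(np.mean(np.array(mapped) == true_factor))
        assert np.mean(hits) >= 0.9


@pytest.fixture(scope="module")
def comparison(small_matrix):
    return a.compare_models(small_matrix, ks=(2, 3, 4, 5), n_sims=8,
                            master_seed=7)


class TestCompareModels:
    def test_reference_delta_is_zero(self, comparison):
        assert comparison.delta_aic.loc[4, "delta_aic_mean"] == 0.0

    def test_paired_design_shares_partitions(self, comparison):
        recs = comparison.records
        seeds_by_k = recs.groupby("k")["seed"].apply(list)
        for k in (2, 3, 5):
            assert seeds_by_k[k] == seeds_by_k[4]

    def test_four_factor_truth_wins(self, comparison):
        assert comparison.winner == 4
        for k in (2, 3):
            assert comparison.delta_aic.loc[k, "delta_aic_mean"] > 2.0

    def test_summary_has_ci_columns(self, comparison):
        for stat in ("chi2", "cfi", "rmsea", "aic"):
            assert {f"{stat}_mean", f"{stat}_ci_low", f"{stat}_ci_high"} <= set(
                comparison.summary.columns)
        lo = comparison.summary["aic_ci_low"]
        hi = comparison.summary["aic_ci_high"]
        assert (lo <= comparison.summary["aic_mean"]).all()
        assert (comparison.summary["aic_mean"] <= hi).all()

    def test_single_simulation_collapses_ci(self, small_matrix):
        cmp1 = a.compare_models(small_matrix, ks=(2, 4), n_sims=1, master_seed=3)
        row = cmp1.summary.loc[4]
        assert row["aic_ci_low"] == row["aic_mean"] == row["aic_ci_high"]

    def test_csv_and_manifest_writers(self, comparison, tmp_path):
        from actionspace.selection import comparison_to_csv, manifest_to_json
        comparison_to_csv(comparison, tmp_path / "cmp.csv")
        manifest_to_json(comparison, tmp_path / "cmp.json")
        back = pd.read_csv(tmp_path / "cmp.csv", index_col=0)
        assert len(back) == 4


class TestDecimation:
    def test_action_decimation_levels_and_winner(self, small_matrix):
        curve = a.decimate_actions(small_matrix, ks=(2, 4), grid=(120, 100),
                                   n_sims=4, master_seed=5)
        assert sorted(curve["level"].unique()) == [100, 120]
        assert (curve[curve["k"] == 4]["delta_aic_mean"] == 0).all()
        assert (curve["winner_k"] == 4).all()

    def test_rater_decimation_shrinks_separation(self):
        cfg = a.default_config(n_actions=120, seed=31)
        study = a.simulate_study(cfg).study
        curve = a.decimate_raters(study, ks=(2, 4), rater_counts=(10, 2),
                                  n_sims=4, master_seed=5)
        d10 = curve[(curve["rater_count"] == 10) & (curve["k"] == 2)][
            "delta_aic_mean"].iloc[0]
        d2 = curve[(curve["rater_count"] == 2) & (curve["k"] == 2)][
            "delta_aic_mean"].iloc[0]
        assert d10 > 2.0
        assert d2 < d10     # noisier aggregates blur the model separation

    def test_rater_count_above_pool_rejected(self):
        cfg = a.default_config(n_actions=60, seed=1)
        study = a.simulate_study(cfg).study
        with pytest.raises(a.ValidationError):
            a.decimate_raters(study, rater_counts=(12,), n_sims=1)


class TestRecognisabilitySplit:
    def test_full_overlap_gives_identical_summaries(self, small_matrix):
        rng = np.random.default_rng(0)
        matches = rng.integers(0, 2, size=(30, small_matrix.shape[0])).astype(float)
        rec = a.recognisability(matches, action_ids=small_matrix.row_ids)
        out = a.recognisability_split(small_matrix, rec, ks=(2, 4),
                                      top_n=small_matrix.shape[0], n_sims=3,
                                      master_seed=2)
        pd.testing.assert_frame_equal(out["most"].summary, out["least"].summary)

    def test_partial_overlap_subsets_share_middle(self, small_matrix):
        rng = np.random.default_rng(1)
        matches = rng.integers(0, 2, size=(30, 120)).astype(float)
        rec = a.recognisability(matches, action_ids=small_matrix.row_ids)
        out = a.recognisability_split(small_matrix, rec, ks=(2, 4), top_n=90,
                                      n_sims=2, master_seed=2)
        assert set(out) == {"most", "least"}
        for cmp_ in out.values():
            assert cmp_.n_sims == 2


class TestFactorReliability:
    def test_exact_copies_give_unit_icc(self, small_matrix):
        values = small_matrix.values.copy()
        values["dup"] = values[values.columns[0]]
        dup_matrix = a.MeanRatingMatrix(values=values)
        structure = np.zeros((values.shape[1], 2))
        structure[0, 0] = structure[-1, 0] = 0.9    # original + its copy
        structure[1:3, 1] = 0.8
        interp = a.interpret(structure, items=list(values.columns))
        out = a.factor_reliability(dup_matrix, interp)
        assert out[0].kappa == pytest.approx(1.0)

    def test_negative_loader_reverse_coded(self, small_matrix):
        values = small_matrix.values.copy()
        values["mirror"] = 10.0 - values[values.columns[0]]
        mat = a.MeanRatingMatrix(values=values)
        structure = np.zeros((values.shape[1], 2))
        structure[0, 0] = 0.9
        structure[-1, 0] = -0.9       # mirrored item loads negatively
        structure[1:3, 1] = 0.8
        interp = a.interpret(structure, items=list(values.columns))
        out = a.factor_reliability(mat, interp)
        assert out[0].kappa == pytest.approx(1.0)   # perfect after reversal

    def test_factor_rater_count_sets_df(self, default_matrix):
        efa = a.fit_efa(default_matrix, k=4, seed=0)
        interp = a.interpret(efa.structure_frame())
        out = a.factor_reliability(default_matrix, interp)
        for factor, res in out.items():
            n_items = len(interp.per_factor[factor])
            assert res.df2 == 239 * (n_items - 1)
            assert res.df1 == 239

    def test_single_item_factor_skipped(self, small_matrix):
        structure = np.zeros((small_matrix.shape[1], 2))
        structure[0, 0] = 0.9                      # lone item on factor 0
        structure[1:4, 1] = 0.8
        interp = a.interpret(structure, items=small_matrix.col_ids)
        out = a.factor_reliability(small_matrix, interp)
        assert 0 not in out and 1 in out
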