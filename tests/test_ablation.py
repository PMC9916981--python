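"""AU ablation, accent derivation, model optimization, splits, comparisons."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_trials
from hypkernel import au_space
from hypkernel.ablation import (
    ablate,
    ablation_map,
    compare_cultures,
    compare_to_chance,
    derive_accents,
    optimize_model,
    split_train_test,
)
from hypkernel.kernel import au_matrix, evaluate_model
from hypkernel.models import HypothesisModel, lateralize
from hypkernel.simulate import StimulusSpec, generate_stimuli


def _model(configs, name="m"):
    return HypothesisModel(name=name, task="basic6", configs=configs)


class TestAblate:
    def test_removing_one_au_leaves_the_rest(self):
        m = _model({"disgust": lateralize({9, 25})})
        out = ablate(m, "disgust", 9)
        assert out.config_sets("disgust") == [{"25"}]

    def test_bilateral_number_removes_both_sides(self):
        m = _model({"happy": lateralize({6, 12})})
        out = ablate(m, "happy", 12)
        assert out.config_sets("happy") == [{"6L", "6R"}]

    def test_single_lateral_coordinate_can_be_ablated(self):
        m = _model({"happy": lateralize({6, 12})})
        out = ablate(m, "happy", "12L")
        assert out.config_sets("happy") == [{"6L", "6R", "12R"}]

    def test_emptied_configurations_dropped_and_deduplicated(self):
        m = _model({"disgust": np.vstack([lateralize({9}), lateralize({9, 25})])})
        out = ablate(m, "disgust", 25)
        assert out.config_sets("disgust") == [{"9"}]

    def test_ablating_the_whole_category_rejected(self):
        m = _model({"disgust": lateralize({9})})
        with pytest.raises(ValueError, match="empties"):
            ablate(m, "disgust", 9)

    def test_absent_au_rejected_not_silently_zero(self):
        m = _model({"disgust": lateralize({9, 25})})
        with pytest.raises(ValueError, match="no configuration"):
            ablate(m, "disgust", 17)

    def test_other_categories_untouched(self):
        m = _model({"disgust": lateralize({9, 25}), "happy": lateralize({6, 12})})
        out = ablate(m, "disgust", 9)
        np.testing.assert_array_equal(out.configs["happy"], m.configs["happy"])

    def test_ablate_then_restore_reproduces_auroc_bit_identically(self):
        rng = np.random.default_rng(8)
        m = _model({"disgust": lateralize({9, 25}), "happy": lateralize({6, 12})})
        stim = generate_stimuli(StimulusSpec(n_stimuli=300), rng=rng)
        labels = rng.choice(["disgust", "happy"], size=300)
        trials = make_trials(au_matrix(stim), labels)
        base = evaluate_model(trials, m)
        restored = ablate(m, "disgust", 9)
        restored.configs["disgust"] = m.configs["disgust"].copy()
        again = evaluate_model(trials, restored)
        assert (base["auroc"] == again["auroc"]).all()


class TestAblationMap:
    def test_au_absent_from_all_models_stays_undefined(self):
        rng = np.random.default_rng(9)
        m = _model({"disgust": lateralize({9, 25}), "happy": lateralize({6, 12})})
        stim = generate_stimuli(StimulusSpec(n_stimuli=200), rng=rng)
        labels = rng.choice(["disgust", "happy"], size=200)
        amap = ablation_map([m], make_trials(au_matrix(stim), labels))
        assert np.isnan(amap.loc["disgust", "17"])
        assert not np.isnan(amap.loc["disgust", "9"])

    def test_planted_dependence_yields_negative_delta(self):
        # observers respond via a model in which AU9 drives disgust:
        # ablating 9 must hurt the prediction of their behavior
        rng = np.random.default_rng(10)
        m = _model({"disgust": lateralize({9, 25}), "happy": lateralize({6, 12})})
        stim = generate_stimuli(StimulusSpec(n_stimuli=1500), rng=rng)
        S = au_matrix(stim)
        from hypkernel.kernel import category_scores

        scores, cats = category_scores(S, m)
        labels = np.array(cats)[(scores + rng.gumbel(size=scores.shape) / 12).argmax(1)]
        amap = ablation_map([m], make_trials(S, labels))
        assert amap.loc["disgust", "9"] < 0

    def test_one_config_categories_skip_without_aborting(self):
        rng = np.random.default_rng(11)
        m = _model({"disgust": lateralize({9}), "happy": lateralize({6, 12})})
        stim = generate_stimuli(StimulusSpec(n_stimuli=200), rng=rng)
        labels = rng.choice(["disgust", "happy"], size=200)
        amap = ablation_map([m], make_trials(au_matrix(stim), labels))
        # ablating 9 would empty disgust: the cell stays undefined
        assert np.isnan(amap.loc["disgust", "9"])
        assert np.isfinite(amap.loc["happy", "6L"])


class TestDeriveAccents:
    def _map(self, values):
        df = pd.DataFrame(np.nan, index=["disgust"], columns=list(au_space.CANONICAL_ORDER))
        for k, v in values.items():
            df.loc["disgust", k] = v
        return {"WE": df}

    def test_sign_rule(self):
        acc = derive_accents(self._map({"9": -0.03, "25": 0.02}))
        assert acc["WE"]["disgust"] == {"critical": ["9"], "detrimental": ["25"]}

    def test_dead_zone_excludes_small_effects(self):
        acc = derive_accents(self._map({"9": 0.01}), epsilon=0.02)
        assert acc["WE"]["disgust"] == {"critical": [], "detrimental": []}

    def test_all_undefined_yields_empty_sets(self):
        acc = derive_accents(self._map({}))
        assert acc["WE"]["disgust"] == {"critical": [], "detrimental": []}

    def test_critical_and_detrimental_always_disjoint(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame(
            rng.normal(0, 0.02, size=(6, 33)),
            index=list("abcdef"), columns=list(au_space.CANONICAL_ORDER),
        )
        acc = derive_accents({"X": df}, epsilon=0.005)
        for cat in acc["X"]:
            assert not set(acc["X"][cat]["critical"]) & set(acc["X"][cat]["detrimental"])


class TestOptimizeModel:
    def _accents(self, critical=(), detrimental=(), cat="disgust"):
        return {"EA": {cat: {"critical": list(critical), "detrimental": list(detrimental)}}}

    def test_add_critical_remove_detrimental(self):
        m = _model({"disgust": lateralize({10, 25})})
        out, flags = optimize_model(m, self._accents(["9"], ["25"]), "EA")
        assert out.config_sets("disgust") == [{"9", "10L", "10R"}]
        assert flags == {"disgust": False}

    def test_empty_accents_leave_model_unchanged(self):
        m = _model({"disgust": lateralize({10, 25})})
        out, _ = optimize_model(m, self._accents(), "EA")
        np.testing.assert_array_equal(out.configs["disgust"], m.configs["disgust"])

    def test_idempotent_when_critical_already_present(self):
        m = _model({"disgust": lateralize({9, 25})})
        out, _ = optimize_model(m, self._accents(critical=["9"]), "EA")
        np.testing.assert_array_equal(out.configs["disgust"], m.configs["disgust"])

    def test_emptied_category_keeps_best_original_and_flags(self):
        cfgs = np.vstack([lateralize({25}), lateralize({25, 26})])
        m = _model({"disgust": cfgs})
        out, flags = optimize_model(m, self._accents(detrimental=["25", "26"]), "EA")
        assert flags["disgust"]
        assert out.config_sets("disgust") == [{"25", "26"}]  # largest original

    def test_unknown_culture_rejected(self):
        m = _model({"disgust": lateralize({9})})
        with pytest.raises(ValueError, match="culture"):
            optimize_model(m, self._accents(), "WE")


class TestSplit:
    def test_sixty_participants_split_forty_twenty(self, small_trials):
        # scaled-down structure check is done on the fixture cultures below;
        # the printed 40/20 arithmetic is checked directly
        parts = [f"p{i}" for i in range(60)]
        rng = np.random.default_rng(0)
        df = pd.concat(
            [
                make_trials(
                    np.eye(33)[rng.integers(0, 33, size=4)],
                    rng.choice(["happy", "fear"], 4),
                    participant=p,
                    culture="WE",
                )
                for p in parts
            ],
            ignore_index=True,
        )
        df["face_id"] = rng.choice([f"f{i}" for i in range(8)], size=len(df))
        plan = split_train_test(df, 2 / 3, seed=5)
        assert len(plan.train_participants["WE"]) == 40
        assert len(plan.test_participants["WE"]) == 20

    def test_partitions_disjoint_and_dropped_counted(self, small_trials):
        plan = split_train_test(small_trials, seed=3)
        plan.assert_disjoint()
        train, test = plan.train_trials(small_trials), plan.test_trials(small_trials)
        assert set(train["stimulus_key"]).isdisjoint(test["stimulus_key"])
        assert set(train["face_id"]).isdisjoint(test["face_id"])
        assert set(train["participant_id"]).isdisjoint(test["participant_id"])
        assert plan.dropped_trials == len(small_trials) - len(train) - len(test)
        assert plan.dropped_trials > 0

    def test_same_seed_reproduces_plan(self, small_trials):
        a = split_train_test(small_trials, seed=9)
        b = split_train_test(small_trials, seed=9)
        assert a.to_dict() == b.to_dict()

    def test_too_few_participants_rejected(self):
        df = make_trials(np.eye(33)[:4], ["happy"] * 4)
        with pytest.raises(ValueError, match=">=2"):
            split_train_test(df, seed=0)


class TestCompareCultures:
    def _table(self, a, b, cat="happy"):
        rows = []
        for i, v in enumerate(a):
            rows.append((f"w{i}", "WE", "m", cat, v, 5, 5))
        for i, v in enumerate(b):
            rows.append((f"e{i}", "EA", "m", cat, v, 5, 5))
        return pd.DataFrame(
            rows, columns=["participant", "culture", "model", "category",
                           "auroc", "n_pos", "n_neg"],
        )

    def test_identical_groups_give_null_statistics(self):
        out = compare_cultures(self._table([0.6, 0.7], [0.6, 0.7]))
        assert out.loc[0, "t"] == pytest.approx(0.0)
        assert out.loc[0, "cohens_d"] == pytest.approx(0.0)

    def test_textbook_two_by_two_example(self):
        # groups (0.7, 0.8) vs (0.5, 0.6): pooled SD = sqrt(0.005),
        # d = 0.2/0.0707 = 2.828, t = d * sqrt(n1*n2/(n1+n2)) = 2.828
        out = compare_cultures(self._table([0.7, 0.8], [0.5, 0.6]))
        t, p = stats.ttest_ind([0.7, 0.8], [0.5, 0.6])
        assert out.loc[0, "t"] == pytest.approx(t)
        assert out.loc[0, "t"] == pytest.approx(2.8284, abs=1e-4)
        assert out.loc[0, "cohens_d"] == pytest.approx(2.8284, abs=1e-4)
        assert out.loc[0, "p"] == pytest.approx(p)

    def test_sign_convention_first_culture_minus_second(self):
        out = compare_cultures(self._table([0.5, 0.6], [0.7, 0.8]))
        assert out.loc[0, "t"] < 0 and out.loc[0, "cohens_d"] < 0
        assert (out.loc[0, "culture_1"], out.loc[0, "culture_2"]) == ("WE", "EA")

    def test_averages_over_models_before_testing(self):
        t1 = self._table([0.6, 0.7], [0.5, 0.6])
        t2 = t1.copy()
        t2["model"] = "m2"
        t2["auroc"] += 0.1
        out = compare_cultures(pd.concat([t1, t2], ignore_index=True))
        expect = compare_cultures(self._table([0.65, 0.75], [0.55, 0.65]))
        assert out.loc[0, "t"] == pytest.approx(expect.loc[0, "t"])

    def test_type_one_error_calibrated_under_null(self):
        # both cultures drawn from one generator: rejections should occur
        # at the nominal alpha
        rng = np.random.default_rng(123)
        hits = 0
        reps = 1000
        for _ in range(reps):
            a = rng.normal(0.7, 0.05, size=20)
            b = rng.normal(0.7, 0.05, size=20)
            out = compare_cultures(self._table(a, b))
            hits += out.loc[0, "p"] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_never_corrected_flag_present(self):
        out = compare_cultures(self._table([0.6, 0.7], [0.5, 0.6]))
        assert (~out["corrected"]).all()

    def test_chance_comparison_one_sample(self):
        table = self._table([0.6, 0.7, 0.8], [0.5, 0.5, 0.5])
        out = compare_to_chance(table)
        vals = [0.6, 0.7, 0.8, 0.5, 0.5, 0.5]
        t, p = stats.ttest_1samp(vals, 0.5)
        row = out.loc[out["model"] == "m"].iloc[0]
        assert row["t"] == pytest.approx(t) and row["p"] == pytest.approx(p)
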