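"""Synthetic observers: mechanistic tracker and generative log-error model."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats

from dazzletrack import (
    MODEL_LADDER,
    ObserverParams,
    TrialSpec,
    build_design,
    cursor_agent,
    default_confusion_params,
    default_design,
    generate_error_table,
    null_confusion_params,
    run_trial,
    simulate_tracks,
)
from dazzletrack.motion import ArenaSpec, MotionParams


class TestCursorAgent:
    def test_noiseless_agent_sits_on_target(self, arena, motion_params):
        tracks = simulate_tracks(5, motion_params, arena, seed=0)
        obs = ObserverParams(lag_ms=0, pos_noise_sd=0, swap_base_rate=0,
                             condition_multipliers={})
        cursor = cursor_agent(tracks, 2, obs, np.random.default_rng(0))
        assert np.array_equal(cursor, tracks[2].positions)

    def test_single_target_never_swaps(self, arena, motion_params):
        tracks = simulate_tracks(1, motion_params, arena, seed=1)
        obs = ObserverParams(lag_ms=0, pos_noise_sd=0, swap_base_rate=5.0,
                             condition_multipliers={})
        cursor = cursor_agent(tracks, 0, obs, np.random.default_rng(0))
        assert np.array_equal(cursor, tracks[0].positions)

    def test_lag_shifts_cursor_back_in_time(self, arena, motion_params):
        tracks = simulate_tracks(1, motion_params, arena, seed=2)
        obs = ObserverParams(lag_ms=100, pos_noise_sd=0, swap_base_rate=0,
                             condition_multipliers={})
        cursor = cursor_agent(tracks, 0, obs, np.random.default_rng(0))
        assert np.array_equal(cursor[50:], tracks[0].positions[40:490])

    def test_invalid_target_index_rejected(self, arena, motion_params):
        tracks = simulate_tracks(2, motion_params, arena, seed=3)
        with pytest.raises(ValueError):
            cursor_agent(tracks, 5, ObserverParams(), np.random.default_rng(0))

    def test_confusion_grows_with_group_size(self):
        # Light Monte-Carlo version of the confusion effect: widely spaced
        # group sizes must rank correctly in mean error.
        means = []
        for g in (1, 20, 60):
            errs = [run_trial(TrialSpec("trinary", "plain", g, seed=1000 * g + r),
                              ObserverParams()).error_px for r in range(30)]
            means.append(np.mean(errs))
        assert means[0] < means[1] < means[2]

    def test_mechanism_and_generative_model_agree_in_sign(self):
        # Mean log errors from the cursor agent regressed on group size show
        # a positive slope, matching the generative model's number trend.
        sizes, logmeans = [], []
        for g in (1, 20, 60):
            errs = [run_trial(TrialSpec("trinary", "plain", g, seed=77000 + 131 * g + r),
                              ObserverParams()).error_px for r in range(20)]
            sizes.append(g)
            logmeans.append(np.log(np.mean(errs)))
        slope = np.polyfit(sizes, logmeans, 1)[0]
        assert slope > 0
        assert default_confusion_params().beta_n1 > 0


class TestGenerateErrorTable:
    def test_zero_noise_reproduces_linear_predictor(self):
        params = replace(default_confusion_params(),
                         participant_sd=0.0, resid_sd=1e-12)
        design = default_design(1)
        table = generate_error_table(design, params, 2, seed=0)
        exog = build_design(design, MODEL_LADDER[4])
        lp = exog.to_numpy() @ params.coefficients(exog.columns)
        assert np.allclose(table[table.participant == 1]["log_error"], lp, atol=1e-9)

    def test_intercept_only_model_recovers_mean_error(self):
        params = replace(default_confusion_params(),
                         beta0=np.log(50.0), beta_n1=0, beta_n2=0,
                         coloration_effects={"parallel": 0, "orthogonal": 0},
                         background_effect=0,
                         interaction_linear={"parallel": 0, "orthogonal": 0},
                         interaction_quad={"parallel": 0, "orthogonal": 0},
                         participant_sd=0.0, resid_sd=1e-9)
        table = generate_error_table(default_design(1), params, 2, seed=0)
        assert np.allclose(table["error_px"], 50.0)

    def test_errors_are_lognormal_within_cell(self):
        params = default_confusion_params()
        design = pd.DataFrame([{"coloration": "parallel", "background": "plain",
                                "group_size": 30}] * 250)
        table = generate_error_table(design, params, 2, seed=4)
        one_cell = table[table.participant == 1]
        assert len(one_cell) == 250
        assert stats.shapiro(one_cell["log_error"]).pvalue > 0.01
        assert stats.shapiro(one_cell["error_px"]).pvalue < 0.01  # raw scale is skewed

    def test_participant_relabeling_preserves_marginal_errors(self):
        table = generate_error_table(default_design(1), default_confusion_params(),
                                     4, seed=6)
        relabeled = table.copy()
        mapping = {1: 3, 3: 1, 2: 4, 4: 2}
        relabeled["participant"] = relabeled["participant"].map(mapping)
        assert np.array_equal(np.sort(relabeled["error_px"]), np.sort(table["error_px"]))

    def test_participant_intercepts_share_one_offset(self):
        params = replace(default_confusion_params(), participant_sd=1.0,
                         resid_sd=1e-9)
        design = default_design(1)
        table = generate_error_table(design, params, 8, seed=8)
        exog = build_design(design, MODEL_LADDER[4])
        lp = exog.to_numpy() @ params.coefficients(exog.columns)
        offsets = [np.ptp(table[table.participant == p]["log_error"].to_numpy() - lp)
                   for p in range(1, 9)]
        assert max(offsets) < 1e-6  # constant shift within participant
        inters = [float((table[table.participant == p]["log_error"].to_numpy() - lp)[0])
                  for p in range(1, 9)]
        assert np.std(inters) > 0.1  # but participants differ

    def test_requires_two_participants(self):
        with pytest.raises(ValueError):
            generate_error_table(default_design(1), default_confusion_params(),
                                 1, seed=0)


def test_default_params_have_parallel_only_interaction():
    p = default_confusion_params()
    assert p.interaction_linear["parallel"] > 0
    assert p.interaction_linear["orthogonal"] == 0
    assert p.coloration_effects["orthogonal"] == 0  # orthogonal == trinary
    n = null_confusion_params()
    assert all(v == 0 for v in n.interaction_linear.values())
    assert all(v == 0 for v in n.interaction_quad.values())
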