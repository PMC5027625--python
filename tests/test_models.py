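"""Mixed-model ladder, AIC bookkeeping, and within-subject CIs."""

import subprocess
import textwrap
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from dazzletrack import (
    MODEL_LADDER,
    build_design,
    compare_models,
    default_confusion_params,
    default_design,
    fit_mixed,
    generate_error_table,
    number_poly,
    within_subject_ci,
)

# Table of fixed-coefficient + variance-component counts for the seven
# candidate models, derived by term-by-term enumeration of the designs.
EXPECTED_K = {0: 14, 1: 20, 2: 16, 3: 14, 4: 12, 5: 8, 6: 9}


@pytest.fixture(scope="module")
def trial_table():
    return generate_error_table(default_design(8), default_confusion_params(),
                                16, seed=202)


@pytest.fixture(scope="module")
def ladder(trial_table):
    return compare_models(trial_table)


class TestNumberPoly:
    def test_basis_is_orthogonal_and_standardized_over_canonical_sizes(self):
        n1, n2 = number_poly([1, 10, 20, 30, 40, 50, 60])
        assert abs(n1.sum()) < 1e-9 and abs(n2.sum()) < 1e-9
        assert abs(np.dot(n1, n2)) < 1e-9
        assert n1.std() == pytest.approx(1.0) and n2.std() == pytest.approx(1.0)
        assert n1[-1] > n1[0]  # increasing linear term
        assert n2[0] > 0 and n2[3] < 0  # convex quadratic term


class TestBuildDesign:
    @pytest.mark.parametrize("mid,k", sorted(EXPECTED_K.items()))
    def test_parameter_count_ledger(self, mid, k):
        X = build_design(default_design(1), MODEL_LADDER[mid])
        assert X.shape[1] + 2 == k

    def test_model4_has_ten_fixed_coefficients(self):
        X = build_design(default_design(1), MODEL_LADDER[4])
        assert X.shape[1] == 10  # 1 + 2 target + 1 background + 2 number + 4 interaction

    def test_merged_coding_halves_target_columns(self):
        x4 = build_design(default_design(1), MODEL_LADDER[4])
        x6 = build_design(default_design(1), MODEL_LADDER[6])
        t4 = [c for c in x4 if c.startswith("target") and ":" not in c]
        t6 = [c for c in x6 if c.startswith("target") and ":" not in c]
        i4 = [c for c in x4 if ":" in c]
        i6 = [c for c in x6 if ":" in c]
        assert len(t6) * 2 == len(t4) and len(i6) * 2 == len(i4)

    def test_unknown_level_rejected(self):
        bad = pd.DataFrame({"coloration": ["spots"], "background": ["plain"],
                            "group_size": [10]})
        with pytest.raises(ValueError):
            build_design(bad, MODEL_LADDER[4])


class TestFitMixed:
    def test_aic_identity_holds_for_every_fit(self, ladder):
        for fit in ladder.fits.values():
            assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.k)
            assert np.isfinite(fit.aic)

    def test_k_matches_ledger(self, ladder):
        for mid, fit in ladder.fits.items():
            assert fit.k == EXPECTED_K[mid]

    def test_nested_models_never_lose_likelihood(self, ladder):
        ll = {mid: fit.loglik for mid, fit in ladder.fits.items()}
        tol = 1e-4
        for small, big in [(5, 4), (4, 3), (3, 2), (2, 1), (6, 4), (0, 1)]:
            assert ll[big] >= ll[small] - tol

    def test_full_rank_codings_agree_on_likelihood(self, trial_table):
        a = fit_mixed(trial_table, MODEL_LADDER[4], ref_coloration="trinary")
        b = fit_mixed(trial_table, MODEL_LADDER[4], ref_coloration="parallel")
        assert a.loglik == pytest.approx(b.loglik, abs=1e-5)
        assert a.aic == pytest.approx(b.aic, abs=1e-4)

    def test_single_participant_rejected(self, trial_table):
        solo = trial_table[trial_table.participant == 1]
        with pytest.raises(ValueError):
            fit_mixed(solo, MODEL_LADDER[5])

    def test_matches_lme4_maximum_likelihood(self, tmp_path):
        """lme4 (the analysis tool the study used) is the independent oracle."""
        table = generate_error_table(default_design(2),
                                     default_confusion_params(), 4, seed=7)
        n1, n2 = number_poly(table["group_size"].to_numpy())
        table = table.assign(n1=n1, n2=n2)
        csv = tmp_path / "table.csv"
        table.to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            d$coloration <- relevel(factor(d$coloration), ref="trinary")
            d$background <- relevel(factor(d$background), ref="plain")
            m <- lmer(log_error ~ coloration + background + n1 + n2 +
                      coloration:n1 + coloration:n2 + (1|participant),
                      data=d, REML=FALSE)
            cat(sprintf("%.6f %.6f %d", logLik(m), AIC(m), attr(logLik(m), "df")))
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True,
                             text=True, check=True)
        r_loglik, r_aic, r_df = out.stdout.split()
        fit = fit_mixed(table, MODEL_LADDER[4])
        assert fit.loglik == pytest.approx(float(r_loglik), abs=1e-3)
        assert fit.aic == pytest.approx(float(r_aic), abs=1e-2)
        assert fit.k == int(r_df)


class TestCompareModels:
    def test_table_sorted_with_delta_aic(self, ladder):
        aic = ladder.table["aic"].to_numpy()
        assert np.all(np.diff(aic) >= 0)
        assert ladder.table["delta_aic"].iloc[0] == 0.0
        near = ladder.table["delta_aic"] < 2.0
        assert (ladder.table.loc[near, "note"] == "prefer fewer terms").all()

    def test_identical_data_identical_table(self, trial_table):
        a = compare_models(trial_table, {4: MODEL_LADDER[4], 5: MODEL_LADDER[5]})
        b = compare_models(trial_table, {4: MODEL_LADDER[4], 5: MODEL_LADDER[5]})
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_parsimony_rule_prefers_fewer_parameters_on_near_ties(self, ladder):
        chosen = ladder.select()
        near = ladder.table[ladder.table["delta_aic"] < 2.0]
        assert chosen in set(near["model_id"])
        assert ladder.fits[chosen].k == near["k"].min()


class TestWithinSubjectCI:
    def test_identical_within_participant_patterns_collapse_ci(self):
        design = default_design(1)
        cells = design.drop_duplicates().reset_index(drop=True)
        rows = []
        for p, offset in enumerate([0.0, 1.0, -2.0, 0.5], start=1):
            for _, cell in cells.iterrows():
                rows.append({"participant": p, **cell,
                             "log_error": offset + 0.01 * cell.group_size})
        data = pd.DataFrame(rows)
        out = within_subject_ci(data)
        assert len(out) == 42
        assert np.allclose(out["ci_half_width"], 0.0, atol=1e-9)

    def test_no_offsets_reduces_to_ordinary_ci_times_morey(self):
        rng = np.random.default_rng(0)
        design = default_design(1)
        frames = []
        for p in range(1, 9):
            df = design.copy()
            df.insert(0, "participant", p)
            df["log_error"] = rng.normal(3.0, 0.5, len(df))
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        out = within_subject_ci(data)
        # Centering removes each participant's mean; with no true offsets the
        # per-cell spread only loses the (tiny) between-participant component.
        from scipy import stats as ss

        cell = data[(data.coloration == "parallel") & (data.background == "plain")
                    & (data.group_size == 1)]["log_error"]
        plain_half = ss.t.ppf(0.975, 7) * cell.std(ddof=1) / np.sqrt(8)
        got = out[(out.coloration == "parallel") & (out.background == "plain")
                  & (out.group_size == 1)]["ci_half_width"].iloc[0]
        morey = np.sqrt(42 / 41)
        assert got == pytest.approx(plain_half * morey, rel=0.25)

    def test_seven_sizes_six_conditions_give_42_cells(self, trial_table):
        out = within_subject_ci(trial_table)
        assert len(out) == 42
        assert (out["n_participants"] == 16).all()

    def test_single_participant_rejected(self, trial_table):
        solo = trial_table[trial_table.participant == 1]
        with pytest.raises(ValueError):
            within_subject_ci(solo)
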