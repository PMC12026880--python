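"""Unit and oracle tests for the regression models."""
import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from shiftuse import BEHAVIORS, models
from shiftuse.models import (
    CollinearityError,
    GridConfig,
    ModelSpec,
    compare_daytypes,
    compute_vif,
    fit,
    fit_model,
    prepare_design,
    run_analysis_grid,
    single_factor_effect,
    substitution_effect,
)
from shiftuse.synth import default_plan, generate_outcomes, generate_participant_table
from shiftuse.types import ValidationError

from conftest import make_regression_dataset


def iso_spec(**kw):
    base = dict(
        family="isotemporal", outcome="wc", day_type="workday",
        reference="SB", standardize=False,
    )
    base.update(kw)
    return ModelSpec(**base)


def sf_spec(**kw):
    base = dict(
        family="single_factor", outcome="wc", day_type="workday",
        focal="SB", standardize=False,
    )
    base.update(kw)
    return ModelSpec(**base)


class TestPrepareDesign:
    def test_isotemporal_columns_reference_dropped(self):
        rng = np.random.default_rng(0)
        df = make_regression_dataset(rng)
        y, X, _ = prepare_design(df, iso_spec())
        assert list(X.columns) == ["LPA", "MVPA", "sleep", "total", "age", "alcohol", "const"]

    def test_delta_scaling(self):
        rng = np.random.default_rng(0)
        df = make_regression_dataset(rng)
        df["workday_lpa"] = 600.0
        _, X, _ = prepare_design(df, iso_spec())
        assert np.allclose(X["LPA"], 20.0)

    def test_log10_outcome(self):
        rng = np.random.default_rng(0)
        df = make_regression_dataset(rng)
        df["tg"] = 100.0
        y, _, _ = prepare_design(df, iso_spec(outcome="tg"))
        assert np.allclose(y, 2.0)

    def test_listwise_deletion_counted(self):
        rng = np.random.default_rng(0)
        df = make_regression_dataset(rng)
        df.loc[:4, "wc"] = np.nan
        _, X, n_dropped = prepare_design(df, iso_spec())
        assert n_dropped == 5
        assert len(X) == len(df) - 5

    def test_too_few_rows(self):
        rng = np.random.default_rng(0)
        df = make_regression_dataset(rng, n=7)
        with pytest.raises(ValidationError, match="too few rows"):
            prepare_design(df, iso_spec())


class TestFitModel:
    def test_all_four_behaviors_plus_total_is_collinear(self):
        rng = np.random.default_rng(1)
        df = make_regression_dataset(rng)
        y, X, _ = prepare_design(df, iso_spec())
        X = X.copy()
        X["SB"] = df["workday_sb"] / 30.0   # re-add the reference
        with pytest.raises(CollinearityError, match="collinear"):
            fit_model(y, X, iso_spec())

    def test_noise_free_recovery(self):
        plan = default_plan()
        for om in plan.outcomes.values():
            om.noise_sd = 0.0
        rec = generate_participant_table(plan, 200, seed=3)
        f = fit(rec, iso_spec())
        est = substitution_effect(f, "LPA")
        # true contrast gamma_LPA - gamma_SB = -1.0, exact without noise
        assert est.beta == pytest.approx(-1.0, abs=1e-8)

    def test_vif_oracle(self):
        """Package VIFs equal 1/(1-R^2) from explicit statsmodels fits."""
        rng = np.random.default_rng(2)
        df = make_regression_dataset(rng)
        _, X, _ = prepare_design(df, iso_spec())
        vif = compute_vif(X)
        for col in X.columns:
            if col == "const":
                continue
            others = X.drop(columns=col)
            r2 = sm.OLS(X[col], others).fit().rsquared
            assert vif[col] == pytest.approx(1.0 / (1.0 - r2), abs=1e-10)

    def test_vif_at_least_one(self):
        rng = np.random.default_rng(3)
        df = make_regression_dataset(rng)
        f = fit(df, iso_spec())
        assert all(v >= 1.0 for v in f.vif.values())

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(4)
        df = make_regression_dataset(rng)
        f = fit(df, iso_spec(standardize=True))
        assert (f.params["ci_low"] <= f.params["estimate"]).all()
        assert (f.params["estimate"] <= f.params["ci_high"]).all()


class TestSubstitutionEffect:
    def test_self_substitution_error(self):
        rng = np.random.default_rng(5)
        f = fit(make_regression_dataset(rng), iso_spec())
        with pytest.raises(ValueError, match="self-substitution"):
            substitution_effect(f, "SB")

    def test_antisymmetry_under_reference_swap(self):
        rng = np.random.default_rng(6)
        df = make_regression_dataset(rng)
        f_a = fit(df, iso_spec(reference="SB"))
        f_b = fit(df, iso_spec(reference="LPA"))
        ab = substitution_effect(f_a, "LPA").beta
        ba = substitution_effect(f_b, "SB").beta
        assert ab == pytest.approx(-ba, abs=1e-8)

    def test_planted_negative_effect_detected(self):
        rec = generate_participant_table(default_plan(), 500, seed=9)
        f = fit(rec, iso_spec())
        est = substitution_effect(f, "LPA")
        assert est.beta < 0
        assert est.ci[1] < 0          # CI excludes 0 at n=500
        assert est.significant

    def test_significance_iff_ci_excludes_zero(self):
        rng = np.random.default_rng(7)
        df = make_regression_dataset(rng)
        f = fit(df, iso_spec(standardize=True))
        for to in ("LPA", "MVPA", "sleep"):
            est = substitution_effect(f, to)
            excludes = est.ci[0] > 0 or est.ci[1] < 0
            assert est.significant == excludes

    def test_delta_linearity(self):
        rng = np.random.default_rng(8)
        df = make_regression_dataset(rng)
        e30 = substitution_effect(fit(df, iso_spec(delta=30.0)), "LPA")
        e60 = substitution_effect(fit(df, iso_spec(delta=60.0)), "LPA")
        assert e60.beta == pytest.approx(2.0 * e30.beta, rel=1e-10)


class TestReparameterization:
    def test_isotemporal_equals_partition_contrasts(self):
        """beta_k = gamma_k - gamma_ref and beta_total = gamma_ref."""
        rng = np.random.default_rng(10)
        for _ in range(10):
            df = make_regression_dataset(rng)
            f = fit(df, iso_spec())
            # independent oracle: partition model on all four behaviours
            cols = [df[f"workday_{b.lower()}"] / 30.0 for b in BEHAVIORS]
            Xg = np.column_stack(cols + [df["age"], df["alcohol"], np.ones(len(df))])
            gamma = np.linalg.lstsq(Xg, df["wc"].to_numpy(float), rcond=None)[0]
            g = dict(zip(BEHAVIORS, gamma[:4]))
            for k in ("LPA", "MVPA", "sleep"):
                assert f.params.loc[k, "estimate"] == pytest.approx(
                    g[k] - g["SB"], abs=1e-8
                )
            assert f.params.loc["total", "estimate"] == pytest.approx(g["SB"], abs=1e-8)


class TestSingleFactor:
    def test_identity_with_reparameterized_regression(self):
        """beta1+beta2 equals the focal coefficient of Y ~ {B, T-B, covs}."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            df = make_regression_dataset(rng)
            f = fit(df, sf_spec())
            est = single_factor_effect(f)
            B = df["workday_sb"].to_numpy(float) / 30.0
            T = sum(df[f"workday_{b.lower()}"] for b in BEHAVIORS).to_numpy(float) / 30.0
            X2 = np.column_stack([B, T - B, df["age"], df["alcohol"], np.ones(len(df))])
            coef = np.linalg.lstsq(X2, df["wc"].to_numpy(float), rcond=None)[0]
            assert est.beta == pytest.approx(coef[0], abs=1e-8)

    def test_all_zero_response(self):
        rng = np.random.default_rng(12)
        df = make_regression_dataset(rng)
        df["wc"] = 0.0
        est = single_factor_effect(fit(df, sf_spec()))
        assert est.beta == pytest.approx(0.0, abs=1e-12)
        assert est.ci[0] == pytest.approx(-est.ci[1], abs=1e-12)

    def test_total_only_effect(self):
        """With gamma identical across behaviours the focal addition effect
        equals the shared per-delta total effect."""
        plan = default_plan()
        g = 0.8
        for om in plan.outcomes.values():
            om.noise_sd = 0.0
            om.gamma = {}
        plan.outcomes["wc"].gamma = {
            "workday": {b: g for b in BEHAVIORS}
        }
        rec = generate_participant_table(plan, 300, seed=13)
        est = single_factor_effect(fit(rec, sf_spec()))
        assert est.beta == pytest.approx(g, abs=1e-8)


class TestInvariances:
    def test_covariate_rescaling_leaves_raw_effect(self):
        rng = np.random.default_rng(14)
        df = make_regression_dataset(rng)
        base = substitution_effect(fit(df, iso_spec()), "LPA").beta
        df2 = df.copy()
        df2["age"] = 2.0 * df2["age"] + 5.0
        again = substitution_effect(fit(df2, iso_spec()), "LPA").beta
        assert again == pytest.approx(base, rel=1e-10)

    def test_outcome_rescaling_leaves_standardized_effect(self):
        rng = np.random.default_rng(15)
        df = make_regression_dataset(rng)
        base = substitution_effect(fit(df, iso_spec(standardize=True)), "LPA").beta
        df2 = df.copy()
        df2["wc"] = df2["wc"] * 3.7
        again = substitution_effect(fit(df2, iso_spec(standardize=True)), "LPA").beta
        assert again == pytest.approx(base, rel=1e-10)


class TestGrid:
    def test_sb_reference_grid_size(self, records66):
        cfg = GridConfig(references=("SB",), families=("isotemporal",))
        grid = run_analysis_grid(records66, cfg)
        assert len(grid) == 11 * 2 * 3

    def test_all_missing_outcome_reported_failed(self, records66):
        rec = records66.copy()
        rec["hdl"] = np.nan
        grid = run_analysis_grid(rec, GridConfig(references=("SB",)))
        hdl = grid[grid["outcome"] == "hdl"]
        rest = grid[grid["outcome"] != "hdl"]
        assert (hdl["status"] == "failed").all()
        assert (rest["status"] == "ok").all()

    def test_zero_variance_predictor_flagged_not_fatal(self, records66):
        rec = records66.copy()
        rec["workday_mvpa"] = 60.0
        grid = run_analysis_grid(
            rec, GridConfig(references=("SB",), families=("isotemporal",))
        )
        work = grid[grid["day_type"] == "workday"]
        leis = grid[grid["day_type"] == "leisure"]
        assert (work["status"] == "failed").all()
        assert (leis["status"] == "ok").all()

    def test_planted_pattern_at_n1000(self, plan):
        """The five calibrated direction cells are recovered; the other ten
        summary-table cells stay non-significant (fixed seed)."""
        from shiftuse.synth import PATTERN_OUTCOMES, PATTERN_PAIRS, PLANTED_PATTERN

        small_noise = default_plan()
        for om in small_noise.outcomes.values():
            om.noise_sd *= 0.25
        rec = generate_participant_table(small_noise, 1000, seed=2)
        cfg = GridConfig(
            outcomes=PATTERN_OUTCOMES, references=("SB", "sleep"),
            families=("isotemporal",),
        )
        grid = run_analysis_grid(rec, cfg)
        planted = {(d, f, t, o): s for d, f, t, o, s in PLANTED_PATTERN}
        for day_type, frm, to in PATTERN_PAIRS:
            for outcome in PATTERN_OUTCOMES:
                cell = grid[
                    (grid["day_type"] == day_type)
                    & (grid["from"] == frm)
                    & (grid["to"] == to)
                    & (grid["outcome"] == outcome)
                ].iloc[0]
                key = (day_type, frm, to, outcome)
                if key in planted:
                    assert cell["significant"], key
                    assert np.sign(cell["beta_std"]) == planted[key], key
                else:
                    assert not cell["significant"], key


class TestCompareDaytypes:
    def test_identical_vectors_degenerate(self):
        rng = np.random.default_rng(16)
        df = make_regression_dataset(rng, n=20)
        for b in BEHAVIORS:
            df[f"leisure_{b.lower()}"] = df[f"workday_{b.lower()}"]
        res = compare_daytypes(df)
        assert res["p"].isna().all()
        assert (res["note"] != "").all()

    def test_six_pair_manual_rank_oracle(self):
        # differences: +5 -3 +8 +1 -6 +2 -> |d| ranks 4 3 6 1 5 2
        workday = np.array([105.0, 97.0, 108.0, 101.0, 94.0, 102.0])
        leisure = np.array([100.0, 100.0, 100.0, 100.0, 100.0, 100.0])
        d = workday - leisure
        ranks = pd.Series(np.abs(d)).rank().to_numpy()
        t_plus = ranks[d > 0].sum()    # 4 + 6 + 1 + 2 = 13
        t_minus = ranks[d < 0].sum()   # 3 + 5 = 8
        df = pd.DataFrame({"workday_sb": workday, "leisure_sb": leisure})
        for b in BEHAVIORS:
            df[f"workday_{b.lower()}"] = workday
            df[f"leisure_{b.lower()}"] = leisure
        res = compare_daytypes(df).set_index("behavior")
        assert res.loc["SB", "statistic"] == min(t_plus, t_minus) == 8.0

    def test_fewer_than_two_pairs_error(self):
        df = pd.DataFrame({f"workday_{b.lower()}": [1.0] for b in BEHAVIORS}
                          | {f"leisure_{b.lower()}": [2.0] for b in BEHAVIORS})
        with pytest.raises(ValidationError, match="at least 2"):
            compare_daytypes(df)

    def test_power_for_sleep_and_lpa_differences(self, plan):
        """At the printed behaviour parameters and n=66, the sleep and LPA
        day-type differences are significant at p<0.001 in >=95% of
        replicates."""
        hits = {"sleep": 0, "LPA": 0}
        n_rep = 200
        for rep in range(n_rep):
            rec = generate_participant_table(plan, 66, seed=1000 + rep)
            res = compare_daytypes(rec.dropna()).set_index("behavior")
            for b in hits:
                if res.loc[b, "p"] < 0.001:
                    hits[b] += 1
        assert hits["sleep"] >= 0.95 * n_rep
        assert hits["LPA"] >= 0.95 * n_rep
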