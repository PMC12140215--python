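import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

import entrainkit as ek
from entrainkit.glm import (
    CANDIDATE_SETS,
    build_design,
    fit_candidates,
    fit_mixed_logit,
    surrogate_auc,
)


def make_trials(rng, n_participants=8, n_per=400, beta_fm=0.5, beta_tacs=0.0,
                sigma=0.4, depth_effect=0.0):
    """Trial table from a known mixed logistic generator."""
    rows = []
    for p in range(n_participants):
        b = rng.normal(0, sigma)
        fm = rng.uniform(-np.pi, np.pi, n_per)
        ta = rng.uniform(-np.pi, np.pi, n_per)
        cond = rng.choice([11.0, 39.0], n_per)
        depth = np.where(cond == 39.0, 0.5, -0.5)
        eta = b + beta_fm * np.cos(fm) + beta_tacs * np.cos(ta) + depth_effect * depth
        acc = (rng.random(n_per) < expit(eta)).astype(int)
        rows.append(pd.DataFrame({
            "participant_id": p, "session_id": 1, "condition": cond,
            "tacs_condition": "active", "fm_phase": fm, "tacs_phase": ta,
            "accuracy": acc,
        }))
    return pd.concat(rows, ignore_index=True)


class TestBuildDesign:
    def test_phase_zero_maps_to_sin0_cos1(self):
        t = pd.DataFrame({"fm_phase": [0.0], "tacs_phase": [np.pi], "condition": [11.0]})
        X = build_design(t, ("fm",))
        assert X["fm_sin"].iloc[0] == pytest.approx(0.0)
        assert X["fm_cos"].iloc[0] == pytest.approx(1.0)

    def test_invariant_to_adding_two_pi(self):
        rng = np.random.default_rng(0)
        t = pd.DataFrame({
            "fm_phase": rng.uniform(-np.pi, np.pi, 50),
            "tacs_phase": rng.uniform(-np.pi, np.pi, 50),
            "condition": 11.0,
        })
        t2 = t.assign(fm_phase=t.fm_phase + 2 * np.pi)
        terms = ("fm", "tacs")
        pd.testing.assert_frame_equal(build_design(t, terms), build_design(t2, terms))

    @pytest.mark.parametrize("terms, ncols", [
        (("fm",), 2), (("tacs",), 2), (("fm", "depth"), 3),
        (("fm", "tacs"), 4), (("fm", "tacs", "depth", "fm:depth", "tacs:depth"), 9),
    ])
    def test_column_counts(self, terms, ncols):
        rng = np.random.default_rng(1)
        t = pd.DataFrame({
            "fm_phase": rng.uniform(-np.pi, np.pi, 20),
            "tacs_phase": rng.uniform(-np.pi, np.pi, 20),
            "condition": rng.choice([11.0, 39.0], 20),
        })
        assert build_design(t, terms).shape[1] == ncols

    def test_nan_phase_rejected(self):
        t = pd.DataFrame({"fm_phase": [np.nan], "condition": [11.0]})
        with pytest.raises(ValueError):
            build_design(t, ("fm",))


class TestMixedLogit:
    def test_matches_lme4_reference(self, tmp_path):
        """ML estimates and AIC agree with R's lme4::glmer (adaptive GH)."""
        rng = np.random.default_rng(1)
        n, G = 400, 8
        g = np.repeat(np.arange(G), n // G)
        x = rng.standard_normal(n)
        b = rng.normal(0, 0.6, G)[g]
        y = (rng.random(n) < expit(0.2 + 0.7 * x + b)).astype(float)
        fit = fit_mixed_logit(x[:, None], y, g, columns=["x"])

        csv = tmp_path / "d.csv"
        pd.DataFrame({"y": y, "x": x, "g": g}).to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(
            "suppressMessages(library(lme4))\n"
            f"d <- read.csv('{csv}')\n"
            "m <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=20)\n"
            "cat(fixef(m), sqrt(unlist(VarCorr(m))), AIC(m), sep=',')\n"
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        icpt, slope, sigma, aic = map(float, out.stdout.strip().split(","))
        assert fit.coef[0] == pytest.approx(icpt, abs=0.01)
        assert fit.coef[1] == pytest.approx(slope, abs=0.01)
        assert fit.sigma == pytest.approx(sigma, abs=0.02)
        assert fit.aic == pytest.approx(aic, abs=0.05)

    def test_reduces_to_plain_logistic_without_group_effect(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(2)
        n = 2000
        x = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.3 + 0.8 * x)).astype(float)
        g = np.repeat(np.arange(10), n // 10)
        fit = fit_mixed_logit(x[:, None], y, g)
        ref = sm.Logit(y, sm.add_constant(x)).fit(disp=0)
        # sigma sits near the boundary (log-parameterized, so not exactly 0)
        assert fit.sigma < 0.25
        np.testing.assert_allclose(fit.coef, ref.params, atol=0.03)
        # the variance parameter costs up to 2 AIC, partially offset by the
        # likelihood gained from fitting group-level sampling noise
        assert ref.aic - 0.1 <= fit.aic <= ref.aic + 2.1

    def test_constant_outcome_rejected(self):
        with pytest.raises(ValueError):
            fit_mixed_logit(np.zeros((10, 1)), np.ones(10), np.zeros(10))


class TestFitCandidates:
    def test_recovers_fm_only_generator(self):
        rng = np.random.default_rng(3)
        table = make_trials(rng, beta_fm=0.6)
        comp = fit_candidates(table)
        assert comp.winner == "fm"
        assert comp.table.iloc[0]["aic"] <= comp.table["aic"].min() + 1e-9

    def test_aic_ordering_invariant_to_trial_order(self):
        rng = np.random.default_rng(4)
        table = make_trials(rng, n_participants=4, n_per=200, beta_fm=0.5)
        comp1 = fit_candidates(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        comp2 = fit_candidates(shuffled)
        assert list(comp1.table["id"]) == list(comp2.table["id"])
        np.testing.assert_allclose(
            comp1.table["aic"].to_numpy(), comp2.table["aic"].to_numpy(), atol=1e-4
        )

    def test_irrelevant_predictors_cost_aic(self):
        """Adding null predictors increases AIC in expectation (2/parameter)."""
        rng = np.random.default_rng(5)
        deltas = []
        for _ in range(20):
            table = make_trials(rng, n_participants=4, n_per=250, beta_fm=0.5)
            comp = fit_candidates(table, {"fm": ("fm",), "fm+tacs": ("fm", "tacs")})
            aics = comp.table.set_index("id")["aic"]
            deltas.append(aics["fm+tacs"] - aics["fm"])
        assert np.mean(deltas) > 0


class TestSurrogateAuc:
    def test_null_refits_center_at_half(self):
        # small table: the in-sample bias of conditional predictions leaves
        # a slight excess over 0.5 that shrinks with trials per participant
        rng = np.random.default_rng(6)
        table = make_trials(rng, n_participants=4, n_per=300, beta_fm=0.6, sigma=0.0)
        obs, null, p = surrogate_auc(table, ("fm",), n_perm=60, seed=7)
        assert obs > 0.55
        assert null.mean() == pytest.approx(0.5, abs=0.035)
        assert p <= 1.0 / 60

    def test_separable_data_saturates(self):
        rng = np.random.default_rng(7)
        n = 400
        fm = rng.uniform(-np.pi, np.pi, n)
        table = pd.DataFrame({
            "participant_id": 0, "condition": 11.0, "fm_phase": fm,
            "tacs_phase": 0.0, "accuracy": (np.cos(fm) > 0).astype(int),
        })
        obs, null, p = surrogate_auc(table, ("fm",), n_perm=30, seed=8)
        assert obs > 0.99
        assert p == 0.0
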