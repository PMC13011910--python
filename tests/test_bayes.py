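"""Inference stage: generalized-inverse contrasts, the Gibbs sampler against
conjugate ground truth, Savage-Dickey Bayes factors against the closed-form
normal-normal oracle, evidence labels, and the three-run stability
protocol."""

import numpy as np
import pandas as pd
import pytest

from alphadrift import (BF_CAP, ModelSpec, bayes_factor,
                        build_contrast_matrix, classify_evidence,
                        condition_scheme, fit_multilevel,
                        run_stability_protocol, savage_dickey,
                        source_scheme)
from alphadrift.bayes import build_design, _prepare


# ---------------------------------------------------------------------------
# contrasts
# ---------------------------------------------------------------------------

class TestContrasts:
    def test_two_level_scheme_gives_half_coding(self):
        s = build_contrast_matrix([[0.5, 0.5], [-1.0, 1.0]])
        np.testing.assert_allclose(s.contrast_matrix[:, 1], [-0.5, 0.5],
                                   atol=1e-12)

    def test_round_trip_identity_for_shipped_schemes(self):
        for s in (condition_scheme(), source_scheme()):
            hc = s.hypothesis_matrix @ s.contrast_matrix
            np.testing.assert_allclose(hc,
                                       np.eye(len(s.hypothesis_matrix)),
                                       atol=1e-12)

    def test_identity_hypotheses_give_identity_contrasts(self):
        s = build_contrast_matrix(np.eye(3))
        np.testing.assert_allclose(s.contrast_matrix, np.eye(3),
                                   atol=1e-12)

    def test_rank_deficient_rejected(self):
        with pytest.raises(ValueError):
            build_contrast_matrix([[1.0, 1.0], [2.0, 2.0]])

    def test_hypothesis_rows_sum_to_zero(self):
        for s in (condition_scheme(), source_scheme()):
            sums = s.hypothesis_matrix[1:].sum(axis=1)
            np.testing.assert_allclose(sums, 0.0, atol=1e-12)


# ---------------------------------------------------------------------------
# design matrices on a synthetic model-generated table
# ---------------------------------------------------------------------------

def model_table(rng, n_subjects=8, n_trials=16, b0=0.0, b1=0.1,
                sd_int=0.3, sd_slope=0.05, sigma=0.5, source="online",
                band="alpha", channel="Pz"):
    """Band-power-like table generated directly from the multilevel model."""
    rows = []
    conds = ("Control", "1Hz", "5Hz", "10Hz")
    per_cond = max(n_trials // 4, 1)
    for s in range(n_subjects):
        a_i = b0 + sd_int * rng.standard_normal()
        b_i = b1 + sd_slope * rng.standard_normal()
        for t in range(1, n_trials + 1):
            y = a_i + b_i * (t - 1) + sigma * rng.standard_normal()
            rows.append({"source": source, "subject": s,
                         "condition": conds[(t - 1) // per_cond % 4],
                         "trial": t,
                         "trial_in_condition": (t - 1) % per_cond + 1,
                         "channel": channel, "band": band,
                         "power_db": y, "power_z": y})
    return pd.DataFrame(rows)


class TestDesign:
    def test_eq2_design_columns(self, rng):
        table = model_table(rng, n_subjects=3, n_trials=8)
        spec = ModelSpec(equation=2)
        sub, groups = _prepare(table, spec)
        X, Z, names, znames = build_design(sub, spec)
        assert names == ["Intercept", "Trial"]     # single experiment
        np.testing.assert_allclose(X[:, 0], 1.0)
        assert X[:, 1].max() == 7.0 and X[:, 1].min() == 0.0
        np.testing.assert_allclose(X, Z)

    def test_eq1_design_uses_condition_contrasts(self, rng):
        a = model_table(rng, n_subjects=3, n_trials=16, source="online")
        b = model_table(rng, n_subjects=3, n_trials=16, source="offline")
        table = pd.concat([a, b], ignore_index=True)
        spec = ModelSpec(equation=1)
        sub, _ = _prepare(table, spec)
        X, Z, names, znames = build_design(sub, spec)
        assert len(names) == 16 and X.shape[1] == 16
        assert Z.shape[1] == 8
        cs = condition_scheme()
        i = names.index("Cond[upd_vs_ctrl]")
        for cond in ("Control", "10Hz"):
            rows = (sub["condition"] == cond).to_numpy()
            np.testing.assert_allclose(X[rows, i],
                                       cs.coding(cond)[0], atol=1e-12)
        j = names.index("Source[on_vs_off]")
        assert set(np.round(X[:, j], 3)) == {0.5, -0.5}


# ---------------------------------------------------------------------------
# sampler correctness
# ---------------------------------------------------------------------------

class TestSampler:
    def test_posterior_matches_conjugate_regression(self, rng):
        """With negligible subject variation and a known strong slope the
        posterior concentrates on the ridge (N(0,1)-prior) solution."""
        table = model_table(rng, n_subjects=10, n_trials=16, b1=0.2,
                            sd_int=0.0, sd_slope=0.0, sigma=0.4)
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=300, n_draws=600)
        fit = fit_multilevel(table, spec, seed=1)
        m = fit.beta_mean("Trial")
        lo, hi = fit.cri_95("Trial")
        assert lo <= 0.2 <= hi
        assert m == pytest.approx(0.2, abs=0.02)

    def test_single_subject_rejected(self, rng):
        table = model_table(rng, n_subjects=1)
        with pytest.raises(ValueError):
            fit_multilevel(table, ModelSpec(equation=2), seed=0)

    def test_simulation_based_coverage(self, rng):
        """True slope inside the 95% CrI in nearly all replicates."""
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=300, n_draws=500)
        hits = 0
        n_rep = 15
        for r in range(n_rep):
            table = model_table(np.random.default_rng(100 + r),
                                b1=0.08, sd_slope=0.04)
            fit = fit_multilevel(table, spec, seed=r)
            lo, hi = fit.cri_95("Trial")
            hits += lo <= 0.08 <= hi
        assert hits >= n_rep - 3

    def test_null_slope_covered(self, rng):
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=300, n_draws=500)
        hits = 0
        for r in range(10):
            table = model_table(np.random.default_rng(200 + r), b1=0.0,
                                sd_slope=0.03)
            fit = fit_multilevel(table, spec, seed=r)
            lo, hi = fit.cri_95("Trial")
            hits += lo <= 0.0 <= hi
        assert hits >= 8


# ---------------------------------------------------------------------------
# Savage-Dickey vs conjugate closed form
# ---------------------------------------------------------------------------

def conjugate_bf10(n, ybar):
    """Closed-form BF10 for the known-variance normal mean with prior
    N(0,1): posterior N(n*ybar/(n+1), 1/(n+1)); Savage-Dickey identity
    gives BF10 = (n+1)^(-1/2) * exp(mu^2 (n+1) / 2)."""
    mu = n * ybar / (n + 1)
    return np.exp(mu ** 2 * (n + 1) / 2) / np.sqrt(n + 1)


class TestSavageDickey:
    def test_matches_conjugate_closed_form_on_grid(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for n in (4, 8, 16, 32, 50):
            for ybar in (0.0, 0.05, 0.1, 0.2):
                mu = n * ybar / (n + 1)
                sd = 1.0 / np.sqrt(n + 1)
                draws = rng.normal(mu, sd, size=100000)
                bf, capped = savage_dickey(draws)
                assert not capped
                rel = abs(bf - conjugate_bf10(n, ybar)) / conjugate_bf10(
                    n, ybar)
                worst = max(worst, rel)
        assert worst < 0.05

    def test_far_from_null_hits_cap(self):
        rng = np.random.default_rng(8)
        bf, capped = savage_dickey(rng.normal(1.0, 0.05, size=5000))
        assert capped and bf == BF_CAP

    def test_prior_equals_posterior_gives_unit_bf(self):
        rng = np.random.default_rng(9)
        bf, capped = savage_dickey(rng.normal(0.0, 1.0, size=50000))
        assert not capped
        assert bf == pytest.approx(1.0, abs=0.1)

    def test_tight_null_posterior_supports_null(self):
        rng = np.random.default_rng(10)
        bf, _ = savage_dickey(rng.normal(0.0, 0.05, size=20000))
        assert bf < 1 / 3


class TestEvidenceLabels:
    @pytest.mark.parametrize("bf,label", [
        (5.0, "evidence_for_effect"), (100.0, "evidence_for_effect"),
        (0.2, "evidence_for_null"), (0.01, "evidence_for_null"),
        (1.0, "insensitive"), (3.0, "insensitive"),
        (1 / 3, "insensitive")])
    def test_thresholds(self, bf, label):
        assert classify_evidence(bf) == label

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(0.0)


class TestDirectionalBF:
    def test_one_sided_doubles_when_all_mass_positive(self, rng):
        table = model_table(rng, n_subjects=8, n_trials=16, b1=0.05,
                            sd_slope=0.01, sigma=0.3)
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=300, n_draws=600)
        fit = fit_multilevel(table, spec, seed=3)
        res = bayes_factor(fit, "Trial")
        p_pos = float(np.mean(fit.draws_for("Trial") > 0))
        if res.capped:
            assert res.bf10_plus == BF_CAP
        elif p_pos > 0.5:
            assert res.bf10_plus >= res.bf10
        if p_pos > 0.99 and not res.capped:
            assert res.bf10_plus == pytest.approx(2 * res.bf10, rel=0.01)


class TestStabilityProtocol:
    @pytest.fixture(scope="class")
    def table(self):
        return model_table(np.random.default_rng(5), n_subjects=6,
                           n_trials=12, b1=0.06, sd_slope=0.02)

    def test_three_runs_pooled(self, table):
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=250, n_draws=400)
        res, summary = run_stability_protocol(table, spec, "Trial",
                                              seeds=(1, 2, 3))
        assert res.mean_bf10 == pytest.approx(np.mean(res.runs))
        lo, hi = summary["cri_95"]
        for rlo, rhi in summary["per_run_cri"]:
            assert lo <= rlo and hi >= rhi
        assert res.label == classify_evidence(res.mean_bf10)

    def test_runs_agree_on_informative_data(self, table):
        spec = ModelSpec(equation=2, n_chains=2, n_warmup=250, n_draws=400)
        _, summary = run_stability_protocol(table, spec, "Trial",
                                            seeds=(4, 5, 6))
        betas = summary["per_run_beta"]
        assert np.ptp(betas) < 0.01

    def test_duplicate_seeds_rejected(self, table):
        spec = ModelSpec(equation=2)
        with pytest.raises(ValueError):
            run_stability_protocol(table, spec, "Trial", seeds=(1, 1, 2))
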