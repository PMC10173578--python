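"""Multivariable IVW and the mediation decomposition."""

from __future__ import annotations

import math

import numpy as np
import pytest

from netmr.mvmr import (
    MediationError,
    MVInstrumentSet,
    build_mv_set,
    mediation_difference,
    mediation_product,
    mvmr_ivw,
    network_decomposition,
    pm_bootstrap,
)
from netmr.simulate import DagSpec, simulate_sumstats
from netmr.uvmr import EstimationError, MRResult, ivw

from conftest import make_instrument_set


def _mvset(beta_exp, se_exp, beta_out, se_out, exposures=None):
    beta_exp = np.atleast_2d(beta_exp)
    exposures = exposures or [f"x{j}" for j in range(beta_exp.shape[1])]
    return MVInstrumentSet(
        exposure_ids=exposures, outcome_id="y",
        snp_ids=[f"rs{i}" for i in range(beta_exp.shape[0])],
        beta_exp=beta_exp, se_exp=se_exp, beta_out=beta_out, se_out=se_out,
    )


def _mr(beta, se, exposure="x0", outcome="y"):
    return MRResult("IVW", beta, se, beta - 1.96 * se, beta + 1.96 * se,
                    0.01, 10, exposure_id=exposure, outcome_id=outcome)


class TestMvmrIvw:
    def test_zero_second_column_reduces_to_univariable(self):
        rng = np.random.default_rng(1)
        bx = rng.uniform(0.1, 0.3, 5)
        so = np.full(5, 0.01)
        by = 0.25 * bx + rng.normal(0, so)
        X = np.column_stack([bx, np.zeros(5)])
        res = mvmr_ivw(_mvset(X, np.full((5, 2), 0.01), by, so))
        uni = ivw(make_instrument_set(bx, by, so))
        assert res.coefficient("x0").beta == pytest.approx(uni.beta, abs=1e-12)
        assert res.coefficient("x0").se == pytest.approx(uni.se, abs=1e-12)
        assert math.isnan(res.coefficient("x1").beta)

    def test_exact_two_exposure_system(self):
        X = np.array([[0.1, 0.0], [0.0, 0.2], [0.1, 0.1], [0.2, -0.1]])
        truth = np.array([0.3, -0.1])
        y = X @ truth
        res = mvmr_ivw(_mvset(X, np.full((4, 2), 0.01), y, np.full(4, 0.01)))
        assert res.coefficient("x0").beta == pytest.approx(0.3, abs=1e-12)
        assert res.coefficient("x1").beta == pytest.approx(-0.1, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(-0.3, 0.3, (6, 2))
        so = rng.uniform(0.01, 0.03, 6)
        y = X @ np.array([0.4, -0.2]) + rng.normal(0, so)
        res = mvmr_ivw(_mvset(X, np.full((6, 2), 0.01), y, so))
        # hand-computed weighted normal equations
        W = np.diag(so ** -2.0)
        A = X.T @ W @ X
        coef = np.linalg.solve(A, X.T @ W @ y)
        resid = y - X @ coef
        q = resid @ W @ resid
        scale = max(1.0, math.sqrt(q / (6 - 2)))
        cov = np.linalg.inv(A) * scale ** 2
        assert res.coefficient("x0").beta == pytest.approx(coef[0], abs=1e-10)
        assert res.coefficient("x1").beta == pytest.approx(coef[1], abs=1e-10)
        assert res.coefficient("x0").se == pytest.approx(math.sqrt(cov[0, 0]), abs=1e-10)

    def test_rank_deficiency_and_size_errors(self):
        X = np.array([[0.1, 0.2], [0.2, 0.4], [0.3, 0.6], [0.15, 0.3]])
        with pytest.raises(EstimationError, match="rank deficient"):
            mvmr_ivw(_mvset(X, np.full((4, 2), 0.01),
                            np.array([1, 2, 3, 4.0]), np.full(4, 0.1)))
        with pytest.raises(EstimationError, match="more SNPs than exposures"):
            mvmr_ivw(_mvset(np.array([[0.1, 0.0], [0.0, 0.2]]),
                            np.full((2, 2), 0.01),
                            np.array([0.1, 0.2]), np.full(2, 0.1)))


class TestMediationDifference:
    def test_reproduces_published_hypertension_pm(self):
        total = _mr(math.log(0.711), 0.05)
        direct = _mr(math.log(0.836), 0.08)
        res = mediation_difference(total, direct, ["hypertension"])
        assert res.pm == pytest.approx(47.35, abs=0.5)
        assert res.indirect_beta == pytest.approx(total.beta - direct.beta)

    def test_no_mediation_and_full_mediation(self):
        total = _mr(-0.3, 0.05)
        assert mediation_difference(total, _mr(-0.3, 0.05)).pm == pytest.approx(0.0)
        assert mediation_difference(total, _mr(0.0, 0.05)).pm == pytest.approx(100.0)

    def test_direct_plus_indirect_is_total_exactly(self):
        res = mediation_difference(_mr(-0.34, 0.05), _mr(-0.18, 0.07))
        assert res.direct_beta + res.indirect_beta == res.total_beta

    def test_zero_total_is_an_error(self):
        with pytest.raises(MediationError, match="PM undefined"):
            mediation_difference(_mr(0.0, 0.05), _mr(-0.1, 0.05))

    def test_mismatched_ids_rejected(self):
        with pytest.raises(MediationError, match="outcome ids differ"):
            mediation_difference(_mr(-0.3, 0.05, outcome="y"),
                                 _mr(-0.2, 0.05, outcome="z"))

    def test_pm_outside_unit_interval_flagged(self):
        res = mediation_difference(_mr(-0.3, 0.05), _mr(-0.5, 0.05))
        assert res.pm < 0
        assert "pm_outside_0_100" in res.flags


class TestMediationProduct:
    def test_broken_path_gives_zero(self):
        res = mediation_product(_mr(0.0, 0.1), _mr(0.2, 0.05), total=_mr(-0.3, 0.05))
        assert res.indirect_beta == 0.0

    def test_delta_method_se_oracle(self):
        a, b = _mr(-0.46, 0.1), _mr(0.2, 0.05)
        res = mediation_product(a, b, total=_mr(-0.3, 0.05))
        assert res.indirect_beta == pytest.approx(-0.092)
        assert res.indirect_se == pytest.approx(
            math.sqrt(0.46 ** 2 * 0.05 ** 2 + 0.2 ** 2 * 0.1 ** 2))

    def test_product_estimates_recover_a_times_b(self):
        """Summary-level noise: mean of a_hat * b_hat across 500
        replicates is within 3 Monte-Carlo SEs of the true product."""
        rng = np.random.default_rng(15)
        a_true, b_true = -0.4, 0.25
        total = _mr(a_true * b_true - 0.2, 0.01)
        ests = np.array([
            mediation_product(
                _mr(rng.normal(a_true, 0.05), 0.05),
                _mr(rng.normal(b_true, 0.04), 0.04),
                total,
            ).indirect_beta
            for _ in range(500)
        ])
        mcse = ests.std(ddof=1) / math.sqrt(ests.size)
        assert abs(ests.mean() - a_true * b_true) < 3 * mcse


class TestNetworkDecomposition:
    def test_combined_row_matches_published_arithmetic(self):
        total = _mr(math.log(0.711), 0.05)
        singles = {
            "hypertension": _mr(math.log(0.836), 0.08),
            "bmi": _mr(math.log(0.774), 0.08),
        }
        combined = _mr(math.log(0.901), 0.1)
        dec = network_decomposition(total, singles, combined)
        assert dec.combined.pm == pytest.approx(69.32, abs=0.5)
        assert len(dec.singles) == 2
        frame = dec.to_frame()
        assert list(frame["mediators"]) == ["hypertension", "bmi", "hypertension+bmi"]

    def test_null_network(self):
        total = _mr(-0.3, 0.05)
        dec = network_decomposition(
            total, {"m1": _mr(-0.3, 0.05), "m2": _mr(-0.3, 0.05)}, _mr(-0.3, 0.05))
        assert all(s.pm == pytest.approx(0.0) for s in dec.singles)
        assert dec.combined.pm == pytest.approx(0.0)

    def test_independent_mediators_make_indirects_additive(self):
        """With mutually independent mediators the combined indirect
        effect should match the sum of single indirects up to noise."""
        combined_minus_sum = []
        for seed in range(15):
            spec = DagSpec(seed=900 + seed, palindromic_rate=0.0, allele_flip_rate=0.0)
            study = simulate_sumstats(spec)
            from netmr.pipeline import analyze_network

            rep = analyze_network(study.tables, "education",
                                  list(spec.mediator_names), "stroke",
                                  seed=1, sensitivity=False)
            dec = rep.decomposition
            combined_minus_sum.append(
                dec.combined.indirect_beta - sum(s.indirect_beta for s in dec.singles))
        arr = np.array(combined_minus_sum)
        assert abs(arr.mean()) < 3 * arr.std(ddof=1) / math.sqrt(arr.size) + 0.01


class TestBuildMvSetAndBootstrap:
    def test_joint_set_from_simulated_study(self):
        spec = DagSpec(seed=21, n_instruments_exposure=20,
                       n_instruments_mediator=(20, 20, 20, 20))
        study = simulate_sumstats(spec)
        mvset = build_mv_set(
            [study.exposure, study.mediator("bmi")], study.outcome)
        assert mvset.exposure_ids == ["education", "bmi"]
        assert mvset.n_snp > 20  # pools both traits' instruments
        res = mvmr_ivw(mvset)
        assert res.coefficient("bmi").beta == pytest.approx(spec.b[1], abs=0.15)

    def test_pm_bootstrap_returns_finite_uncertainty(self):
        spec = DagSpec(seed=31, n_instruments_exposure=25,
                       n_instruments_mediator=(25, 25, 25, 25))
        study = simulate_sumstats(spec)
        from netmr.instruments import select_instruments
        from netmr.sumstats import harmonize

        total_set = select_instruments(harmonize(study.exposure, study.outcome))
        mvset = build_mv_set([study.exposure, study.mediator("hypertension")],
                             study.outcome)
        boot = pm_bootstrap(total_set, mvset, seed=3, n_boot=200)
        assert boot["pm_se"] > 0
        assert boot["pm_ci_low"] < boot["pm_ci_high"]
        assert boot["n_failed"] < 20
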