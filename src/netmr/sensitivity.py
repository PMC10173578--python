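"""Sensitivity diagnostics for a fitted instrument set.

Covers heterogeneity (Cochran's Q in the IVW and Egger frameworks),
influence (leave-one-out IVW refits), outlier detection and correction
(a residual-sum-of-squares global test with per-SNP outlier and
distortion tests calibrated by parametric simulation, in the MR-PRESSO
style), directionality (the Steiger variance-explained comparison), and
analytic power for a binary outcome.

Heterogeneity is reported, never used to auto-drop SNPs; outliers are
removed only through the outlier test itself or explicit exclusion
lists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .uvmr import (
    EstimationError,
    MRResult,
    _egger_fit,
    _ivw_point,
    ivw,
)


@dataclass(frozen=True)
class QResult:
    """Cochran's Q heterogeneity statistic."""

    Q: float
    df: int
    pval: float
    framework: str  # "IVW" | "Egger"


def cochran_q(instruments, framework: str = "IVW") -> QResult:
    """Heterogeneity of per-SNP estimates about the fitted model.

    Q = sum_j w_j (beta_out_j - fitted_j)^2 with w_j = se_out_j^-2;
    fitted values come from the zero-intercept (IVW, df = n-1) or
    free-intercept (Egger, df = n-2) weighted fit, and the p-value from
    the chi-square reference.
    """
    bx, sx, by, so = instruments.arrays()
    n = bx.size
    if framework == "IVW":
        if n < 2:
            raise EstimationError("Q (IVW) needs at least 2 SNPs")
        _, _, q = _ivw_point(bx, by, so)
        df = n - 1
    elif framework == "Egger":
        if n < 3:
            raise EstimationError("Q (Egger) needs at least 3 SNPs")
        *_, q = _egger_fit(bx, by, so)
        df = n - 2
    else:
        raise EstimationError(f"unknown framework {framework!r}")
    return QResult(Q=q, df=df, pval=float(stats.chi2.sf(q, df)), framework=framework)


@dataclass(frozen=True)
class LeaveOneOutEntry:
    snp_id: str
    result: MRResult
    flagged: bool
    sign_flip: bool


def leave_one_out(
    instruments, model: str = "multiplicative_random", binary_outcome: bool = True
) -> list[LeaveOneOutEntry]:
    """One IVW refit per omitted SNP.

    An omission is flagged when its CI excludes the full-set point
    estimate or the effect changes sign — the influence pattern a single
    pleiotropic SNP produces.
    """
    if instruments.n_snp < 3:
        raise EstimationError("leave-one-out needs at least 3 SNPs")
    full = ivw(instruments, model=model, binary_outcome=binary_outcome)
    out = []
    for pair in instruments.pairs:
        sub = instruments.without([pair.snp_id])
        res = ivw(sub, model=model, binary_outcome=binary_outcome)
        sign_flip = full.beta != 0 and res.beta != 0 and (res.beta > 0) != (full.beta > 0)
        outside = not (res.ci_low <= full.beta <= res.ci_high)
        out.append(LeaveOneOutEntry(pair.snp_id, res, outside or sign_flip, sign_flip))
    return out


@dataclass
class PressoResult:
    """Global, per-SNP outlier, and distortion tests.

    Outliers are reported only when the global test is significant; the
    corrected estimate refits IVW on the non-outlier subset.
    """

    global_rss_obs: float
    global_pval: float
    outlier_snps: list[str]
    outlier_pvals: dict[str, float]
    distortion_pval: float | None
    beta_raw: MRResult
    beta_corrected: MRResult
    n_sim: int
    seed: int


def presso(
    instruments,
    seed: int,
    n_sim: int = 1000,
    alpha_outlier: float = 0.05,
    alpha_global: float = 0.05,
    model: str = "multiplicative_random",
    binary_outcome: bool = True,
) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with outlier correction.

    The observed global statistic is sum_j w_j (beta_out_j -
    theta_hat(-j) beta_exp_j)^2 with theta_hat(-j) the leave-one-out
    fixed-effect IVW estimate.  Its null distribution is built by
    parametric simulation: betas are redrawn from normals centred at
    (beta_exp_j, theta_hat(-j) beta_exp_j) with the observed SEs.
    Per-SNP outlier p-values are the simulated tail shares of each SNP's
    weighted residual, Bonferroni-adjusted across SNPs.  The distortion
    test compares the raw and outlier-corrected estimates against
    refits with random non-outlier subsets of the same size removed.
    """
    bx, sx, by, so = instruments.arrays()
    n = bx.size
    if n < 4:
        raise EstimationError("the outlier test needs at least 4 SNPs")
    if n_sim < 100:
        raise EstimationError("n_sim must be at least 100")
    w = so ** -2.0
    wxy = w * bx * by
    wxx = w * bx * bx
    s1, s2 = wxy.sum(), wxx.sum()
    theta_loo = (s1 - wxy) / (s2 - wxx)
    res_obs = w * (by - theta_loo * bx) ** 2
    rss_obs = float(res_obs.sum())

    rng = np.random.default_rng(seed)
    e_sim = rng.normal(bx, sx, size=(n_sim, n))
    o_sim = rng.normal(theta_loo * bx, so, size=(n_sim, n))
    wxy_s = w * e_sim * o_sim
    wxx_s = w * e_sim * e_sim
    th_loo_s = (wxy_s.sum(axis=1, keepdims=True) - wxy_s) / (
        wxx_s.sum(axis=1, keepdims=True) - wxx_s
    )
    res_s = w * (o_sim - th_loo_s * e_sim) ** 2
    rss_s = res_s.sum(axis=1)
    global_pval = float((1 + np.sum(rss_s >= rss_obs)) / (1 + n_sim))

    p_snp = (1 + np.sum(res_s >= res_obs, axis=0)) / (1 + n_sim)
    p_adj = np.minimum(1.0, p_snp * n)

    snp_ids = [p.snp_id for p in instruments.pairs]
    outlier_pvals = dict(zip(snp_ids, map(float, p_adj)))
    outliers: list[str] = []
    if global_pval < alpha_global:
        outliers = [s for s, p in zip(snp_ids, p_adj) if p < alpha_outlier]

    beta_raw = ivw(instruments, model=model, binary_outcome=binary_outcome)
    distortion_pval: float | None = None
    if outliers and len(outliers) < n:
        corrected_set = instruments.without(outliers)
        beta_corrected = ivw(corrected_set, model=model, binary_outcome=binary_outcome)
        # Distortion null: remove random same-size draws (with
        # replacement) of non-outlier SNPs instead of the outliers.
        non_out = np.array([i for i, s in enumerate(snp_ids) if s not in outliers])
        k = len(outliers)
        if beta_corrected.beta != 0:
            d_obs = 100.0 * (beta_corrected.beta - beta_raw.beta) / abs(beta_corrected.beta)
            d_null = np.empty(n_sim)
            draws = rng.choice(non_out, size=(n_sim, k), replace=True)
            for i in range(n_sim):
                idx = np.unique(draws[i])
                th = (s1 - wxy[idx].sum()) / (s2 - wxx[idx].sum())
                d_null[i] = 100.0 * (th - beta_raw.beta) / abs(th) if th != 0 else np.inf
            distortion_pval = float(
                (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (1 + n_sim)
            )
    else:
        beta_corrected = beta_raw
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_snps=outliers,
        outlier_pvals=outlier_pvals,
        distortion_pval=distortion_pval,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
        n_sim=n_sim,
        seed=seed,
    )


@dataclass(frozen=True)
class SampleInfo:
    """Per-trait GWAS sample size, with the effective-n variant for
    binary traits: n_eff = 4 / (1/n_case + 1/n_control)."""

    n: float
    binary: bool = False
    n_case: float | None = None
    n_control: float | None = None

    @property
    def n_eff(self) -> float:
        if not self.binary:
            return self.n
        if not self.n_case or not self.n_control:
            raise EstimationError("binary trait needs case and control counts")
        return 4.0 / (1.0 / self.n_case + 1.0 / self.n_control)


@dataclass(frozen=True)
class SteigerResult:
    """Directionality check: instruments should explain more variance in
    the exposure than in the outcome."""

    r2_exposure: float
    r2_outcome: float
    direction_correct: bool
    pval: float


def steiger(instruments, exposure: SampleInfo, outcome: SampleInfo) -> SteigerResult:
    """Steiger directionality test.

    Per-SNP variance explained uses the squared-correlation
    approximation r^2 = z^2 / (z^2 + n) with z = beta/se and n the
    (effective) sample size; summed r^2 on the two sides are compared
    and tested via the normal test on the difference of
    Fisher-transformed correlations across independent samples.
    """
    if exposure.n_eff <= 3 or outcome.n_eff <= 3:
        raise EstimationError("sample sizes must exceed 3")
    bx, sx, by, so = instruments.arrays()
    zx = bx / sx
    zy = by / so
    r2x = float(np.sum(zx ** 2 / (zx ** 2 + exposure.n_eff)))
    r2y = float(np.sum(zy ** 2 / (zy ** 2 + outcome.n_eff)))
    r2x = min(r2x, 1.0 - 1e-12)
    r2y = min(r2y, 1.0 - 1e-12)
    rx, ry = math.sqrt(r2x), math.sqrt(r2y)
    denom = math.sqrt(1.0 / (exposure.n_eff - 3) + 1.0 / (outcome.n_eff - 3))
    z = (math.atanh(rx) - math.atanh(ry)) / denom
    pval = float(2 * stats.norm.sf(abs(z)))
    return SteigerResult(
        r2_exposure=r2x, r2_outcome=r2y,
        direction_correct=r2x > r2y, pval=pval,
    )


@dataclass(frozen=True)
class PowerInput:
    """Inputs to the analytic binary-outcome power calculation."""

    n_outcome: float
    case_fraction: float
    r2_instruments: float
    true_or: float
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.case_fraction < 1):
            raise EstimationError("case_fraction must be in (0,1)")
        if not (0 < self.r2_instruments < 1):
            raise EstimationError("r2_instruments must be in (0,1)")
        if not (0 < self.alpha < 1):
            raise EstimationError("alpha must be in (0,1)")
        if not (self.true_or > 0):
            raise EstimationError("true_or must be positive")
        if not (self.n_outcome > 0):
            raise EstimationError("n_outcome must be positive")


def power_binary(inp: PowerInput) -> float:
    """Two-sided analytic power of the IVW test for a binary outcome.

    Under the linearized logistic model the IVW estimate of the
    log-odds effect has variance approximately
    1 / (n K (1-K) r^2), so the noncentrality is
    sqrt(n K (1-K) r^2) * |ln OR| and the two-sided power at level
    alpha follows from the normal reference.  At OR = 1 this returns
    alpha exactly and it increases to 1 with n, r^2, or |ln OR|.
    """
    s = math.sqrt(inp.n_outcome * inp.case_fraction * (1 - inp.case_fraction)
                  * inp.r2_instruments) * abs(math.log(inp.true_or))
    z = stats.norm.ppf(1 - inp.alpha / 2)
    return float(stats.norm.cdf(-z + s) + stats.norm.cdf(-z - s))
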