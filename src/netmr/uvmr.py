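"""Univariable two-sample MR estimators.

All estimators operate on harmonized per-SNP effect pairs
(beta_exp, se_exp, beta_out, se_out) and return the causal effect on the
outcome scale per unit of exposure — the log-odds scale when the outcome
is binary, with the odds ratio attached as a presentation transform.

Estimators
----------
wald_ratio
    Single-SNP ratio estimate with first-order (delta-method) SE.
ivw
    Inverse-variance-weighted estimate: zero-intercept weighted
    regression of outcome on exposure betas with weights se_out^-2.
    The default multiplicative random-effects model inflates the fixed
    SE by max(1, sqrt(Q / (n-1))).
egger
    Weighted regression with a free intercept after orienting all
    exposure betas non-negative; a nonzero intercept indicates
    directional pleiotropy.  Inference uses t with n-2 df and the
    classical estimated-scale SEs, so the intercept test is exactly
    calibrated under the null.
max_likelihood
    Profile maximum likelihood under bivariate normal measurement error
    with known SEs on both sides.
raps
    Robust adjusted profile score: solves the psi-weighted profile-score
    equation, optionally with Huber robustness and an overdispersion
    variance component tau^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .sumstats import HarmonizedPair


class EstimationError(ValueError):
    """An estimator's preconditions are not met."""


class ConvergenceError(RuntimeError):
    """Iterative estimation failed to converge.

    Carries the last iterate in ``last``.
    """

    def __init__(self, message: str, last: float | None = None):
        super().__init__(message)
        self.last = last


@dataclass
class MRResult:
    """A causal-effect estimate on the log-odds (or raw outcome) scale.

    ``or_scale`` holds the exp-transformed (OR, CI low, CI high) triple
    when the outcome is binary; ``extras`` carries method-specific
    diagnostics such as the Egger intercept or the RAPS tau^2.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    or_scale: tuple[float, float, float] | None = None
    extras: dict = field(default_factory=dict)
    exposure_id: str | None = None
    outcome_id: str | None = None


def _two_sided_p(z: float, df: int | None = None) -> float:
    if not math.isfinite(z):
        return 0.0
    if df is None:
        return float(2 * stats.norm.sf(abs(z)))
    return float(2 * stats.t.sf(abs(z), df))


def _finish(
    method: str,
    beta: float,
    se: float,
    n_snp: int,
    binary_outcome: bool,
    df: int | None = None,
    extras: dict | None = None,
    ids: tuple[str | None, str | None] = (None, None),
) -> MRResult:
    crit = stats.norm.ppf(0.975) if df is None else stats.t.ppf(0.975, df)
    if se > 0:
        z = beta / se
        pval = _two_sided_p(z, df)
    else:
        pval = 1.0 if beta == 0 else 0.0
    lo, hi = beta - crit * se, beta + crit * se
    or_scale = (math.exp(beta), math.exp(lo), math.exp(hi)) if binary_outcome else None
    return MRResult(
        method=method, beta=float(beta), se=float(se),
        ci_low=float(lo), ci_high=float(hi), pval=pval, n_snp=n_snp,
        or_scale=or_scale, extras=extras or {},
        exposure_id=ids[0], outcome_id=ids[1],
    )


def _set_arrays(instruments) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    bx, sx, by, so = instruments.arrays()
    if bx.size == 0:
        raise EstimationError("empty instrument set")
    return bx, sx, by, so


def _set_ids(instruments) -> tuple[str | None, str | None]:
    return (
        getattr(instruments, "exposure_id", None),
        getattr(instruments, "outcome_id", None),
    )


def wald_ratio(pair: HarmonizedPair, binary_outcome: bool = True) -> MRResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    SE is first-order: se_out / |beta_exp| (exposure-side noise ignored,
    as in the ratio method's leading term).
    """
    if pair.beta_exp == 0:
        raise EstimationError(f"undefined ratio: beta_exp = 0 for {pair.snp_id}")
    beta = pair.beta_out / pair.beta_exp
    se = pair.se_out / abs(pair.beta_exp)
    return _finish("Wald ratio", beta, se, 1, binary_outcome)


def _ivw_point(bx: np.ndarray, by: np.ndarray, so: np.ndarray) -> tuple[float, float, float]:
    """Fixed-effect IVW point estimate; returns (beta, se_fixed, Q)."""
    w = so ** -2.0
    sxx = float(np.sum(w * bx * bx))
    if sxx == 0:
        raise EstimationError("all exposure betas are zero")
    beta = float(np.sum(w * bx * by)) / sxx
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, sxx ** -0.5, q


def ivw(
    instruments,
    model: str = "multiplicative_random",
    binary_outcome: bool = True,
) -> MRResult:
    """Inverse-variance-weighted estimate over an instrument set.

    With a single SNP this reduces to the Wald ratio.  Cochran's Q at
    the estimate is stored in ``extras`` together with the SE scaling
    factor applied under the multiplicative random-effects model.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown IVW model {model!r}")
    bx, sx, by, so = _set_arrays(instruments)
    n = bx.size
    ids = _set_ids(instruments)
    if n == 1:
        res = wald_ratio(instruments.pairs[0], binary_outcome)
        res.method = "IVW"
        res.exposure_id, res.outcome_id = ids
        return res
    beta, se_fixed, q = _ivw_point(bx, by, so)
    scale = 1.0
    if model == "multiplicative_random":
        scale = max(1.0, math.sqrt(q / (n - 1)))
    se = se_fixed * scale
    extras = {
        "model": model, "Q": q, "Q_df": n - 1,
        "Q_pval": float(stats.chi2.sf(q, n - 1)),
        "se_scale": scale, "se_fixed": se_fixed,
    }
    return _finish("IVW", beta, se, n, binary_outcome, extras=extras, ids=ids)


def _egger_fit(
    bx: np.ndarray, by: np.ndarray, so: np.ndarray
) -> tuple[float, float, float, float, float]:
    """Weighted free-intercept fit on sign-oriented data.

    Returns (intercept, slope, se_int, se_slope, Q) with classical
    estimated-scale SEs.
    """
    s = np.where(bx < 0, -1.0, 1.0)
    x = bx * s
    y = by * s
    w = so ** -2.0
    n = x.size
    X = np.column_stack([np.ones(n), x])
    a = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    try:
        coef = np.linalg.solve(a, b)
    except np.linalg.LinAlgError:
        raise EstimationError("degenerate exposure betas in Egger regression") from None
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    sigma2 = q / (n - 2)
    cov = np.linalg.inv(a) * sigma2
    return float(coef[0]), float(coef[1]), math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1]), q


def egger(instruments, binary_outcome: bool = True) -> MRResult:
    """MR-Egger regression: slope is the causal estimate, the intercept
    tests directional pleiotropy.

    Exposure betas are oriented non-negative (flipping the paired
    outcome beta) before fitting, which the free intercept requires for
    interpretability.  Both slope and intercept use t(n-2) reference
    distributions.
    """
    bx, sx, by, so = _set_arrays(instruments)
    n = bx.size
    if n < 3:
        raise EstimationError("MR-Egger needs at least 3 SNPs")
    intercept, slope, se_int, se_slope, q = _egger_fit(bx, by, so)
    df = n - 2
    extras = {
        "intercept": intercept,
        "intercept_se": se_int,
        "intercept_pval": _two_sided_p(intercept / se_int if se_int > 0 else math.inf, df),
        "Q": q, "Q_df": df, "Q_pval": float(stats.chi2.sf(q, df)),
    }
    return _finish("MR-Egger", slope, se_slope, n, binary_outcome, df=df,
                   extras=extras, ids=_set_ids(instruments))


def _profile_objective(theta: float, bx, sx, by, so) -> float:
    v = so ** 2 + theta ** 2 * sx ** 2
    return float(np.sum((by - theta * bx) ** 2 / v))


def max_likelihood(
    instruments, binary_outcome: bool = True, max_iter: int = 500
) -> MRResult:
    """Profile maximum-likelihood estimate.

    Model: each SNP's observed (beta_exp, beta_out) are independent
    normals centred at (gamma_j, theta * gamma_j) with known SEs.
    Profiling out the gamma_j leaves the objective
    sum_j (beta_out - theta beta_exp)^2 / (se_out^2 + theta^2 se_exp^2),
    minimised numerically; the SE comes from the observed (profile)
    information.
    """
    bx, sx, by, so = _set_arrays(instruments)
    if bx.size < 2:
        raise EstimationError("maximum likelihood needs at least 2 SNPs")
    theta0, se0, _ = _ivw_point(bx, by, so)
    half = max(1.0, 50.0 * se0)
    res = optimize.minimize_scalar(
        _profile_objective, args=(bx, sx, by, so),
        bounds=(theta0 - half, theta0 + half), method="bounded",
        options={"xatol": 1e-12, "maxiter": max_iter},
    )
    if not res.success:
        raise ConvergenceError("profile likelihood did not converge", last=float(res.x))
    theta = float(res.x)
    h = max(1e-6, 1e-5 * abs(theta))
    g2 = (
        _profile_objective(theta + h, bx, sx, by, so)
        - 2 * _profile_objective(theta, bx, sx, by, so)
        + _profile_objective(theta - h, bx, sx, by, so)
    ) / h ** 2
    info = 0.5 * g2  # -2 log L curvature -> observed information
    if info <= 0:
        raise ConvergenceError("non-positive observed information", last=theta)
    se = info ** -0.5
    return _finish("Maximum likelihood", theta, se, bx.size, binary_outcome,
                   extras={"objective": float(res.fun)}, ids=_set_ids(instruments))


def _huber_psi(t: np.ndarray, c: float) -> np.ndarray:
    return np.clip(t, -c, c)


def _raps_score(theta: float, tau2: float, bx, sx, by, so, psi) -> float:
    v = so ** 2 + theta ** 2 * sx ** 2 + tau2
    rt = np.sqrt(v)
    t = (by - theta * bx) / rt
    u = (bx * v + (by - theta * bx) * theta * sx ** 2) / (v * rt)  # -dt/dtheta
    return float(np.sum(psi(t) * u))


def raps(
    instruments,
    loss: str = "l2",
    huber_c: float = 1.345,
    overdispersion: bool = False,
    binary_outcome: bool = True,
) -> MRResult:
    """Robust adjusted profile score estimate.

    Solves sum_j psi(t_j(theta)) * (-dt_j/dtheta) = 0 where
    t_j = (beta_out - theta beta_exp) / sqrt(se_out^2 + theta^2 se_exp^2
    + tau^2), with psi the identity (``l2``) or the Huber function
    (constant 1.345 by default).  With ``overdispersion`` the pleiotropy
    variance tau^2 is estimated jointly by method of moments.  The SE is
    a sandwich estimate with a model-based middle term.
    """
    bx, sx, by, so = _set_arrays(instruments)
    n = bx.size
    if n < 3:
        raise EstimationError("RAPS needs at least 3 SNPs")
    if loss == "l2":
        psi = lambda t: t  # noqa: E731
        delta = 1.0  # E[psi(Z) Z] under Z ~ N(0,1)
        epsi2 = 1.0  # E[psi(Z)^2]
    elif loss == "huber":
        c = huber_c
        psi = lambda t: _huber_psi(t, c)  # noqa: E731
        delta = 1.0 - 2.0 * stats.norm.cdf(-c)
        epsi2 = (
            1.0 - 2.0 * (c * stats.norm.pdf(c) + stats.norm.cdf(-c))
            + 2.0 * c ** 2 * stats.norm.cdf(-c)
        )
    else:
        raise EstimationError(f"unknown loss {loss!r}")

    theta0, se0, _ = _ivw_point(bx, by, so)

    def solve_theta(tau2: float) -> float:
        half = max(1.0, 10.0 * se0)
        for attempt in range(2):
            lo, hi = theta0 - half, theta0 + half
            flo = _raps_score(lo, tau2, bx, sx, by, so, psi)
            fhi = _raps_score(hi, tau2, bx, sx, by, so, psi)
            if flo == 0.0:
                return lo
            if fhi == 0.0:
                return hi
            if flo * fhi < 0:
                return float(optimize.brentq(
                    _raps_score, lo, hi, args=(tau2, bx, sx, by, so, psi), xtol=1e-12
                ))
            half *= 5.0  # widen bracket once
        raise ConvergenceError("no sign change in the profile score bracket", last=theta0)

    tau2 = 0.0
    theta = solve_theta(tau2)
    if overdispersion:
        target = (n - 1) * delta  # E[sum psi(t) t] at the truth

        def moment(tau2_val: float, theta_val: float) -> float:
            v = so ** 2 + theta_val ** 2 * sx ** 2 + tau2_val
            t = (by - theta_val * bx) / np.sqrt(v)
            return float(np.sum(psi(t) * t)) - target

        tau_max = 100.0 * float(np.max(so ** 2))
        for _ in range(50):
            if moment(0.0, theta) <= 0:
                new_tau2 = 0.0
            elif moment(tau_max, theta) > 0:
                raise ConvergenceError("overdispersion estimate diverged", last=theta)
            else:
                new_tau2 = float(optimize.brentq(moment, 0.0, tau_max, args=(theta,), xtol=1e-12))
            new_theta = solve_theta(new_tau2)
            done = abs(new_theta - theta) < 1e-10 and abs(new_tau2 - tau2) < 1e-12
            theta, tau2 = new_theta, new_tau2
            if done:
                break

    # Sandwich SE: A = numerical score derivative, B = model-based
    # variance of the score, E[psi^2] * sum u_j^2.
    h = max(1e-7, 1e-6 * abs(theta))
    a = (
        _raps_score(theta + h, tau2, bx, sx, by, so, psi)
        - _raps_score(theta - h, tau2, bx, sx, by, so, psi)
    ) / (2 * h)
    v = so ** 2 + theta ** 2 * sx ** 2 + tau2
    rt = np.sqrt(v)
    u = (bx * v + (by - theta * bx) * theta * sx ** 2) / (v * rt)
    b_mid = epsi2 * float(np.sum(u ** 2))
    if a == 0:
        raise ConvergenceError("flat profile score at the root", last=theta)
    se = math.sqrt(b_mid) / abs(a)
    extras = {"loss": loss, "tau2": tau2, "overdispersion": overdispersion}
    if loss == "huber":
        extras["huber_c"] = huber_c
    return _finish("MR-RAPS", theta, se, n, binary_outcome, extras=extras,
                   ids=_set_ids(instruments))


def results_frame(results: Iterable[MRResult]) -> pd.DataFrame:
    """Tidy one-row-per-method table mirroring a forest-plot layout."""
    rows = []
    for r in results:
        row = {
            "exposure": r.exposure_id, "outcome": r.outcome_id,
            "method": r.method, "n_snp": r.n_snp,
            "beta": r.beta, "se": r.se,
            "ci_low": r.ci_low, "ci_high": r.ci_high, "pval": r.pval,
        }
        if r.or_scale is not None:
            row["or"], row["or_ci_low"], row["or_ci_high"] = r.or_scale
        rows.append(row)
    return pd.DataFrame(rows)
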