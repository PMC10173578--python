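"""Multivariable MR and the network mediation decomposition.

Multivariable IVW regresses outcome betas jointly on several exposures'
betas (zero intercept, weights se_out^-2); each coefficient is the
conditional (direct) effect of that exposure given the others.  The
mediation decomposition splits the univariable total effect of the
primary exposure into direct and indirect parts:

    indirect = total - direct          (difference method, the default)
    PM       = 100 * indirect / total  (proportion mediated, percent)

computed on the log-odds scale for a binary outcome.  A product-method
alternative (a x b paths) and a bootstrap-over-instruments uncertainty
route are also provided.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import ClumpParams, InstrumentError, LDMatrix, ld_clump_greedy
from .sumstats import HarmonizedSet, SummaryStatTable, harmonize
from .uvmr import EstimationError, MRResult, _finish, _ivw_point


class MediationError(ValueError):
    """Mediation quantity undefined or inputs inconsistent."""


@dataclass
class MVInstrumentSet:
    """Instruments for several exposures jointly.

    ``beta_exp`` is the SNP x exposure matrix of per-allele effects,
    aligned to a common effect allele across all traits.
    """

    exposure_ids: list[str]
    outcome_id: str
    snp_ids: list[str]
    beta_exp: np.ndarray  # (n_snp, n_exposures)
    se_exp: np.ndarray
    beta_out: np.ndarray  # (n_snp,)
    se_out: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n, p = self.beta_exp.shape
        if len(self.snp_ids) != n or len(self.exposure_ids) != p:
            raise EstimationError("MV set dimensions are inconsistent")
        if len(set(self.snp_ids)) != n:
            raise EstimationError("duplicated SNP rows in MV set")
        if np.any(self.se_out <= 0):
            raise EstimationError("nonpositive outcome SE in MV set")

    @property
    def n_snp(self) -> int:
        return len(self.snp_ids)

    def resample(self, rng: np.random.Generator) -> "MVInstrumentSet":
        idx = rng.integers(0, self.n_snp, self.n_snp)
        return MVInstrumentSet(
            self.exposure_ids, self.outcome_id,
            [f"b{i}" for i in range(self.n_snp)],
            self.beta_exp[idx], self.se_exp[idx],
            self.beta_out[idx], self.se_out[idx],
        )


@dataclass
class MVMRResult:
    """Per-exposure conditional effects from one multivariable fit."""

    exposure_ids: list[str]
    outcome_id: str
    estimates: dict[str, MRResult]
    n_snp: int
    extras: dict = field(default_factory=dict)

    def coefficient(self, exposure_id: str) -> MRResult:
        return self.estimates[exposure_id]


def mvmr_ivw(
    mvset: MVInstrumentSet,
    model: str = "multiplicative_random",
    binary_outcome: bool = True,
) -> MVMRResult:
    """Multivariable IVW: weighted multiple regression of outcome betas
    on the exposure-beta matrix with zero intercept.

    Coefficient SEs come from the weighted normal equations; under the
    default multiplicative random-effects model they are inflated by
    max(1, sqrt(Q / (n - p))), which reduces exactly to univariable IVW
    when a single exposure is included.  Exposures whose beta column is
    identically zero are dropped from the fit and reported as NaN; rank
    deficiency among the remaining columns is an error.
    """
    if model not in ("fixed", "multiplicative_random"):
        raise EstimationError(f"unknown model {model!r}")
    X_all = mvset.beta_exp
    y = mvset.beta_out
    w = mvset.se_out ** -2.0
    n, p_all = X_all.shape
    active = [j for j in range(p_all) if np.any(X_all[:, j] != 0)]
    X = X_all[:, active]
    p = len(active)
    if p == 0:
        raise EstimationError("all exposure beta columns are zero")
    if n <= p:
        raise EstimationError("need more SNPs than exposures")
    sw = np.sqrt(w)
    if np.linalg.matrix_rank(sw[:, None] * X) < p:
        raise EstimationError("exposure beta matrix is rank deficient")
    a = X.T @ (w[:, None] * X)
    coef = np.linalg.solve(a, X.T @ (w * y))
    resid = y - X @ coef
    q = float(np.sum(w * resid ** 2))
    df = n - p
    scale = max(1.0, math.sqrt(q / df)) if model == "multiplicative_random" else 1.0
    cov = np.linalg.inv(a) * scale ** 2
    estimates: dict[str, MRResult] = {}
    for j, exp_id in enumerate(mvset.exposure_ids):
        if j not in active:
            estimates[exp_id] = MRResult(
                method="MVMR-IVW", beta=float("nan"), se=float("nan"),
                ci_low=float("nan"), ci_high=float("nan"), pval=float("nan"),
                n_snp=n, extras={"note": "all-zero exposure column"},
                exposure_id=exp_id, outcome_id=mvset.outcome_id,
            )
            continue
        k = active.index(j)
        res = _finish(
            "MVMR-IVW", float(coef[k]), math.sqrt(cov[k, k]), n, binary_outcome,
            extras={
                "conditioning": [e for e in mvset.exposure_ids if e != exp_id],
                "Q": q, "Q_df": df, "Q_pval": float(stats.chi2.sf(q, df)),
                "se_scale": scale, "model": model,
            },
            ids=(exp_id, mvset.outcome_id),
        )
        estimates[exp_id] = res
    return MVMRResult(
        exposure_ids=list(mvset.exposure_ids), outcome_id=mvset.outcome_id,
        estimates=estimates, n_snp=n,
        extras={"Q": q, "Q_df": df, "se_scale": scale, "model": model},
    )


def build_mv_set(
    exposure_tables: Sequence[SummaryStatTable],
    outcome_table: SummaryStatTable,
    params: ClumpParams = ClumpParams(),
    ld: LDMatrix | None = None,
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
) -> MVInstrumentSet:
    """Assemble a joint instrument set for multivariable MR.

    The instrument pool is the union of SNPs reaching the significance
    threshold for at least one included exposure, re-clumped jointly
    (ranking by the minimum p across exposures), then harmonized so all
    traits share the first exposure's allele coding.
    """
    if not exposure_tables:
        raise EstimationError("need at least one exposure table")
    ref = exposure_tables[0]
    pool: dict[str, float] = {}
    for tab in exposure_tables:
        for rec in tab.records:
            if rec.pval < params.p_threshold:
                pool[rec.snp_id] = min(pool.get(rec.snp_id, 1.0), rec.pval)
    # require availability in every table
    for tab in list(exposure_tables) + [outcome_table]:
        pool = {s: p for s, p in pool.items() if s in tab}
    if not pool:
        raise InstrumentError("no shared genome-wide-significant SNPs across traits")
    df = pd.DataFrame(
        {
            "snp": list(pool),
            "chr": [ref.get(s).chrom for s in pool],
            "pos": [ref.get(s).pos for s in pool],
            "pval": [pool[s] for s in pool],
        }
    )
    kept = ld_clump_greedy(df, ld=ld, params=params)
    ref_sub = ref.subset(kept)

    aligned: dict[str, HarmonizedSet] = {}
    keep_ids = set(kept)
    for tab in list(exposure_tables[1:]) + [outcome_table]:
        h = harmonize(ref_sub, tab, palindrome_policy, eaf_window)
        aligned[tab.trait_id] = h
        keep_ids &= {p.snp_id for p in h.pairs}
    snp_ids = [s for s in kept if s in keep_ids]
    if not snp_ids:
        raise InstrumentError("harmonization left no joint instruments")

    p = len(exposure_tables)
    n = len(snp_ids)
    beta_exp = np.zeros((n, p))
    se_exp = np.zeros((n, p))
    for i, s in enumerate(snp_ids):
        rec = ref.get(s)
        beta_exp[i, 0], se_exp[i, 0] = rec.beta, rec.se
    for j, tab in enumerate(exposure_tables[1:], start=1):
        pairs = {q.snp_id: q for q in aligned[tab.trait_id].pairs}
        for i, s in enumerate(snp_ids):
            beta_exp[i, j], se_exp[i, j] = pairs[s].beta_out, pairs[s].se_out
    out_pairs = {q.snp_id: q for q in aligned[outcome_table.trait_id].pairs}
    beta_out = np.array([out_pairs[s].beta_out for s in snp_ids])
    se_out = np.array([out_pairs[s].se_out for s in snp_ids])
    return MVInstrumentSet(
        exposure_ids=[t.trait_id for t in exposure_tables],
        outcome_id=outcome_table.trait_id,
        snp_ids=snp_ids, beta_exp=beta_exp, se_exp=se_exp,
        beta_out=beta_out, se_out=se_out,
        provenance={
            "pool_size": len(pool), "n_clumped": len(kept),
            "n_joint": n, "params": params,
        },
    )


@dataclass
class MediationResult:
    """Total/direct/indirect decomposition with proportion mediated.

    PM is in percent and reported unbounded (it may be negative or
    exceed 100); a quality flag marks such cases.  Uncertainty is a
    delta-method approximation that treats the total and direct
    estimates as independent normals.
    """

    mediators: tuple[str, ...]
    method: str  # "difference" | "product"
    total_beta: float
    total_se: float
    direct_beta: float
    direct_se: float
    indirect_beta: float
    indirect_se: float
    pm: float
    pm_se: float
    pm_ci_low: float
    pm_ci_high: float
    flags: list[str] = field(default_factory=list)


def _pm_delta(total: float, total_se: float, direct: float, direct_se: float):
    pm = 100.0 * (total - direct) / total
    var = 100.0 ** 2 * (direct_se ** 2 / total ** 2
                        + direct ** 2 * total_se ** 2 / total ** 4)
    se = math.sqrt(var)
    z = stats.norm.ppf(0.975)
    return pm, se, pm - z * se, pm + z * se


def _check_ids(a: MRResult, b: MRResult) -> None:
    if a.exposure_id and b.exposure_id and a.exposure_id != b.exposure_id:
        raise MediationError(
            f"exposure ids differ: {a.exposure_id!r} vs {b.exposure_id!r}"
        )
    if a.outcome_id and b.outcome_id and a.outcome_id != b.outcome_id:
        raise MediationError(
            f"outcome ids differ: {a.outcome_id!r} vs {b.outcome_id!r}"
        )


def mediation_difference(
    total: MRResult, direct: MRResult, mediators: Sequence[str] = ()
) -> MediationResult:
    """Two-step (difference-method) decomposition: indirect = total - direct."""
    if total.beta == 0:
        raise MediationError("total effect is zero; PM undefined")
    _check_ids(total, direct)
    indirect = total.beta - direct.beta
    indirect_se = math.sqrt(total.se ** 2 + direct.se ** 2)
    pm, pm_se, lo, hi = _pm_delta(total.beta, total.se, direct.beta, direct.se)
    flags = [] if 0 <= pm <= 100 else ["pm_outside_0_100"]
    return MediationResult(
        mediators=tuple(mediators), method="difference",
        total_beta=total.beta, total_se=total.se,
        direct_beta=direct.beta, direct_se=direct.se,
        indirect_beta=indirect, indirect_se=indirect_se,
        pm=pm, pm_se=pm_se, pm_ci_low=lo, pm_ci_high=hi, flags=flags,
    )


def mediation_product(
    a: MRResult,
    b: MRResult,
    total: MRResult | None = None,
    mediators: Sequence[str] = (),
) -> MediationResult:
    """Product-method indirect effect a x b with the product delta SE.

    ``a`` is the exposure-to-mediator effect, ``b`` the conditional
    mediator-to-outcome effect.  PM requires a supplied total.
    """
    indirect = a.beta * b.beta
    indirect_se = math.sqrt(a.beta ** 2 * b.se ** 2 + b.beta ** 2 * a.se ** 2)
    if total is None:
        raise MediationError("product-method PM needs a total effect")
    if total.beta == 0:
        raise MediationError("total effect is zero; PM undefined")
    direct = total.beta - indirect
    pm = 100.0 * indirect / total.beta
    var = 100.0 ** 2 * (indirect_se ** 2 / total.beta ** 2
                        + indirect ** 2 * total.se ** 2 / total.beta ** 4)
    pm_se = math.sqrt(var)
    z = stats.norm.ppf(0.975)
    flags = [] if 0 <= pm <= 100 else ["pm_outside_0_100"]
    return MediationResult(
        mediators=tuple(mediators), method="product",
        total_beta=total.beta, total_se=total.se,
        direct_beta=direct, direct_se=float("nan"),
        indirect_beta=indirect, indirect_se=indirect_se,
        pm=pm, pm_se=pm_se, pm_ci_low=pm - z * pm_se, pm_ci_high=pm + z * pm_se,
        flags=flags,
    )


@dataclass
class NetworkDecomposition:
    """Single-mediator decompositions plus the all-mediator combined one."""

    singles: list[MediationResult]
    combined: MediationResult

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.singles + [self.combined]:
            rows.append(
                {
                    "mediators": "+".join(r.mediators),
                    "method": r.method,
                    "total_or": math.exp(r.total_beta),
                    "direct_or": math.exp(r.direct_beta),
                    "total_beta": r.total_beta, "total_se": r.total_se,
                    "direct_beta": r.direct_beta, "direct_se": r.direct_se,
                    "indirect_beta": r.indirect_beta, "indirect_se": r.indirect_se,
                    "pm_percent": round(r.pm, 2),
                    "pm_se": r.pm_se,
                    "pm_ci_low": r.pm_ci_low, "pm_ci_high": r.pm_ci_high,
                    "flags": ";".join(r.flags),
                }
            )
        return pd.DataFrame(rows)

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            json.loads(self.to_frame().to_json(orient="records")), indent=2, **kwargs
        )


def network_decomposition(
    total: MRResult,
    direct_single: Mapping[str, MRResult],
    direct_all: MRResult,
) -> NetworkDecomposition:
    """Difference-method decomposition per mediator plus combined."""
    singles = [
        mediation_difference(total, direct, mediators=(med,))
        for med, direct in direct_single.items()
    ]
    combined = mediation_difference(
        total, direct_all, mediators=tuple(direct_single.keys())
    )
    return NetworkDecomposition(singles=singles, combined=combined)


def pm_bootstrap(
    total_set,
    mvset: MVInstrumentSet,
    seed: int,
    exposure_index: int = 0,
    n_boot: int = 1000,
    model: str = "multiplicative_random",
) -> dict:
    """Bootstrap-over-instruments PM uncertainty.

    Resamples SNPs with replacement independently in the univariable
    (total) and multivariable (direct) sets — an alternative to the
    delta method, whose independence assumption is knowingly an
    approximation because the two sets share SNPs.
    """
    rng = np.random.default_rng(seed)
    bx, sx, by, so = total_set.arrays()
    n_tot = bx.size
    exp_id = mvset.exposure_ids[exposure_index]
    draws = []
    failures = 0
    for _ in range(n_boot):
        idx = rng.integers(0, n_tot, n_tot)
        try:
            t_beta, _, _ = _ivw_point(bx[idx], by[idx], so[idx])
            mres = mvmr_ivw(mvset.resample(rng), model=model)
            d_beta = mres.coefficient(exp_id).beta
            if t_beta == 0:
                raise MediationError("zero total")
            draws.append(100.0 * (t_beta - d_beta) / t_beta)
        except (EstimationError, MediationError):
            failures += 1
    draws_arr = np.array(draws)
    return {
        "pm_se": float(np.std(draws_arr, ddof=1)),
        "pm_ci_low": float(np.percentile(draws_arr, 2.5)),
        "pm_ci_high": float(np.percentile(draws_arr, 97.5)),
        "n_boot": n_boot, "n_failed": failures, "seed": seed,
    }
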