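"""Synthetic two-sample GWAS summary statistics under a known causal DAG.

The generator instantiates an exposure -> mediators -> binary-outcome
graph and emits, for every trait, a summary-statistic table over the
union of all instruments, with estimated betas equal to the true path
effects plus sampling noise whose SE is the theoretical value implied by
the stated sample size and allele frequency.  Summary statistics are
produced directly — no individual-level genotypes — which keeps every
study desk-scale; exposure- and outcome-side noise never share random
draws, enforcing two-sample independence.

Continuous traits are on the SD scale (per-SNP SE ~= 1/sqrt(2 f (1-f) n));
the binary outcome is on the log-odds scale with the linearized logistic
approximation SE ~= 1/sqrt(2 f (1-f) n K (1-K)) and case/control counts
attached.  Allele frequencies are uniform on [0.05, 0.5]; palindromic
SNPs and randomly flipped allele codings are generated at configurable
rates to exercise harmonization.

The default parameter values mirror the motivating study design: an
educational-attainment-like exposure, four mediators whose
mediator-to-outcome log-odds effects match reported stroke odds ratios,
a total effect of ln(0.711), and path coefficients chosen so the
combined proportion mediated is 65%.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .sumstats import SummaryStatRecord, SummaryStatTable

_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))
_PLAIN_PAIRS = (
    ("A", "G"), ("G", "A"), ("A", "C"), ("C", "A"),
    ("T", "G"), ("G", "T"), ("T", "C"), ("C", "T"),
)

# Paper-shaped defaults: total = ln(0.711), combined PM = 0.65 split
# (0.30, 0.18, 0.12, 0.05) across the four mediators, with
# mediator->outcome effects matching reported stroke odds ratios
# (1.317, 1.220, 1.429) and 1.105 for the fourth.
_TOTAL = math.log(0.711)
_PM_SPLIT = (0.30, 0.18, 0.12, 0.05)
_B_DEFAULT = (math.log(1.317), math.log(1.220), math.log(1.429), 0.1)
_A_DEFAULT = tuple(f * _TOTAL / b for f, b in zip(_PM_SPLIT, _B_DEFAULT))
_C_DEFAULT = (1 - sum(_PM_SPLIT)) * _TOTAL


class SimulationError(ValueError):
    """Invalid DAG specification."""


@dataclass(frozen=True)
class DagSpec:
    """True causal graph and simulation parameters.

    ``a`` are exposure-to-mediator effects, ``b`` mediator-to-outcome
    effects (log-odds), ``c`` the direct exposure-to-outcome effect
    (log-odds); true estimands are total = c + sum(a_i b_i),
    indirect_i = a_i b_i, PM_i = a_i b_i / total.
    """

    seed: int
    exposure_name: str = "education"
    outcome_name: str = "stroke"
    mediator_names: tuple[str, ...] = ("hypertension", "bmi", "smoking", "tv_time")
    a: tuple[float, ...] = _A_DEFAULT
    b: tuple[float, ...] = _B_DEFAULT
    c: float = _C_DEFAULT
    n_instruments_exposure: int = 50
    n_instruments_mediator: tuple[int, ...] = (50, 50, 50, 50)
    h2_exposure: float = 0.05
    h2_mediator: tuple[float, ...] = (0.05, 0.05, 0.05, 0.05)
    n_exposure: float = 100_000
    n_mediator: tuple[float, ...] = (100_000, 100_000, 100_000, 100_000)
    n_outcome: float = 100_000
    case_fraction: float = 0.09
    pleiotropy_frac: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    tau: float = 0.0
    palindromic_rate: float = 0.1
    allele_flip_rate: float = 0.2
    maf_range: tuple[float, float] = (0.05, 0.5)
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        k = len(self.mediator_names)
        for name, seq in (
            ("a", self.a), ("b", self.b),
            ("n_instruments_mediator", self.n_instruments_mediator),
            ("h2_mediator", self.h2_mediator), ("n_mediator", self.n_mediator),
        ):
            if len(seq) != k:
                raise SimulationError(f"{name} must have one entry per mediator")
        if not (0 < self.case_fraction < 1):
            raise SimulationError("case_fraction must be in (0,1)")
        for h2 in (self.h2_exposure, *self.h2_mediator):
            if not (0 < h2 < 1):
                raise SimulationError("variance explained must be in (0,1)")
        if self.n_instruments_exposure < 1:
            raise SimulationError("exposure needs at least one instrument")
        if not (0 <= self.pleiotropy_frac <= 1):
            raise SimulationError("pleiotropy_frac must be in [0,1]")
        if not (0 < self.maf_range[0] < self.maf_range[1] <= 0.5):
            raise SimulationError("maf_range must satisfy 0 < lo < hi <= 0.5")
        if self.seed is None:
            raise SimulationError("seed is mandatory")

    @property
    def k(self) -> int:
        return len(self.mediator_names)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DagSpec":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("mediator_names", "a", "b", "n_instruments_mediator",
                    "h2_mediator", "n_mediator", "maf_range"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass(frozen=True)
class TrueEffects:
    """Closed-form estimands implied by a :class:`DagSpec`."""

    total: float
    direct: float
    indirect: dict[str, float]
    pm: dict[str, float]  # percent
    pm_combined: float  # percent
    pm_undefined: bool = False


def true_effects(spec: DagSpec) -> TrueEffects:
    """Total/direct/indirect effects and PMs, on the log-odds scale."""
    indirect = {m: ai * bi for m, ai, bi in zip(spec.mediator_names, spec.a, spec.b)}
    total = spec.c + sum(indirect.values())
    if total == 0:
        nan = float("nan")
        return TrueEffects(
            total=0.0, direct=spec.c, indirect=indirect,
            pm={m: nan for m in indirect}, pm_combined=nan, pm_undefined=True,
        )
    pm = {m: 100.0 * v / total for m, v in indirect.items()}
    return TrueEffects(
        total=total, direct=spec.c, indirect=indirect,
        pm=pm, pm_combined=100.0 * sum(indirect.values()) / total,
    )


@dataclass
class SimulatedStudy:
    """Per-trait summary tables plus the ground-truth record."""

    spec: DagSpec
    tables: dict[str, SummaryStatTable]
    truth: TrueEffects
    seed: int
    generator_version: str = "1"

    @property
    def exposure(self) -> SummaryStatTable:
        return self.tables[self.spec.exposure_name]

    @property
    def outcome(self) -> SummaryStatTable:
        return self.tables[self.spec.outcome_name]

    def mediator(self, name: str) -> SummaryStatTable:
        return self.tables[name]

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, table in self.tables.items():
            table.write(out / f"{name}.tsv")
        self.spec.to_yaml(out / "dag_spec.yaml")
        truth = asdict(self.truth)
        (out / "truth.json").write_text(json.dumps(truth, indent=2))


def simulate_sumstats(spec: DagSpec) -> SimulatedStudy:
    """Draw one two-sample summary-statistic study from the DAG.

    Regenerating with the same spec (same seed) is bit-identical.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_traits = 2 + spec.k
    children = ss.spawn(1 + n_traits)
    rng = np.random.default_rng(children[0])  # structure: SNPs, effects

    counts = [spec.n_instruments_exposure, *spec.n_instruments_mediator]
    node_of = np.repeat(np.arange(1 + spec.k), counts)  # 0 = exposure
    m_total = node_of.size

    maf = rng.uniform(*spec.maf_range, m_total)
    het = 2.0 * maf * (1.0 - maf)  # per-SNP genotype variance
    is_palin = rng.random(m_total) < spec.palindromic_rate
    palin_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), m_total)
    plain_idx = rng.integers(0, len(_PLAIN_PAIRS), m_total)
    alleles = [
        _PALINDROMIC_PAIRS[pi] if pal else _PLAIN_PAIRS[qi]
        for pal, pi, qi in zip(is_palin, palin_idx, plain_idx)
    ]
    chroms = [(s % 22) + 1 for s in range(m_total)]
    # Distinct 25 Mb slots keep true instruments independent under the
    # 10 Mb distance-only clumping fallback.
    positions = [1_000_000 + (s // 22) * 25_000_000 for s in range(m_total)]
    snp_ids = [f"rs{100000 + s}" for s in range(m_total)]

    # True per-SNP effects on the SNP's own node, scaled so the node's
    # instruments explain exactly h2 of its (unit) variance.
    h2 = [spec.h2_exposure, *spec.h2_mediator]
    raw = rng.normal(size=m_total)
    beta_own = np.zeros(m_total)
    for g in range(1 + spec.k):
        mask = node_of == g
        norm = float(np.sum(het[mask] * raw[mask] ** 2))
        beta_own[mask] = raw[mask] * math.sqrt(h2[g] / norm)

    a = np.asarray(spec.a)
    b = np.asarray(spec.b)
    total = spec.c + float(np.sum(a * b))

    # True effects of every SNP on every trait, via path products.
    exp_mask = node_of == 0
    true_beta: dict[str, np.ndarray] = {}
    true_beta[spec.exposure_name] = np.where(exp_mask, beta_own, 0.0)
    for i, med in enumerate(spec.mediator_names):
        med_mask = node_of == i + 1
        true_beta[med] = np.where(exp_mask, a[i] * beta_own, 0.0) \
            + np.where(med_mask, beta_own, 0.0)
    out_effect = np.where(exp_mask, total * beta_own, 0.0)
    for i in range(spec.k):
        out_effect = out_effect + np.where(node_of == i + 1, b[i] * beta_own, 0.0)
    if spec.pleiotropy_frac > 0:
        pleio = rng.random(m_total) < spec.pleiotropy_frac
        # Offsets are oriented relative to the allele that raises the
        # SNP's own trait, so a nonzero mean is directional in the
        # Egger-intercept sense (constant offsets under symmetric
        # effect-size draws would cancel after sign orientation).
        orient = np.where(beta_own >= 0, 1.0, -1.0)
        out_effect = out_effect + pleio * orient * rng.normal(
            spec.pleiotropy_mean, max(spec.pleiotropy_sd, 1e-300), m_total
        )
    if spec.tau > 0:
        out_effect = out_effect + rng.normal(0.0, spec.tau, m_total)
    true_beta[spec.outcome_name] = out_effect

    k_frac = spec.case_fraction
    trait_order = [spec.exposure_name, *spec.mediator_names, spec.outcome_name]
    n_of = {spec.exposure_name: spec.n_exposure, spec.outcome_name: spec.n_outcome}
    n_of.update(dict(zip(spec.mediator_names, spec.n_mediator)))

    tables: dict[str, SummaryStatTable] = {}
    for t, trait in enumerate(trait_order):
        trait_rng = np.random.default_rng(children[1 + t])
        binary = trait == spec.outcome_name
        n_gwas = n_of[trait]
        se = 1.0 / np.sqrt(het * n_gwas * ((k_frac * (1 - k_frac)) if binary else 1.0))
        beta_hat = true_beta[trait] + spec.noise_scale * trait_rng.normal(0.0, se)
        pval = 2.0 * _norm_sf(np.abs(beta_hat) / se)
        flip = np.zeros(m_total, dtype=bool)
        if trait != spec.exposure_name and spec.allele_flip_rate > 0:
            flip = trait_rng.random(m_total) < spec.allele_flip_rate
        n_case = round(k_frac * n_gwas) if binary else None
        n_control = n_gwas - n_case if binary else None
        records = []
        for s in range(m_total):
            ea, oa = alleles[s]
            beta_s, eaf_s = float(beta_hat[s]), float(maf[s])
            if flip[s]:
                ea, oa = oa, ea
                beta_s, eaf_s = -beta_s, 1.0 - eaf_s
            records.append(
                SummaryStatRecord(
                    snp_id=snp_ids[s], effect_allele=ea, other_allele=oa,
                    beta=beta_s, se=float(se[s]),
                    pval=float(min(max(pval[s], 5e-324), 1.0)),
                    chrom=str(chroms[s]), pos=positions[s], eaf=eaf_s,
                    n=n_gwas, n_case=n_case, n_control=n_control,
                )
            )
        tables[trait] = SummaryStatTable(
            trait, "binary" if binary else "continuous", records
        )
    return SimulatedStudy(
        spec=spec, tables=tables, truth=true_effects(spec), seed=spec.seed
    )


def _norm_sf(z: np.ndarray) -> np.ndarray:
    from scipy.stats import norm

    return norm.sf(z)
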