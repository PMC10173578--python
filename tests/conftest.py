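from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from netmr.instruments import ClumpParams, InstrumentSet
from netmr.sumstats import HarmonizedPair, HarmonizedSet

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_instrument_set(
    bx, by, so, sx=None, exposure_id="exp", outcome_id="out"
) -> InstrumentSet:
    """Build an instrument set directly from effect arrays (helper for
    estimator tests that don't need the harmonization path)."""
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    so = np.asarray(so, dtype=float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, dtype=float)
    pairs = [
        HarmonizedPair(
            snp_id=f"rs{i}", effect_allele="A", other_allele="G",
            beta_exp=float(bx[i]), se_exp=float(sx[i]), pval_exp=1e-12,
            beta_out=float(by[i]), se_out=float(so[i]), pval_out=0.5,
            eaf_exp=0.3, eaf_out=0.3, status="kept",
            chrom=str(i % 22 + 1), pos=1_000_000 + 25_000_000 * (i // 22),
        )
        for i in range(bx.size)
    ]
    hset = HarmonizedSet(exposure_id, outcome_id, pairs)
    return InstrumentSet(hset, ClumpParams())


@pytest.fixture
def consistent_set() -> InstrumentSet:
    """Five instruments whose per-SNP ratios all equal 0.2 exactly."""
    bx = np.array([0.05, 0.1, 0.15, 0.2, 0.25])
    return make_instrument_set(bx, 0.2 * bx, np.full(5, 0.01))


@pytest.fixture
def toy_two_snp_set() -> InstrumentSet:
    """The closed-form IVW example: beta = (10+40)/(100+100) = 0.25."""
    return make_instrument_set([0.1, 0.2], [0.01, 0.08], [0.01, 0.02])


@pytest.fixture
def noisy_set() -> InstrumentSet:
    """Six instruments with heterogeneous ratios, fixed draws."""
    rng = np.random.default_rng(42)
    bx = rng.uniform(0.05, 0.3, 6)
    so = rng.uniform(0.01, 0.03, 6)
    by = 0.3 * bx + rng.normal(0, so)
    sx = np.full(6, 0.005)
    return make_instrument_set(bx, by, so, sx)
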