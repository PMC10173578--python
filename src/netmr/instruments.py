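"""Instrument selection: significance filtering, LD clumping, strength.

Instruments are SNPs that pass genome-wide significance for the exposure
(P < 5e-8 by default) and survive greedy LD clumping at r^2 < 0.001
within a 10 Mb window.  When no LD matrix is available the clumper runs
in distance-only mode and treats every same-chromosome SNP within the
window as correlated — a conservative fallback that preserves the
independence guarantee without a reference panel.

Instrument strength is summarised by the per-SNP F statistic
(beta/se)^2; a mean F at or below 10 flags the set as weak.
Confounder-associated SNPs are removed through a user-supplied exclusion
list (snp_id, reason) rather than a live database query.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .sumstats import HarmonizedPair, HarmonizedSet

WEAK_F_THRESHOLD = 10.0


class InstrumentError(ValueError):
    """Instrument selection cannot proceed."""


class ClumpError(ValueError):
    """LD clumping failed (e.g. SNP missing from the LD matrix)."""


@dataclass(frozen=True)
class ClumpParams:
    """LD-clumping parameters.

    Defaults follow standard two-sample practice: genome-wide
    significance 5e-8, r^2 < 0.001, 10 Mb window (inclusive distance on
    the same chromosome).
    """

    p_threshold: float = 5e-8
    r2_threshold: float = 0.001
    window_bp: int = 10_000_000

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold < 1):
            raise InstrumentError("p_threshold must be in (0,1)")
        if not (0 <= self.r2_threshold <= 1):
            raise InstrumentError("r2_threshold must be in [0,1]")
        if self.window_bp <= 0:
            raise InstrumentError("window_bp must be positive")


class LDMatrix:
    """Symmetric SNP x SNP r^2 matrix with SNP-id labels."""

    def __init__(self, snp_ids: Sequence[str], r2: np.ndarray):
        r2 = np.asarray(r2, dtype=float)
        n = len(snp_ids)
        if r2.shape != (n, n):
            raise ClumpError("r2 matrix shape does not match snp id count")
        if np.any(r2 < 0) or np.any(r2 > 1):
            raise ClumpError("r2 values must lie in [0,1]")
        if not np.allclose(np.diag(r2), 1.0):
            raise ClumpError("r2 diagonal must be 1")
        if not np.allclose(r2, r2.T):
            raise ClumpError("r2 matrix must be symmetric")
        self.snp_ids = list(snp_ids)
        self._idx = {s: i for i, s in enumerate(self.snp_ids)}
        self.r2 = r2

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._idx

    def r2_between(self, a: str, b: str) -> float:
        try:
            return float(self.r2[self._idx[a], self._idx[b]])
        except KeyError as exc:
            raise ClumpError(f"SNP {exc.args[0]!r} missing from LD matrix") from None

    @classmethod
    def from_tsv(cls, path: str | Path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.columns), df.to_numpy())

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r2, index=self.snp_ids, columns=self.snp_ids).to_csv(path, sep="\t")


def ld_clump_greedy(
    snps: pd.DataFrame,
    ld: LDMatrix | None = None,
    params: ClumpParams = ClumpParams(),
) -> list[str]:
    """Greedy LD clumping; returns kept SNP ids in selection order.

    ``snps`` needs columns ``snp``, ``chr``, ``pos``, ``pval``.  SNPs are
    ranked ascending by p-value (ties broken by position then id); the
    best remaining SNP is kept and all remaining SNPs on the same
    chromosome within ``window_bp`` whose r^2 with it reaches
    ``r2_threshold`` are removed.  Without an LD matrix, any
    same-chromosome SNP within the window is removed.
    """
    required = {"snp", "chr", "pos", "pval"}
    if not required.issubset(snps.columns):
        raise ClumpError(f"clump input needs columns {sorted(required)}")
    df = snps.sort_values(["pval", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    remaining = list(df.itertuples(index=False))
    kept: list[str] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best.snp)
        survivors = []
        for row in remaining:
            same_chrom = str(row.chr) == str(best.chr)
            in_window = same_chrom and abs(int(row.pos) - int(best.pos)) <= params.window_bp
            if in_window:
                if ld is None:
                    continue  # distance-only mode: treat as correlated
                if ld.r2_between(best.snp, row.snp) >= params.r2_threshold:
                    continue
            survivors.append(row)
        remaining = survivors
    return kept


def f_statistic(pair: HarmonizedPair) -> float:
    """Per-SNP instrument strength, the squared-t approximation (beta/se)^2."""
    if not pair.se_exp > 0:
        raise InstrumentError("se_exp must be positive")
    return (pair.beta_exp / pair.se_exp) ** 2


@dataclass
class InstrumentSet:
    """A harmonized set restricted to selected instruments.

    Carries the clumping parameters used and per-SNP F statistics; a
    mean F at or below 10 marks the set as weak.
    """

    hset: HarmonizedSet
    params: ClumpParams
    provenance: dict = field(default_factory=dict)

    @property
    def exposure_id(self) -> str:
        return self.hset.exposure_id

    @property
    def outcome_id(self) -> str:
        return self.hset.outcome_id

    @property
    def pairs(self) -> list[HarmonizedPair]:
        return self.hset.pairs

    @property
    def n_snp(self) -> int:
        return self.hset.n_snp

    @property
    def snp_ids(self) -> list[str]:
        return [p.snp_id for p in self.pairs]

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        return self.hset.arrays()

    @property
    def f_stats(self) -> np.ndarray:
        bx, sx, _, _ = self.arrays()
        return (bx / sx) ** 2

    @property
    def mean_f(self) -> float:
        return float(np.mean(self.f_stats)) if self.n_snp else float("nan")

    @property
    def is_weak(self) -> bool:
        return self.mean_f <= WEAK_F_THRESHOLD

    @property
    def weak_snps(self) -> list[str]:
        f = self.f_stats
        return [p.snp_id for p, fj in zip(self.pairs, f) if fj <= WEAK_F_THRESHOLD]

    def subset(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        return replace(self, hset=self.hset.subset(snp_ids), provenance=dict(self.provenance))

    def without(self, snp_ids: Iterable[str]) -> "InstrumentSet":
        return replace(self, hset=self.hset.without(snp_ids), provenance=dict(self.provenance))


def select_instruments(
    hset: HarmonizedSet,
    params: ClumpParams = ClumpParams(),
    ld: LDMatrix | None = None,
) -> InstrumentSet:
    """Filter to genome-wide-significant SNPs and clump to independence."""
    sig = [p for p in hset.pairs if p.pval_exp < params.p_threshold]
    if not sig:
        raise InstrumentError(
            f"no SNPs pass P < {params.p_threshold:g} for {hset.exposure_id}"
        )
    df = pd.DataFrame(
        {
            "snp": [p.snp_id for p in sig],
            "chr": [p.chrom for p in sig],
            "pos": [p.pos for p in sig],
            "pval": [p.pval_exp for p in sig],
        }
    )
    kept = ld_clump_greedy(df, ld=ld, params=params)
    order = {s: i for i, s in enumerate(kept)}
    sub = hset.subset(kept)
    sub.pairs.sort(key=lambda p: order[p.snp_id])
    provenance = {
        "n_significant": len(sig),
        "n_clumped_out": len(sig) - len(kept),
        "ld_mode": "matrix" if ld is not None else "distance_only",
    }
    return InstrumentSet(sub, params, provenance)


def read_exclusion_list(path: str | Path) -> dict[str, str]:
    """Read a two-column (snp_id, reason) TSV; a header row is optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        df[1] = "listed"
    if str(df.iloc[0, 0]).lower() in ("snp", "snp_id", "rsid"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1].fillna("listed")))


def apply_exclusions(
    instruments: InstrumentSet,
    exclusions: Mapping[str, str] | Iterable[tuple[str, str]],
) -> InstrumentSet:
    """Remove confounder-associated SNPs, recording each removal.

    SNPs in the list that are absent from the set trigger a warning only;
    emptying the set entirely is an error.
    """
    if not isinstance(exclusions, Mapping):
        exclusions = dict(exclusions)
    present = set(instruments.snp_ids)
    removed = {s: r for s, r in exclusions.items() if s in present}
    unknown = sorted(set(exclusions) - present)
    if unknown:
        warnings.warn(
            f"exclusion list names {len(unknown)} SNP(s) not in the instrument set: "
            + ", ".join(unknown[:5]),
            stacklevel=2,
        )
    if not removed:
        return instruments
    if len(removed) == instruments.n_snp:
        raise InstrumentError("empty instrument set after exclusions")
    out = instruments.without(removed)
    out.provenance = dict(instruments.provenance)
    out.provenance.setdefault("exclusions", [])
    out.provenance["exclusions"] = out.provenance["exclusions"] + sorted(removed.items())
    return out
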