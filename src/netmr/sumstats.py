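"""Read, validate, and harmonize GWAS summary statistics.

Summary statistics are exchanged as delimited text tables (TSV or CSV)
with a header row.  The canonical column names are::

    snp  chr  pos  ea  oa  eaf  beta  se  pval  n  ncase  ncontrol

Any other layout can be read by supplying a ``column_map`` that maps
canonical names to the names used in the file.  Base-pair positions are
1-based throughout, following GWAS summary-data convention.

Harmonization aligns the outcome association of each shared SNP to the
exposure's effect allele.  Allele order swaps negate the outcome beta and
reflect the allele frequency; complementary-strand codings are translated
before alignment; palindromic SNPs (A/T or C/G) are either dropped or,
optionally, oriented by allele-frequency agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = (
    "snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval",
    "n", "ncase", "ncontrol",
)
REQUIRED_COLUMNS = ("snp", "ea", "oa", "beta", "se", "pval")

KEPT_STATUSES = ("kept", "flipped", "strand_flipped")
DROPPED_STATUSES = ("dropped_palindromic", "dropped_incompatible")


class SumstatError(ValueError):
    """Malformed or unusable summary-statistic input."""


class HarmonizeError(ValueError):
    """Exposure/outcome pair cannot be harmonized."""


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP-trait association.

    ``beta`` is the per-effect-allele association: log-odds for binary
    traits, SD or raw units for continuous traits.  ``eaf`` is the
    effect-allele frequency and may be missing (``None``).
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chrom: str = ""
    pos: int = 0
    eaf: float | None = None
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None

    def violations(self) -> list[str]:
        """Return reasons this record violates the type invariants."""
        out: list[str] = []
        if not (self.se > 0) or not math.isfinite(self.se):
            out.append("nonpositive SE")
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            out.append("invalid allele")
        elif self.effect_allele == self.other_allele:
            out.append("identical alleles")
        if not (0 < self.pval <= 1):
            out.append("p-value outside (0,1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            out.append("EAF outside [0,1]")
        if not math.isfinite(self.beta):
            out.append("non-finite beta")
        if (
            self.n is not None
            and self.n_case is not None
            and self.n_control is not None
            and abs(self.n_case + self.n_control - self.n) > 1.0
        ):
            out.append("case/control counts do not sum to n")
        return out


@dataclass(frozen=True)
class TraitMeta:
    """Trait-level metadata attached to a summary-statistic table."""

    trait_id: str
    trait_type: str  # "continuous" | "binary"
    n: float | None = None
    n_case: float | None = None
    n_control: float | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatError(f"unknown trait_type {self.trait_type!r}")


@dataclass
class SummaryStatTable:
    """Validated per-trait table of :class:`SummaryStatRecord`.

    SNP ids are unique within a table; rows rejected during reading are
    kept in ``rejections`` as ``(snp_or_row_label, reason)`` pairs.
    """

    trait_id: str
    trait_type: str
    records: list[SummaryStatRecord]
    rejections: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise SumstatError(f"unknown trait_type {self.trait_type!r}")
        self._index: dict[str, SummaryStatRecord] = {}
        for rec in self.records:
            if rec.snp_id in self._index:
                raise SumstatError(f"duplicate snp_id {rec.snp_id!r} in {self.trait_id}")
            self._index[rec.snp_id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> SummaryStatRecord:
        return self._index[snp_id]

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    @property
    def n_missing_eaf(self) -> int:
        return sum(1 for r in self.records if r.eaf is None)

    def subset(self, snp_ids: Iterable[str]) -> "SummaryStatTable":
        wanted = set(snp_ids)
        return SummaryStatTable(
            self.trait_id, self.trait_type,
            [r for r in self.records if r.snp_id in wanted],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id, "chr": r.chrom, "pos": r.pos,
                "ea": r.effect_allele, "oa": r.other_allele,
                "eaf": np.nan if r.eaf is None else r.eaf,
                "beta": r.beta, "se": r.se, "pval": r.pval,
                "n": np.nan if r.n is None else r.n,
                "ncase": np.nan if r.n_case is None else r.n_case,
                "ncontrol": np.nan if r.n_control is None else r.n_control,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _opt(value) -> float | None:
    if value is None:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return None if math.isnan(v) else v


def read_sumstats(
    path: str | Path,
    trait_meta: TraitMeta,
    column_map: Mapping[str, str] | None = None,
) -> SummaryStatTable:
    """Read a delimited summary-statistic file into a validated table.

    Parameters
    ----------
    path:
        TSV or CSV file with a header row (delimiter is sniffed).
    trait_meta:
        Trait id/type and fallback sample sizes used when the file lacks
        ``n``/``ncase``/``ncontrol`` columns.
    column_map:
        Optional mapping from canonical column names (see
        :data:`CANONICAL_COLUMNS`) to the names used in the file.

    Rows violating record invariants are rejected, with a per-row reason
    recorded on the returned table; missing EAF is allowed.
    """
    path = Path(path)
    if not path.exists():
        raise SumstatError(f"summary-statistic file not found: {path}")
    df = pd.read_csv(path, sep=None, engine="python")
    if column_map:
        rename = {v: k for k, v in column_map.items()}
        df = df.rename(columns=rename)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SumstatError(f"missing required column(s): {', '.join(missing)}")

    records: list[SummaryStatRecord] = []
    rejections: list[tuple[str, str]] = []
    for i, row in df.iterrows():
        snp = str(row["snp"])
        rec = SummaryStatRecord(
            snp_id=snp,
            effect_allele=str(row["ea"]).strip().upper(),
            other_allele=str(row["oa"]).strip().upper(),
            beta=float(row["beta"]),
            se=float(row["se"]),
            pval=float(row["pval"]),
            chrom=str(row["chr"]) if "chr" in df.columns else "",
            pos=int(row["pos"]) if "pos" in df.columns and not pd.isna(row["pos"]) else 0,
            eaf=_opt(row.get("eaf")),
            n=_opt(row.get("n")) if _opt(row.get("n")) is not None else trait_meta.n,
            n_case=_opt(row.get("ncase")) if _opt(row.get("ncase")) is not None else trait_meta.n_case,
            n_control=_opt(row.get("ncontrol")) if _opt(row.get("ncontrol")) is not None else trait_meta.n_control,
        )
        bad = rec.violations()
        if bad:
            rejections.append((snp, "; ".join(bad)))
        else:
            records.append(rec)
    if not records:
        raise SumstatError(f"zero valid rows in {path}")
    table = SummaryStatTable(trait_meta.trait_id, trait_meta.trait_type, records)
    table.rejections = rejections
    return table


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure/outcome associations for one SNP after allele alignment.

    Alleles are stored in the exposure's coding; ``status`` records what
    was done to the outcome row to reach it.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    pval_exp: float
    beta_out: float
    se_out: float
    pval_out: float
    eaf_exp: float | None
    eaf_out: float | None
    status: str
    chrom: str = ""
    pos: int = 0


@dataclass
class HarmonizedSet:
    """Harmonized exposure/outcome pairs — the unit of all MR estimators."""

    exposure_id: str
    outcome_id: str
    pairs: list[HarmonizedPair]
    dropped: dict[str, str] = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            if p.snp_id in seen:
                raise HarmonizeError(f"duplicate snp_id {p.snp_id!r}")
            seen.add(p.snp_id)
            if not (p.se_exp > 0 and p.se_out > 0):
                raise HarmonizeError(f"nonpositive SE for kept pair {p.snp_id!r}")

    @property
    def n_snp(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Return (beta_exp, se_exp, beta_out, se_out) arrays."""
        bx = np.array([p.beta_exp for p in self.pairs])
        sx = np.array([p.se_exp for p in self.pairs])
        by = np.array([p.beta_out for p in self.pairs])
        so = np.array([p.se_out for p in self.pairs])
        return bx, sx, by, so

    def subset(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        wanted = set(snp_ids)
        return replace(
            self, pairs=[p for p in self.pairs if p.snp_id in wanted],
            dropped=dict(self.dropped), provenance=dict(self.provenance),
        )

    def without(self, snp_ids: Iterable[str]) -> "HarmonizedSet":
        bad = set(snp_ids)
        return replace(
            self, pairs=[p for p in self.pairs if p.snp_id not in bad],
            dropped=dict(self.dropped), provenance=dict(self.provenance),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": p.snp_id, "chr": p.chrom, "pos": p.pos,
                "ea": p.effect_allele, "oa": p.other_allele,
                "beta_exp": p.beta_exp, "se_exp": p.se_exp, "pval_exp": p.pval_exp,
                "beta_out": p.beta_out, "se_out": p.se_out, "pval_out": p.pval_out,
                "eaf_exp": np.nan if p.eaf_exp is None else p.eaf_exp,
                "eaf_out": np.nan if p.eaf_out is None else p.eaf_out,
                "status": p.status,
            }
            for p in self.pairs
        ]
        return pd.DataFrame(rows)

    def write(self, path: str | Path, sep: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def _orientation(o_ea: str, o_oa: str, e_ea: str, e_oa: str) -> tuple[str | None, bool]:
    """How the outcome coding relates to the exposure coding.

    Returns ``(order, strand)`` where order is "same"/"swap"/None and
    strand indicates a complementary-strand translation was needed.
    """
    if (o_ea, o_oa) == (e_ea, e_oa):
        return "same", False
    if (o_ea, o_oa) == (e_oa, e_ea):
        return "swap", False
    c_ea, c_oa = COMPLEMENT.get(o_ea), COMPLEMENT.get(o_oa)
    if (c_ea, c_oa) == (e_ea, e_oa):
        return "same", True
    if (c_ea, c_oa) == (e_oa, e_ea):
        return "swap", True
    return None, False


def harmonize(
    exposure: SummaryStatTable,
    outcome: SummaryStatTable,
    palindrome_policy: str = "drop",
    eaf_window: float = 0.08,
) -> HarmonizedSet:
    """Align outcome associations to the exposure's effect allele.

    Parameters
    ----------
    palindrome_policy:
        ``"drop"`` removes palindromic (A/T, C/G) SNPs outright;
        ``"infer_by_eaf"`` orients them by allele-frequency agreement and
        drops those whose EAF on either side is within ``eaf_window`` of
        0.5 (or whose EAF is missing), where strand cannot be inferred.
    eaf_window:
        Half-width of the ambiguous frequency band around 0.5.
    """
    if palindrome_policy not in ("drop", "infer_by_eaf"):
        raise HarmonizeError(f"unknown palindrome_policy {palindrome_policy!r}")
    if exposure.trait_id == outcome.trait_id:
        raise HarmonizeError("exposure and outcome are the same trait")
    shared = [s for s in exposure.snp_ids if s in outcome]
    if not shared:
        raise HarmonizeError("no shared SNPs between exposure and outcome")

    pairs: list[HarmonizedPair] = []
    dropped: dict[str, str] = {}
    counts = dict.fromkeys(KEPT_STATUSES + DROPPED_STATUSES, 0)

    for snp in shared:
        e = exposure.get(snp)
        o = outcome.get(snp)
        status, b_out, eaf_out = _align_one(e, o, palindrome_policy, eaf_window)
        counts[status] += 1
        if status in DROPPED_STATUSES:
            dropped[snp] = status
            continue
        pairs.append(
            HarmonizedPair(
                snp_id=snp,
                effect_allele=e.effect_allele,
                other_allele=e.other_allele,
                beta_exp=e.beta, se_exp=e.se, pval_exp=e.pval,
                beta_out=b_out, se_out=o.se, pval_out=o.pval,
                eaf_exp=e.eaf, eaf_out=eaf_out,
                status=status, chrom=e.chrom, pos=e.pos,
            )
        )
    provenance = {
        "palindrome_policy": palindrome_policy,
        "eaf_window": eaf_window,
        "n_shared": len(shared),
        "counts": counts,
    }
    return HarmonizedSet(exposure.trait_id, outcome.trait_id, pairs, dropped, provenance)


def _align_one(
    e: SummaryStatRecord,
    o: SummaryStatRecord,
    policy: str,
    window: float,
) -> tuple[str, float, float | None]:
    """Align one outcome record to the exposure coding.

    Returns ``(status, beta_out, eaf_out)``; beta/eaf are meaningful only
    for kept statuses.
    """
    if _is_palindromic(e.effect_allele, e.other_allele):
        if {o.effect_allele, o.other_allele} != {e.effect_allele, e.other_allele}:
            return "dropped_incompatible", o.beta, o.eaf
        if policy == "drop":
            return "dropped_palindromic", o.beta, o.eaf
        if e.eaf is None or o.eaf is None:
            return "dropped_palindromic", o.beta, o.eaf
        if abs(e.eaf - 0.5) <= window or abs(o.eaf - 0.5) <= window:
            return "dropped_palindromic", o.beta, o.eaf
        # Label alignment first, then strand inference by EAF agreement:
        # after alignment the two frequencies must fall on the same side
        # of 0.5; otherwise the outcome is on the other strand and the
        # effect direction is reversed.
        b_out, eaf_out = o.beta, o.eaf
        flips = 0
        if o.effect_allele != e.effect_allele:
            b_out, eaf_out, flips = -b_out, 1 - eaf_out, flips + 1
        if (e.eaf - 0.5) * (eaf_out - 0.5) < 0:
            b_out, eaf_out, flips = -b_out, 1 - eaf_out, flips + 1
        return ("flipped" if flips % 2 else "kept"), b_out, eaf_out

    order, strand = _orientation(o.effect_allele, o.other_allele, e.effect_allele, e.other_allele)
    if order is None:
        return "dropped_incompatible", o.beta, o.eaf
    if order == "same":
        status = "strand_flipped" if strand else "kept"
        return status, o.beta, o.eaf
    status = "strand_flipped" if strand else "flipped"
    eaf_out = None if o.eaf is None else 1 - o.eaf
    return status, -o.beta, eaf_out
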