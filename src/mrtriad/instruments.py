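"""Instrument selection and exposure-outcome harmonization.

Covers the four gates applied before any causal estimate: a p-value
threshold on the exposure associations, greedy LD clumping within a genomic
window, a per-SNP strength filter F = (beta/se)^2 >= cutoff, and allele
harmonization between the exposure and outcome tables (sign flips for
swapped alleles, frequency-based resolution of palindromic variants).
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from pathlib import Path

import numpy as np
import pandas as pd

from mrtriad.summary_io import SummaryStats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# defaults mirroring common two-sample MR practice
DEFAULT_P_THRESHOLD = 1e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_KB = 10_000
DEFAULT_F_MIN = 10.0
DEFAULT_PALINDROMIC_EAF_WINDOW = 0.08


@dataclasses.dataclass
class LDInfo:
    """Pairwise LD (r-squared) for a set of SNPs.

    ``r2`` is symmetric with unit diagonal and entries in [0, 1].  When a
    pair is absent (or the whole object is None at the call site) its r2 is
    treated as zero, degrading clumping to distance-only pruning.
    """

    snp_ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        k = len(self.snp_ids)
        if self.r2.shape != (k, k):
            raise ValueError(f"r2 matrix shape {self.r2.shape} != ({k}, {k})")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-8):
            raise ValueError("r2 diagonal must be exactly 1")
        if (self.r2 < -1e-12).any() or (self.r2 > 1 + 1e-12).any():
            raise ValueError("r2 values must lie in [0, 1]")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def pair_r2(self, a: str, b: str) -> float:
        """r2 for a SNP pair, 0.0 when either SNP is unknown."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return 0.0
        return float(self.r2[ia, ib])


def read_ld_matrix(path: str | Path) -> LDInfo:
    """Read a square r2 matrix from TSV (header row/index = SNP ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return LDInfo(list(df.columns), df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDInfo, path: str | Path) -> None:
    pd.DataFrame(ld.r2, index=ld.snp_ids, columns=ld.snp_ids).to_csv(
        path, sep="\t", float_format="%.6g"
    )


@dataclasses.dataclass
class HarmonizedSet:
    """Exposure-outcome matched instrument table after harmonization.

    One row per retained SNP with aligned effect alleles: ``beta_exp``,
    ``se_exp``, ``beta_out``, ``se_out``, ``f_stat`` and a ``flipped`` flag.
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame

    REQUIRED = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "f_stat", "flipped"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"HarmonizedSet missing columns: {missing}")
        if not (self.table["se_exp"] > 0).all() or not (self.table["se_out"] > 0).all():
            raise ValueError("all standard errors must be positive")
        self.table = self.table.reset_index(drop=True)

    @property
    def n_snps(self) -> int:
        return len(self.table)

    def drop_snps(self, snp_ids) -> "HarmonizedSet":
        keep = ~self.table["snp_id"].isin(list(snp_ids))
        return HarmonizedSet(
            self.exposure_id, self.outcome_id, self.table.loc[keep].reset_index(drop=True)
        )


def select_instruments(stats: SummaryStats, p_threshold: float = DEFAULT_P_THRESHOLD) -> SummaryStats:
    """Rows with pval strictly below the threshold, input order preserved."""
    mask = stats.table["pval"] < p_threshold
    if not mask.any():
        import warnings

        warnings.warn(
            f"no instruments for {stats.trait_id} at p < {p_threshold}", stacklevel=2
        )
    return stats.subset(mask)


def f_statistic(beta, se):
    """Per-SNP instrument strength F = (beta / se)^2.

    Accepts scalars or arrays; se must be strictly positive.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if (se <= 0).any():
        raise ValueError("se must be > 0")
    out = (beta / se) ** 2
    return float(out) if out.ndim == 0 else out


def filter_f(stats: SummaryStats, f_min: float = DEFAULT_F_MIN) -> SummaryStats:
    """Keep SNPs whose strength F = (beta/se)^2 is at least ``f_min``."""
    f = f_statistic(stats.table["beta"].to_numpy(), stats.table["se"].to_numpy())
    return stats.subset(pd.Series(f >= f_min, index=stats.table.index))


def clump(
    stats: SummaryStats,
    ld: LDInfo | None = None,
    r2_max: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_KB,
) -> SummaryStats:
    """Greedy LD clumping.

    Repeatedly take the remaining SNP with the lowest p-value (ties broken by
    lexicographic snp_id, making the result invariant to input row order) as
    an index SNP, then discard every remaining SNP on the same chromosome
    within ``window_kb`` whose r2 with the index is >= ``r2_max``.  With no
    LDInfo the pairwise r2 is taken as 0, so only co-located SNPs at
    ``r2_max <= 0`` would conflict and clumping is effectively
    distance-agnostic; with an LDInfo it prunes correlated neighbours.
    Returns the index SNPs in the original row order of ``stats``.
    """
    df = stats.table
    order = df.sort_values(["pval", "snp_id"], kind="mergesort").index
    window_bp = float(window_kb) * 1000.0

    alive = set(order)
    kept: list = []
    chrom = df["chrom"]
    pos = df["pos"]
    snp = df["snp_id"]
    for idx in order:
        if idx not in alive:
            continue
        kept.append(idx)
        alive.discard(idx)
        if not alive:
            break
        same_chr = [j for j in alive if chrom[j] == chrom[idx]]
        for j in same_chr:
            if abs(float(pos[j]) - float(pos[idx])) <= window_bp:
                r2 = ld.pair_r2(snp[idx], snp[j]) if ld is not None else 0.0
                if r2 >= r2_max:
                    alive.discard(j)
    keep_mask = df.index.isin(kept)
    return stats.subset(pd.Series(keep_mask, index=df.index))


def _is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    return ((a1 == "A") & (a2 == "T")) | ((a1 == "T") & (a2 == "A")) | (
        (a1 == "C") & (a2 == "G")
    ) | ((a1 == "G") & (a2 == "C"))


def harmonize(
    exp: SummaryStats,
    out: SummaryStats,
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW,
    orient_positive: bool = True,
) -> tuple[HarmonizedSet, Counter]:
    """Align outcome effect alleles to the exposure's and join on snp_id.

    Non-palindromic SNPs: a direct allele match (or its strand complement)
    keeps the outcome beta; a swapped match flips its sign and marks the row
    ``flipped``; anything else is dropped and audited.  Palindromic SNPs
    (A/T or C/G) cannot be resolved by alleles: they are kept only when both
    effect-allele frequencies are available, both fall outside
    ``0.5 +/- palindromic_eaf_window``, and agree on which allele is the
    minor one (flipping if they disagree consistently); otherwise dropped.

    With ``orient_positive`` (default) rows are re-oriented afterwards so
    every ``beta_exp`` is non-negative, flipping ``beta_out`` in tandem —
    required for a consistently-signed Egger intercept.

    Raises ``ValueError`` when the join is empty.
    """
    audit: Counter = Counter()
    m = exp.table.merge(out.table, on="snp_id", suffixes=("_exp", "_out"), how="inner")
    if m.empty:
        raise ValueError(
            f"no shared SNPs between {exp.trait_id} and {out.trait_id}"
        )

    ea_x, oa_x = m["effect_allele_exp"], m["other_allele_exp"]
    ea_y, oa_y = m["effect_allele_out"], m["other_allele_out"]
    cea_y = ea_y.map(COMPLEMENT)
    coa_y = oa_y.map(COMPLEMENT)

    palindromic = _is_palindromic(ea_x, oa_x)

    direct = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    comp_direct = (cea_y == ea_x) & (coa_y == oa_x)
    comp_swapped = (cea_y == oa_x) & (coa_y == ea_x)

    keep = pd.Series(False, index=m.index)
    flip = pd.Series(False, index=m.index)

    np_mask = ~palindromic
    keep |= np_mask & (direct | comp_direct)
    flip_np = np_mask & ~(direct | comp_direct) & (swapped | comp_swapped)
    keep |= flip_np
    flip |= flip_np
    n_mismatch = int((np_mask & ~keep).sum())
    if n_mismatch:
        audit["allele_mismatch"] += n_mismatch

    # palindromic: alleles are uninformative; resolve by frequency
    eaf_x = m["eaf_exp"]
    eaf_y = m["eaf_out"]
    lo, hi = 0.5 - palindromic_eaf_window, 0.5 + palindromic_eaf_window
    informative = (
        eaf_x.notna()
        & eaf_y.notna()
        & ((eaf_x < lo) | (eaf_x > hi))
        & ((eaf_y < lo) | (eaf_y > hi))
    )
    same_side = (eaf_x < 0.5) == (eaf_y < 0.5)
    pal_keep = palindromic & informative & same_side
    pal_flip = palindromic & informative & ~same_side
    keep |= pal_keep | pal_flip
    flip |= pal_flip
    n_pal_drop = int((palindromic & ~informative).sum())
    if n_pal_drop:
        audit["palindromic_dropped"] += n_pal_drop

    h = m.loc[keep].copy()
    hflip = flip.loc[keep]
    h["beta_out"] = np.where(hflip, -h["beta_out"], h["beta_out"])
    h["eaf_out"] = np.where(hflip & h["eaf_out"].notna(), 1 - h["eaf_out"], h["eaf_out"])
    h["flipped"] = hflip.to_numpy()
    h["f_stat"] = (h["beta_exp"] / h["se_exp"]) ** 2

    if orient_positive:
        neg = h["beta_exp"] < 0
        h.loc[neg, "beta_out"] = -h.loc[neg, "beta_out"]
        h.loc[neg, "beta_exp"] = -h.loc[neg, "beta_exp"]

    cols = [
        "snp_id",
        "chrom_exp",
        "pos_exp",
        "beta_exp",
        "se_exp",
        "beta_out",
        "se_out",
        "eaf_exp",
        "eaf_out",
        "f_stat",
        "flipped",
    ]
    h = h[cols].rename(columns={"chrom_exp": "chrom", "pos_exp": "pos"})
    return HarmonizedSet(exp.trait_id, out.trait_id, h), audit


def filter_harmonized_f(h: HarmonizedSet, f_min: float = DEFAULT_F_MIN) -> HarmonizedSet:
    """Drop harmonized rows whose instrument strength falls below ``f_min``."""
    keep = h.table["f_stat"] >= f_min
    return HarmonizedSet(h.exposure_id, h.outcome_id, h.table.loc[keep].reset_index(drop=True))
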