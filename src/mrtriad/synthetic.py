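"""Seeded generator of two-sample GWAS summary statistics.

Simulates a ground-truth causal system — exposure -> mediator -> outcome
with optional direct effect, directional pleiotropy for an invalid fraction
of instruments, and equicorrelated LD blocks — and emits per-SNP summary
statistics whose observed betas are the true marginal effects plus sampling
noise at the analytic GWAS standard error for the configured sample sizes.
Continuous traits are on the standardized scale; the binary outcome is on
the log-odds scale with its standard error scaled by case/control
imbalance.

SNPs are split into exposure instruments (optionally part pleiotropic) and
mediator-specific instruments so that each trait in a triple has its own
valid instrument set, matching the two-step MR design the mediation
analysis assumes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import stats as sps

from mrtriad.instruments import LDInfo
from mrtriad.mediation import PathEstimate
from mrtriad.summary_io import SummaryStats

_TINY_P = 1e-300


class SimConfig(BaseModel):
    """Parameters of one simulated exposure/mediator/outcome triple."""

    n_snps: int = Field(100, gt=0, description="total candidate SNPs")
    n_exp: int = Field(20_000, gt=0)
    n_med: int = Field(20_000, gt=0)
    n_out: int = Field(100_000, gt=0)
    h2_exp: float = Field(0.05, gt=0, le=1, description="variance explained by exposure instruments")
    h2_med: float | None = Field(None, description="mediator-specific instrument h2; defaults to h2_exp")
    theta_em: float = 0.0
    theta_mo: float = 0.0
    theta_direct: float = 0.0
    pleio_mean: float = 0.0
    pleio_sd: float = 0.0
    prop_invalid: float = Field(0.0, ge=0, le=1)
    mediator_snp_frac: float = Field(
        0.0, ge=0, lt=1, description="fraction of SNPs reserved as mediator-only instruments"
    )
    ld_block_size: int = Field(1, ge=1)
    ld_r2: float = Field(0.0, ge=0, le=1)
    binary_outcome_prevalence: float = Field(0.1, gt=0, lt=1)
    seed: int

    @model_validator(mode="after")
    def _check(self) -> "SimConfig":
        if self.h2_med is not None and not (0 < self.h2_med <= 1):
            raise ValueError("h2_med must be in (0, 1]")
        if self.ld_block_size > 1 and self.ld_r2 <= 0:
            raise ValueError("ld_block_size > 1 requires ld_r2 > 0")
        return self


@dataclasses.dataclass
class TruthSet:
    """Ground truth serialized beside every generated dataset."""

    table: pd.DataFrame  # snp_id, true_exp, true_med, true_out, pleio, role
    theta_em: float
    theta_mo: float
    theta_direct: float
    invalid_snps: list[str]

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_em * self.theta_mo

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta_em": self.theta_em,
            "theta_mo": self.theta_mo,
            "theta_direct": self.theta_direct,
            "theta_total": self.theta_total,
            "invalid_snps": self.invalid_snps,
            "snps": self.table.to_dict(orient="records"),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def _gwas_se(eaf: np.ndarray, n: int, case_fraction: float | None = None) -> np.ndarray:
    """Analytic standard error of a per-allele GWAS beta.

    Standardized continuous trait: 1 / sqrt(2 p (1-p) n).  Binary trait on
    the log-odds scale: the denominator gains the Bernoulli variance
    v (1 - v) of the case fraction.
    """
    denom = 2 * eaf * (1 - eaf) * n
    if case_fraction is not None:
        denom = denom * case_fraction * (1 - case_fraction)
    return 1.0 / np.sqrt(denom)


def _scale_to_h2(effects: np.ndarray, eaf: np.ndarray, h2: float) -> np.ndarray:
    """Rescale raw effects so the explained variance sums to h2."""
    var = np.sum(2 * eaf * (1 - eaf) * effects**2)
    if var == 0:
        return effects
    return effects * np.sqrt(h2 / var)


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * sps.norm.sf(np.abs(beta / se))
    return np.clip(p, _TINY_P, 1.0)


def _correlated_noise(rng, n_snps: int, block_id: np.ndarray, rho: float) -> np.ndarray:
    """Unit-variance noise equicorrelated at rho within LD blocks."""
    e = rng.standard_normal(n_snps)
    if rho <= 0:
        return e
    n_blocks = int(block_id.max()) + 1
    shared = rng.standard_normal(n_blocks)
    return np.sqrt(rho) * shared[block_id] + np.sqrt(1 - rho) * e


def simulate_triple(
    cfg: SimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, TruthSet, LDInfo | None]:
    """Generate (exposure, mediator, outcome, truth, ld) from one config.

    True per-allele effects: exposure instruments carry effects scaled to
    ``h2_exp``; mediator-only instruments carry effects scaled to ``h2_med``
    on the mediator alone.  Mediator effects add ``theta_em`` times the
    exposure effects; outcome effects are ``theta_direct`` times exposure
    plus ``theta_mo`` times mediator effects plus a pleiotropic shift
    (N(pleio_mean, pleio_sd)) for the invalid fraction of exposure
    instruments.  With LD blocks, one index SNP per block carries the causal
    effect and the rest show the attenuated marginal effect r x index, with
    sampling noise equicorrelated at r = sqrt(ld_r2).

    Regeneration with the same config (same seed) is bit-identical.
    """
    rng = np.random.default_rng(cfg.seed)
    m = cfg.n_snps
    h2_med = cfg.h2_med if cfg.h2_med is not None else cfg.h2_exp

    block = np.arange(m) // cfg.ld_block_size
    n_blocks = int(block.max()) + 1
    is_index = np.zeros(m, dtype=bool)
    is_index[np.searchsorted(block, np.arange(n_blocks))] = True
    r = float(np.sqrt(cfg.ld_r2)) if cfg.ld_block_size > 1 else 0.0

    snp_id = np.array([f"rs{100000 + i}" for i in range(m)])
    chrom = (block % 22 + 1).astype(str)
    # blocks on the same chromosome sit 25 Mb apart; SNPs inside a block 5 kb
    pos = (block // 22) * 25_000_000 + (np.arange(m) - np.searchsorted(block, block)) * 5_000 + 1
    eaf = rng.uniform(0.1, 0.9, m)

    # causal roles are assigned to index SNPs only; proxies inherit r * effect
    index_ids = np.flatnonzero(is_index)
    n_med_idx = int(round(cfg.mediator_snp_frac * len(index_ids)))
    med_idx = index_ids[len(index_ids) - n_med_idx :]
    exp_idx = index_ids[: len(index_ids) - n_med_idx]

    role = np.array(["null"] * m, dtype=object)
    role[exp_idx] = "exposure_iv"
    role[med_idx] = "mediator_iv"

    a = np.zeros(m)  # SNP -> exposure
    a[exp_idx] = rng.standard_normal(len(exp_idx))
    a[exp_idx] = _scale_to_h2(a[exp_idx], eaf[exp_idx], cfg.h2_exp)
    c = np.zeros(m)  # SNP -> mediator (mediator-specific)
    if len(med_idx):
        c[med_idx] = rng.standard_normal(len(med_idx))
        c[med_idx] = _scale_to_h2(c[med_idx], eaf[med_idx], h2_med)

    pleio = np.zeros(m)
    n_invalid = int(round(cfg.prop_invalid * len(exp_idx)))
    invalid = rng.choice(exp_idx, size=n_invalid, replace=False) if n_invalid else np.array([], dtype=int)
    if n_invalid:
        pleio[invalid] = rng.normal(cfg.pleio_mean, cfg.pleio_sd, n_invalid)

    b = cfg.theta_em * a + c  # SNP -> mediator, total
    g = cfg.theta_direct * a + cfg.theta_mo * b + pleio  # SNP -> outcome

    # marginal (observable) effects: proxies attenuated by the LD correlation
    atten = np.where(is_index, 1.0, r)
    true_exp = atten * a[block * cfg.ld_block_size]
    true_med = atten * b[block * cfg.ld_block_size]
    true_out = atten * g[block * cfg.ld_block_size]

    se_exp = _gwas_se(eaf, cfg.n_exp)
    se_med = _gwas_se(eaf, cfg.n_med)
    se_out = _gwas_se(eaf, cfg.n_out, cfg.binary_outcome_prevalence)

    beta_exp = true_exp + se_exp * _correlated_noise(rng, m, block, r)
    beta_med = true_med + se_med * _correlated_noise(rng, m, block, r)
    beta_out = true_out + se_out * _correlated_noise(rng, m, block, r)

    alleles = np.array(["A", "C", "G", "T"])
    ea = alleles[rng.integers(0, 4, m)]
    oa = np.array([rng.choice([x for x in "ACGT" if x != e]) for e in ea])

    def table(beta, se, n):
        return pd.DataFrame(
            {
                "snp_id": snp_id,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": ea,
                "other_allele": oa,
                "eaf": eaf,
                "beta": beta,
                "se": se,
                "pval": _pvals(beta, se),
                "n": float(n),
            }
        )

    exp_stats = SummaryStats("sim_exposure", table(beta_exp, se_exp, cfg.n_exp))
    med_stats = SummaryStats("sim_mediator", table(beta_med, se_med, cfg.n_med))
    out_stats = SummaryStats("sim_outcome", table(beta_out, se_out, cfg.n_out))

    truth = TruthSet(
        table=pd.DataFrame(
            {
                "snp_id": snp_id,
                "role": role,
                "true_exp": true_exp,
                "true_med": true_med,
                "true_out": true_out,
                "pleio": pleio,
            }
        ),
        theta_em=cfg.theta_em,
        theta_mo=cfg.theta_mo,
        theta_direct=cfg.theta_direct,
        invalid_snps=[str(s) for s in snp_id[invalid]],
    )

    ld = None
    if cfg.ld_block_size > 1:
        r2 = np.where(block[:, None] == block[None, :], cfg.ld_r2, 0.0)
        np.fill_diagonal(r2, 1.0)
        ld = LDInfo(list(snp_id), r2)
    return exp_stats, med_stats, out_stats, truth, ld


def make_worked_example() -> dict[str, PathEstimate]:
    """The printed uPA / X-22776 / heart-failure mediation row as a fixture.

    Path coefficients with their published 95% intervals: total effect of
    the exposure on the outcome, exposure-to-mediator, mediator-to-outcome.
    """
    return {
        "beta_all": PathEstimate.from_ci(-0.0704, -0.1247, -0.0161),
        "beta1": PathEstimate.from_ci(0.1162, 0.0305, 0.2020),
        "beta2": PathEstimate.from_ci(0.1020, 0.0271, 0.1769),
    }
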