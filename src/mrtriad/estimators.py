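"""Causal-effect estimators for a harmonized instrument set.

Five methods operating on per-SNP Wald ratios (outcome effect / exposure
effect): inverse-variance-weighted (IVW), Egger regression with a free
intercept, the weighted median, and simple/weighted mode estimates.  IVW is
reported with multiplicative random effects by default (the residual
variance inflation is floored at 1) and is numerically identical to a
zero-intercept weighted least-squares regression of outcome betas on
exposure betas with weights 1/se_out^2.

Confidence intervals use a fixed z of 1.96 throughout; Egger p-values use a
t distribution with J - 2 degrees of freedom, everything else the normal
approximation.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

from mrtriad.instruments import HarmonizedSet

Z95 = 1.96

METHODS = ("ivw", "egger", "weighted_median", "simple_mode", "weighted_mode")


@dataclasses.dataclass
class MREstimate:
    """One estimator's causal effect on the log-odds scale."""

    method: str
    beta: float
    se: float
    pval: float
    n_snps: int
    ci_low: float = dataclasses.field(default=None)  # type: ignore[assignment]
    ci_high: float = dataclasses.field(default=None)  # type: ignore[assignment]
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is None:
            self.ci_low = self.beta - Z95 * self.se
        if self.ci_high is None:
            self.ci_high = self.beta + Z95 * self.se
        if not (0 < self.pval <= 1):
            self.pval = min(max(self.pval, np.nextafter(0, 1)), 1.0)

    def to_row(self) -> dict:
        row = {
            "method": self.method,
            "n_snps": self.n_snps,
            "beta": self.beta,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
        }
        row.update(to_odds_ratio(self))
        if self.intercept is not None:
            row.update(
                intercept=self.intercept,
                intercept_se=self.intercept_se,
                intercept_p=self.intercept_p,
            )
        return row


def ratio_estimates(h: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratios and first-order standard errors.

    wald = beta_out / beta_exp, wald_se = se_out / |beta_exp|.  Rows with
    beta_exp == 0 are dropped (their ratio is undefined) and counted in the
    ``n_dropped`` frame attribute.
    """
    t = h.table
    ok = t["beta_exp"] != 0
    r = pd.DataFrame(
        {
            "snp_id": t.loc[ok, "snp_id"],
            "wald": t.loc[ok, "beta_out"] / t.loc[ok, "beta_exp"],
            "wald_se": t.loc[ok, "se_out"] / t.loc[ok, "beta_exp"].abs(),
        }
    ).reset_index(drop=True)
    r.attrs["n_dropped"] = int((~ok).sum())
    return r


def _ivw_arrays(wald: np.ndarray, wald_se: np.ndarray, random_effects: bool = True):
    """IVW beta/se/Q from ratio arrays.  Returns (beta, se, q)."""
    w = 1.0 / wald_se**2
    beta = float(np.sum(wald * w) / np.sum(w))
    q = float(np.sum(w * (wald - beta) ** 2))
    var_fixed = 1.0 / float(np.sum(w))
    j = len(wald)
    if random_effects and j > 1:
        var = var_fixed * max(1.0, q / (j - 1))
    else:
        var = var_fixed
    return beta, math.sqrt(var), q


def wald_single(h: HarmonizedSet) -> MREstimate:
    """Single-SNP Wald ratio, labelled method='ivw' with n_snps=1.

    Screening has to return an answer for every exposure; after strict
    clumping a single surviving instrument is common, and the Wald ratio is
    the only available estimate.
    """
    r = ratio_estimates(h)
    if len(r) != 1:
        raise ValueError(f"wald_single requires exactly 1 usable SNP, got {len(r)}")
    beta = float(r["wald"].iloc[0])
    se = float(r["wald_se"].iloc[0])
    p = 2 * sps.norm.sf(abs(beta / se))
    return MREstimate("ivw", beta, se, float(p), 1)


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate over >= 2 SNPs.

    Multiplicative random effects by default: se is inflated by
    sqrt(max(1, Q / (J - 1))).  ``random_effects=False`` gives the
    fixed-effect standard error.
    """
    r = ratio_estimates(h)
    if len(r) < 2:
        raise ValueError("ivw requires >= 2 SNPs; use wald_single for 1")
    beta, se, _ = _ivw_arrays(
        r["wald"].to_numpy(), r["wald_se"].to_numpy(), random_effects
    )
    p = 2 * sps.norm.sf(abs(beta / se))
    return MREstimate("ivw", beta, se, float(p), len(r))


def egger(h: HarmonizedSet) -> MREstimate:
    """Egger regression: weighted fit of beta_out on beta_exp with intercept.

    Weights are 1/se_out^2; rows are oriented to beta_exp >= 0 internally.
    The slope estimates the causal effect; a nonzero intercept indicates
    directional pleiotropy.  Standard errors carry the multiplicative
    inflation sqrt(max(1, Q_egger / (J - 2))); p-values are two-sided t with
    J - 2 df.
    """
    t = h.table
    j = len(t)
    if j < 3:
        raise ValueError("egger requires >= 3 SNPs")
    sign = np.where(t["beta_exp"] < 0, -1.0, 1.0)
    x = (t["beta_exp"] * sign).to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("egger requires variation in exposure betas")
    y = (t["beta_out"] * sign).to_numpy(dtype=float)
    w = 1.0 / t["se_out"].to_numpy(dtype=float) ** 2

    X = np.column_stack([np.ones(j), x])
    xtw = X.T * w
    xtwx_inv = np.linalg.inv(xtw @ X)
    coef = xtwx_inv @ (xtw @ y)
    resid = y - X @ coef
    q_egger = float(np.sum(w * resid**2))
    phi = max(1.0, q_egger / (j - 2))
    cov = xtwx_inv * phi
    se_int, se_slope = np.sqrt(np.diag(cov))

    slope_p = 2 * sps.t.sf(abs(coef[1] / se_slope), df=j - 2)
    int_p = 2 * sps.t.sf(abs(coef[0] / se_int), df=j - 2)
    return MREstimate(
        "egger",
        float(coef[1]),
        float(se_slope),
        float(slope_p),
        j,
        intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_p=float(int_p),
    )


def _weighted_median_point(wald: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median of the ratios.

    Sort ratios ascending; with normalized weights w_(j), the cumulative
    position of ratio j is S_j = sum_{i<=j} w_(i) - w_(j)/2.  The estimate
    interpolates linearly between the two order statistics whose positions
    bracket 0.5 (equal weights reduce to the plain interpolated median).
    """
    order = np.argsort(wald, kind="stable")
    b = wald[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    if 0.5 <= s[0]:
        return float(b[0])
    if 0.5 >= s[-1]:
        return float(b[-1])
    k = int(np.searchsorted(s, 0.5, side="right")) - 1
    if s[k] == 0.5:
        return float(b[k])
    frac = (0.5 - s[k]) / (s[k + 1] - s[k])
    return float(b[k] + frac * (b[k + 1] - b[k]))


def _bootstrap_se(point_fn, wald, wald_se, boot_reps, seed) -> float:
    """Parametric bootstrap: redraw each ratio from N(wald, wald_se)."""
    rng = np.random.default_rng(seed)
    draws = rng.normal(wald, wald_se, size=(boot_reps, len(wald)))
    ests = np.array([point_fn(row) for row in draws])
    return float(ests.std(ddof=1))


def weighted_median(
    h: HarmonizedSet, boot_reps: int = 1000, seed: int = 0
) -> MREstimate:
    """Weighted-median estimate, consistent with up to 50% invalid weight.

    Inverse-variance weights on the Wald ratios; the standard error comes
    from a seeded parametric bootstrap of ``boot_reps`` redraws.
    """
    r = ratio_estimates(h)
    if len(r) < 3:
        raise ValueError("weighted_median requires >= 3 SNPs")
    wald = r["wald"].to_numpy()
    wald_se = r["wald_se"].to_numpy()
    weights = 1.0 / wald_se**2
    beta = _weighted_median_point(wald, weights)
    se = _bootstrap_se(
        lambda d: _weighted_median_point(d, weights), wald, wald_se, boot_reps, seed
    )
    p = 2 * sps.norm.sf(abs(beta / se)) if se > 0 else 1.0
    return MREstimate("weighted_median", beta, se, float(p), len(r))


def _mad_scale(x: np.ndarray) -> float:
    """Normal-consistent median absolute deviation (x 1.4826)."""
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def _mode_point(
    wald: np.ndarray,
    weights: np.ndarray,
    bandwidth_factor: float,
    grid_points: int = 512,
) -> float:
    """Argmax of the weighted normal-kernel density of the ratios.

    Bandwidth is ``bandwidth_factor`` times the modified-MAD scale of the
    ratios shrunk by J^(-1/5); the density is evaluated on ``grid_points``
    equally spaced points spanning the ratios plus 3 bandwidths each side.
    All ratios identical (zero bandwidth) returns the common value.
    """
    j = len(wald)
    s = _mad_scale(wald)
    bw = bandwidth_factor * 0.9 * s * j ** (-1 / 5)
    if bw <= 0:
        return float(wald[0])
    grid = np.linspace(wald.min() - 3 * bw, wald.max() + 3 * bw, grid_points)
    dens = kernel_density(grid, wald, weights, bw)
    return float(grid[int(np.argmax(dens))])


def kernel_density(
    grid: np.ndarray, wald: np.ndarray, weights: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Weighted normal-kernel density of ``wald`` evaluated on ``grid``."""
    z = (grid[:, None] - wald[None, :]) / bandwidth
    k = np.exp(-0.5 * z**2)
    wn = weights / weights.sum()
    return (k * wn[None, :]).sum(axis=1) / (bandwidth * math.sqrt(2 * math.pi))


def mode_estimate(
    h: HarmonizedSet,
    weighted: bool = True,
    bandwidth_factor: float = 1.0,
    boot_reps: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimate (simple when ``weighted=False``).

    Consistent when the largest group of instruments sharing a ratio is
    valid (plurality validity).  Bootstrap se as in the weighted median.
    """
    r = ratio_estimates(h)
    if len(r) < 3:
        raise ValueError("mode_estimate requires >= 3 SNPs")
    wald = r["wald"].to_numpy()
    wald_se = r["wald_se"].to_numpy()
    weights = 1.0 / wald_se**2 if weighted else np.ones(len(wald))
    beta = _mode_point(wald, weights, bandwidth_factor)
    se = _bootstrap_se(
        lambda d: _mode_point(d, weights, bandwidth_factor),
        wald,
        wald_se,
        boot_reps,
        seed,
    )
    p = 2 * sps.norm.sf(abs(beta / se)) if se > 0 else 1.0
    method = "weighted_mode" if weighted else "simple_mode"
    return MREstimate(method, beta, se, float(p), len(r))


def to_odds_ratio(e: MREstimate) -> dict:
    """OR = exp(beta) with 95% bounds exp(beta -/+ 1.96 se)."""
    return {
        "or": math.exp(e.beta),
        "or_low": math.exp(e.beta - Z95 * e.se),
        "or_high": math.exp(e.beta + Z95 * e.se),
    }


def all_estimates(
    h: HarmonizedSet, boot_reps: int = 1000, seed: int = 0
) -> list[MREstimate]:
    """Run whichever of the five estimators the SNP count supports."""
    j = len(ratio_estimates(h))
    if j == 0:
        return []
    if j == 1:
        return [wald_single(h)]
    out = [ivw(h)]
    if j >= 3:
        out.append(egger(h))
        out.append(weighted_median(h, boot_reps=boot_reps, seed=seed))
        out.append(mode_estimate(h, weighted=False, boot_reps=boot_reps, seed=seed + 1))
        out.append(mode_estimate(h, weighted=True, boot_reps=boot_reps, seed=seed + 2))
    return out


def estimates_table(estimates: list[MREstimate]) -> pd.DataFrame:
    """Stack MREstimate rows into the per-pair report table."""
    return pd.DataFrame([e.to_row() for e in estimates])
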