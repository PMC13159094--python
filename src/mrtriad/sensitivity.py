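"""Heterogeneity, pleiotropy, outlier, and influence diagnostics.

Cochran's Q on the Wald ratios, the Egger intercept test, a
simulation-based outlier procedure with global / per-SNP / distortion
tests, and leave-one-out influence of each instrument on the IVW estimate.
Diagnostics "pass" when their p-value exceeds alpha (no detected
heterogeneity / pleiotropy).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats as sps

from mrtriad.estimators import _ivw_arrays, egger, ratio_estimates
from mrtriad.instruments import HarmonizedSet

DEFAULT_N_SIM = 1000
DEFAULT_OUTLIER_ALPHA = 0.05
PASS_ALPHA = 0.05


@dataclasses.dataclass
class SensitivityReport:
    """Per exposure-outcome pair diagnostic bundle."""

    q_stat: float
    q_df: int
    q_pval: float
    egger_intercept: float | None
    egger_intercept_p: float | None
    presso_global_p: float | None
    presso_outliers: list[str]
    presso_distortion_p: float | None
    loo: pd.DataFrame
    alpha: float = PASS_ALPHA

    @property
    def heterogeneity_pass(self) -> bool:
        return self.q_pval > self.alpha

    @property
    def pleiotropy_pass(self) -> bool | None:
        if self.egger_intercept_p is None:
            return None
        return self.egger_intercept_p > self.alpha

    def to_row(self) -> dict:
        return {
            "q_stat": self.q_stat,
            "q_df": self.q_df,
            "q_pval": self.q_pval,
            "heterogeneity_pass": self.heterogeneity_pass,
            "egger_intercept": self.egger_intercept,
            "egger_intercept_p": self.egger_intercept_p,
            "pleiotropy_pass": self.pleiotropy_pass,
            "presso_global_p": self.presso_global_p,
            "presso_outliers": ",".join(self.presso_outliers),
            "presso_distortion_p": self.presso_distortion_p,
        }


def cochran_q(h: HarmonizedSet) -> dict:
    """Cochran's Q against the fixed-effect IVW estimate.

    Q = sum_j w_j (wald_j - beta_fixed)^2 with w_j = 1/wald_se_j^2;
    p from chi-square with J - 1 degrees of freedom.
    """
    r = ratio_estimates(h)
    j = len(r)
    if j < 2:
        raise ValueError("cochran_q requires >= 2 SNPs")
    _, _, q = _ivw_arrays(r["wald"].to_numpy(), r["wald_se"].to_numpy())
    return {"q_stat": q, "q_df": j - 1, "q_pval": float(sps.chi2.sf(q, j - 1))}


def leave_one_out(h: HarmonizedSet) -> pd.DataFrame:
    """IVW estimate with each SNP removed in turn (one row per SNP)."""
    r = ratio_estimates(h)
    j = len(r)
    if j < 3:
        raise ValueError("leave_one_out requires >= 3 SNPs")
    wald = r["wald"].to_numpy()
    wald_se = r["wald_se"].to_numpy()
    rows = []
    for k in range(j):
        keep = np.arange(j) != k
        beta, se, _ = _ivw_arrays(wald[keep], wald_se[keep])
        rows.append({"left_out_snp": r["snp_id"].iloc[k], "beta": beta, "se": se})
    return pd.DataFrame(rows)


def _loo_slopes(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Zero-intercept WLS slope of y on x with SNP j removed, for all j.

    Vectorized over rows when y is 2-D (simulations x SNPs).
    """
    sxx = np.sum(w * x * x)
    sxy = (w * x * y).sum(axis=-1, keepdims=True)
    loo_sxx = sxx - w * x * x
    loo_sxy = sxy - w * x * y
    return loo_sxy / loo_sxx


def presso(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
) -> dict:
    """Simulation-based pleiotropy outlier test (global, outlier, distortion).

    Observed statistic: each SNP's outcome beta is predicted from the
    leave-one-out zero-intercept WLS slope times its exposure beta; the
    global statistic is the 1/se_out^2-weighted residual sum of squares.
    The null distribution comes from ``n_sim`` parametric redraws of each
    outcome beta around its leave-one-out prediction; the global p is the
    (add-one smoothed) fraction of simulated RSS at least as large as
    observed.  Per-SNP outlier p-values compare each observed squared
    residual to its own simulated distribution, Bonferroni-corrected at
    ``outlier_alpha``.  When outliers are found, the distortion p compares
    the estimate shift after removing them against the shift from removing
    equally many random SNPs.

    Fewer than 4 SNPs: the test is unavailable (all keys None).
    """
    if n_sim <= 0:
        raise ValueError("n_sim must be positive")
    t = h.table
    j = len(t)
    if j < 4:
        return {
            "presso_global_p": None,
            "presso_outliers": [],
            "presso_distortion_p": None,
        }
    rng = np.random.default_rng(seed)
    x = t["beta_exp"].to_numpy(dtype=float)
    y = t["beta_out"].to_numpy(dtype=float)
    se = t["se_out"].to_numpy(dtype=float)
    w = 1.0 / se**2

    loo_obs = _loo_slopes(x, y[None, :], w)[0]
    resid_obs = y - loo_obs * x
    rss_obs_terms = w * resid_obs**2
    rss_obs = float(rss_obs_terms.sum())

    y_sim = rng.normal(loo_obs * x, se, size=(n_sim, j))
    loo_sim = _loo_slopes(x, y_sim, w)
    resid_sim = y_sim - loo_sim * x
    rss_sim_terms = w * resid_sim**2
    rss_sim = rss_sim_terms.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    p_snp = (1 + (rss_sim_terms >= rss_obs_terms[None, :]).sum(axis=0)) / (n_sim + 1)
    outlier_mask = p_snp * j < outlier_alpha
    outliers = list(t.loc[outlier_mask, "snp_id"])

    distortion_p = None
    if outliers and outlier_mask.sum() < j - 1:
        beta_full = float(np.sum(w * x * y) / np.sum(w * x * x))
        keep = ~outlier_mask
        beta_noout = float(
            np.sum(w[keep] * x[keep] * y[keep]) / np.sum(w[keep] * x[keep] * x[keep])
        )
        d_obs = beta_noout - beta_full
        n_out = int(outlier_mask.sum())
        d_null = np.empty(n_sim)
        idx = np.arange(j)
        for i in range(n_sim):
            drop = rng.choice(idx, size=n_out, replace=False)
            keep_i = np.setdiff1d(idx, drop)
            d_null[i] = (
                np.sum(w[keep_i] * x[keep_i] * y[keep_i])
                / np.sum(w[keep_i] * x[keep_i] * x[keep_i])
                - beta_full
            )
        distortion_p = float((1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sim + 1))

    return {
        "presso_global_p": global_p,
        "presso_outliers": outliers,
        "presso_distortion_p": distortion_p,
    }


def sensitivity_report(
    h: HarmonizedSet,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
    outlier_alpha: float = DEFAULT_OUTLIER_ALPHA,
    alpha: float = PASS_ALPHA,
) -> SensitivityReport:
    """Assemble the full diagnostic bundle for one exposure-outcome pair."""
    q = cochran_q(h)
    if h.n_snps >= 3:
        e = egger(h)
        intercept, intercept_p = e.intercept, e.intercept_p
        loo = leave_one_out(h)
    else:
        intercept = intercept_p = None
        loo = pd.DataFrame(columns=["left_out_snp", "beta", "se"])
    pr = presso(h, n_sim=n_sim, seed=seed, outlier_alpha=outlier_alpha)
    return SensitivityReport(
        q_stat=q["q_stat"],
        q_df=q["q_df"],
        q_pval=q["q_pval"],
        egger_intercept=intercept,
        egger_intercept_p=intercept_p,
        presso_global_p=pr["presso_global_p"],
        presso_outliers=pr["presso_outliers"],
        presso_distortion_p=pr["presso_distortion_p"],
        loo=loo,
        alpha=alpha,
    )
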