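import numpy as np
import pandas as pd
import pytest

from mrtriad.instruments import HarmonizedSet
from mrtriad.summary_io import SummaryStats


def make_stats(trait_id="trait", **cols):
    """Build a SummaryStats from column overrides on a 5-row template."""
    n = len(next(iter(cols.values()))) if cols else 5
    base = {
        "snp_id": [f"rs{i}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": list(range(1_000_000, 1_000_000 + n * 100_000, 100_000)),
        "effect_allele": ["A"] * n,
        "other_allele": ["G"] * n,
        "eaf": [0.3] * n,
        "beta": [0.1] * n,
        "se": [0.01] * n,
        "pval": [1e-8] * n,
        "n": [10_000.0] * n,
    }
    base.update(cols)
    return SummaryStats(trait_id, pd.DataFrame(base))


def make_harmonized(wald, wald_se, beta_exp=None, exposure="exp", outcome="out"):
    """HarmonizedSet with prescribed Wald ratios.

    beta_exp defaults to 1 so that beta_out equals the ratio and se_out the
    ratio se.
    """
    wald = np.asarray(wald, dtype=float)
    wald_se = np.asarray(wald_se, dtype=float)
    bx = np.ones_like(wald) if beta_exp is None else np.asarray(beta_exp, dtype=float)
    t = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(len(wald))],
            "beta_exp": bx,
            "se_exp": np.full_like(wald, 0.01),
            "beta_out": wald * bx,
            "se_out": wald_se * np.abs(bx),
            "f_stat": (bx / 0.01) ** 2,
            "flipped": False,
        }
    )
    return HarmonizedSet(exposure, outcome, t)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_harmonized():
    """10 SNPs, homogeneous true ratio 0.1 plus mild noise."""
    gen = np.random.default_rng(7)
    bx = gen.uniform(0.1, 0.4, 10)
    wald_se = gen.uniform(0.02, 0.05, 10)
    wald = 0.1 + gen.normal(0, wald_se)
    return make_harmonized(wald, wald_se, beta_exp=bx)
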