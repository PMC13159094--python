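"""Product-of-coefficients mediation on three MR path estimates.

Given the total effect of the exposure on the outcome (beta_all), the
exposure-to-mediator effect (beta1) and the mediator-to-outcome effect
(beta2), the indirect effect is beta1 * beta2 with a delta-method standard
error, the direct effect is beta_all minus the indirect effect, and the
mediated proportion is indirect / total.  A negative proportion is reported
as-is and flagged as inconsistent mediation (indirect path opposing the
total effect), never clamped.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats as sps

Z95 = 1.96


@dataclasses.dataclass(frozen=True)
class PathEstimate:
    """One path coefficient with its standard error."""

    beta: float
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("path estimate se must be > 0")

    @classmethod
    def from_ci(cls, beta: float, ci_low: float, ci_high: float) -> "PathEstimate":
        """Recover the se from a symmetric 95% interval."""
        return cls(beta, (ci_high - ci_low) / (2 * Z95))

    @property
    def ci(self) -> tuple[float, float]:
        return (self.beta - Z95 * self.se, self.beta + Z95 * self.se)


@dataclasses.dataclass
class MediationResult:
    """One mediation triple: the row layout of the mediation report table."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta_all: PathEstimate
    beta1: PathEstimate
    beta2: PathEstimate
    indirect: float
    indirect_se: float
    indirect_ci: tuple[float, float]
    sobel_p: float
    direct: float
    proportion: float | None
    proportion_se: float | None
    proportion_ci: tuple[float, float] | None
    inconsistent: bool
    ci_method: str

    def to_row(self) -> dict:
        row = {
            "exposure": self.exposure_id,
            "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta.1": round(self.beta1.beta, 4),
            "beta.1_ci_low": round(self.beta1.ci[0], 4),
            "beta.1_ci_high": round(self.beta1.ci[1], 4),
            "beta.2": round(self.beta2.beta, 4),
            "beta.2_ci_low": round(self.beta2.ci[0], 4),
            "beta.2_ci_high": round(self.beta2.ci[1], 4),
            "beta.all": round(self.beta_all.beta, 4),
            "beta.all_ci_low": round(self.beta_all.ci[0], 4),
            "beta.all_ci_high": round(self.beta_all.ci[1], 4),
            "mediated_effect": round(self.indirect, 4),
            "mediated_effect_ci_low": round(self.indirect_ci[0], 4),
            "mediated_effect_ci_high": round(self.indirect_ci[1], 4),
            "sobel_p": self.sobel_p,
            "direct_effect": round(self.direct, 4),
            "inconsistent_mediation": self.inconsistent,
        }
        if self.proportion is not None:
            row["mediated_proportion_pct"] = round(100 * self.proportion, 1)
            row["mediated_proportion_ci_low_pct"] = round(100 * self.proportion_ci[0], 1)
            row["mediated_proportion_ci_high_pct"] = round(100 * self.proportion_ci[1], 1)
        else:
            row["mediated_proportion_pct"] = None
            row["mediated_proportion_ci_low_pct"] = None
            row["mediated_proportion_ci_high_pct"] = None
        return row


def mediate(
    beta_all: PathEstimate,
    beta1: PathEstimate,
    beta2: PathEstimate,
    ci_method: str = "delta",
    second_order: bool = False,
    boot_reps: int = 5000,
    seed: int = 0,
    exposure_id: str = "exposure",
    mediator_id: str = "mediator",
    outcome_id: str = "outcome",
) -> MediationResult:
    """Product-of-coefficients mediation with delta / Sobel / bootstrap CIs.

    indirect = beta1 * beta2 exactly; direct = beta_all - indirect;
    proportion = indirect / beta_all (undefined, not an error, when
    beta_all is 0).

    ``delta`` and ``sobel`` both use the first-order variance
    beta1^2 se2^2 + beta2^2 se1^2 (``second_order=True`` adds se1^2 se2^2)
    with a 1.96-z interval; ``bootstrap`` draws the three betas from
    independent normals and takes percentile bounds for the indirect effect
    and proportion.  The Sobel z-test p-value is always reported.

    The proportion interval treats indirect and total as independent — a
    documented approximation, since the shared exposure instruments
    correlate them in truth.
    """
    if ci_method not in ("delta", "sobel", "bootstrap"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    indirect = beta1.beta * beta2.beta
    var1 = beta1.beta**2 * beta2.se**2 + beta2.beta**2 * beta1.se**2
    if second_order:
        var1 += beta1.se**2 * beta2.se**2
    indirect_se = math.sqrt(var1)
    sobel_p = 2 * sps.norm.sf(abs(indirect / indirect_se)) if indirect_se > 0 else 1.0

    direct = beta_all.beta - indirect

    if beta_all.beta != 0:
        proportion = indirect / beta_all.beta
        # delta expansion of a ratio with independent numerator/denominator
        prop_var = (
            indirect_se**2 / beta_all.beta**2
            + indirect**2 * beta_all.se**2 / beta_all.beta**4
        )
        proportion_se = math.sqrt(prop_var)
    else:
        proportion = proportion_se = None

    if ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        b1 = rng.normal(beta1.beta, beta1.se, boot_reps)
        b2 = rng.normal(beta2.beta, beta2.se, boot_reps)
        ball = rng.normal(beta_all.beta, beta_all.se, boot_reps)
        ind = b1 * b2
        indirect_ci = tuple(np.percentile(ind, [2.5, 97.5]))
        if proportion is not None:
            prop = ind / ball
            proportion_ci = tuple(np.percentile(prop, [2.5, 97.5]))
        else:
            proportion_ci = None
    else:
        indirect_ci = (indirect - Z95 * indirect_se, indirect + Z95 * indirect_se)
        if proportion is not None:
            proportion_ci = (
                proportion - Z95 * proportion_se,
                proportion + Z95 * proportion_se,
            )
        else:
            proportion_ci = None

    inconsistent = proportion is not None and proportion < 0

    return MediationResult(
        exposure_id=exposure_id,
        mediator_id=mediator_id,
        outcome_id=outcome_id,
        beta_all=beta_all,
        beta1=beta1,
        beta2=beta2,
        indirect=indirect,
        indirect_se=indirect_se,
        indirect_ci=indirect_ci,
        sobel_p=float(sobel_p),
        direct=direct,
        proportion=proportion,
        proportion_se=proportion_se,
        proportion_ci=proportion_ci,
        inconsistent=inconsistent,
        ci_method=ci_method,
    )


def extract_path_betas(
    exposure_outcome,
    exposure_mediator,
    mediator_outcome,
    method: str = "ivw",
) -> tuple[PathEstimate, PathEstimate, PathEstimate]:
    """Pull (beta_all, beta1, beta2) for one estimator from three tables.

    Each argument is an estimates table (as written per pair) with
    ``method``, ``beta`` and ``se`` columns.  Raises ``KeyError`` naming the
    path when the requested method is absent from any of them.
    """
    paths = {
        "exposure->outcome": exposure_outcome,
        "exposure->mediator": exposure_mediator,
        "mediator->outcome": mediator_outcome,
    }
    out = {}
    for name, table in paths.items():
        match = table.loc[table["method"] == method]
        if match.empty:
            raise KeyError(f"method {method!r} missing from {name} estimates")
        out[name] = PathEstimate(
            float(match["beta"].iloc[0]), float(match["se"].iloc[0])
        )
    return out["exposure->outcome"], out["exposure->mediator"], out["mediator->outcome"]
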