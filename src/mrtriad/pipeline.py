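"""Three-step screening orchestration.

Step 1: forward MR of every exposure on the outcome (IVW primary, the
other four methods reported without gating).  Reverse MR of the outcome on
the screened exposures excludes reverse-causal hits.  Step 2: the same
screen of mediators on the outcome at a stricter alpha.  Step 3: for each
surviving exposure and significant mediator, an exposure-to-mediator MR
gates assembly of the mediation triple and the product-of-coefficients
decomposition.

Every run is deterministic given its config (all seeds and thresholds are
recorded in the JSON manifest) and every report number is re-derivable
from the per-stage TSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field

from mrtriad import summary_io
from mrtriad.estimators import all_estimates, estimates_table
from mrtriad.instruments import (
    DEFAULT_CLUMP_KB,
    DEFAULT_CLUMP_R2,
    DEFAULT_F_MIN,
    DEFAULT_P_THRESHOLD,
    DEFAULT_PALINDROMIC_EAF_WINDOW,
    HarmonizedSet,
    LDInfo,
    clump,
    filter_f,
    harmonize,
    select_instruments,
)
from mrtriad.mediation import MediationResult, extract_path_betas, mediate
from mrtriad.sensitivity import sensitivity_report
from mrtriad.summary_io import SummaryStats


class ScreenConfig(BaseModel):
    """Thresholds and seeds for one screening run."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    clump_r2: float = DEFAULT_CLUMP_R2
    clump_kb: float = DEFAULT_CLUMP_KB
    f_min: float = DEFAULT_F_MIN
    palindromic_eaf_window: float = DEFAULT_PALINDROMIC_EAF_WINDOW
    alpha_stage1: float = Field(0.05, gt=0, lt=1)
    alpha_mediators: float = Field(0.01, gt=0, lt=1)
    alpha_reverse: float = Field(0.05, gt=0, lt=1)
    alpha_link: float = Field(0.05, gt=0, lt=1, description="exposure->mediator gate")
    boot_reps: int = 1000
    presso_n_sim: int = 1000
    run_sensitivity: bool = True
    multiple_testing: str = Field("none", pattern="^(none|bonferroni|fdr)$")
    seed: int = 0


@dataclasses.dataclass
class PairResult:
    """One exposure-outcome MR with its diagnostics."""

    exposure_id: str
    outcome_id: str
    status: str  # ok | no_instruments | single_snp
    harmonized: HarmonizedSet | None
    estimates: pd.DataFrame | None
    sensitivity: object | None

    def primary(self) -> pd.Series | None:
        """The IVW row (the primary analytical method)."""
        if self.estimates is None:
            return None
        ivw_rows = self.estimates.loc[self.estimates["method"] == "ivw"]
        return ivw_rows.iloc[0] if len(ivw_rows) else None


def prepare_instruments(
    exp: SummaryStats,
    out: SummaryStats,
    cfg: ScreenConfig,
    ld: LDInfo | None = None,
) -> HarmonizedSet | None:
    """p-threshold -> F filter -> clumping -> harmonization.

    Returns None when no instrument survives or no SNP is shared with the
    outcome table.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sel = select_instruments(exp, cfg.p_threshold)
    if sel.n_snps == 0:
        return None
    sel = filter_f(sel, cfg.f_min)
    if sel.n_snps == 0:
        return None
    sel = clump(sel, ld=ld, r2_max=cfg.clump_r2, window_kb=cfg.clump_kb)
    try:
        h, _ = harmonize(sel, out, cfg.palindromic_eaf_window)
    except ValueError:
        return None
    return h if h.n_snps > 0 else None


def analyze_pair(
    exp: SummaryStats,
    out: SummaryStats,
    cfg: ScreenConfig,
    ld: LDInfo | None = None,
    sensitivity: bool | None = None,
) -> PairResult:
    """Full single-pair MR: instruments, all estimators, diagnostics."""
    h = prepare_instruments(exp, out, cfg, ld)
    if h is None:
        return PairResult(exp.trait_id, out.trait_id, "no_instruments", None, None, None)
    ests = all_estimates(h, boot_reps=cfg.boot_reps, seed=cfg.seed)
    if not ests:
        return PairResult(exp.trait_id, out.trait_id, "no_instruments", h, None, None)
    table = estimates_table(ests)
    status = "single_snp" if h.n_snps == 1 else "ok"
    sens = None
    run_sens = cfg.run_sensitivity if sensitivity is None else sensitivity
    if run_sens and h.n_snps >= 2:
        sens = sensitivity_report(h, n_sim=cfg.presso_n_sim, seed=cfg.seed)
    return PairResult(exp.trait_id, out.trait_id, status, h, table, sens)


def _adjust(pvals: pd.Series, how: str) -> pd.Series:
    if how == "none":
        return pvals
    from statsmodels.stats.multitest import multipletests

    method = {"bonferroni": "bonferroni", "fdr": "fdr_bh"}[how]
    ok = pvals.notna()
    adj = pvals.copy()
    adj.loc[ok] = multipletests(pvals[ok], method=method)[1]
    return adj


def screen_exposures(
    exposures: list[SummaryStats],
    outcome: SummaryStats,
    cfg: ScreenConfig,
    alpha: float | None = None,
    ld: LDInfo | None = None,
) -> tuple[pd.DataFrame, dict[str, PairResult]]:
    """MR of every exposure on the outcome, ranked by IVW p then id.

    Exposures yielding no usable instruments are kept with their status
    rather than dropped.  ``alpha`` defaults to ``cfg.alpha_stage1``.
    Returns the ranking table and the per-exposure PairResult details.
    """
    if not exposures:
        raise ValueError("empty exposure list")
    alpha = cfg.alpha_stage1 if alpha is None else alpha
    rows = []
    details: dict[str, PairResult] = {}
    for exp in exposures:
        pr = analyze_pair(exp, outcome, cfg, ld)
        details[exp.trait_id] = pr
        row: dict = {"exposure": exp.trait_id, "status": pr.status}
        primary = pr.primary()
        if primary is not None:
            row.update(
                n_snps=int(primary["n_snps"]),
                beta=primary["beta"],
                se=primary["se"],
                pval=primary["pval"],
                odds_ratio=primary["or"],
                or_low=primary["or_low"],
                or_high=primary["or_high"],
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    if "pval" not in table.columns:
        table["pval"] = float("nan")
    table["pval_adj"] = _adjust(table["pval"], cfg.multiple_testing)
    table["significant"] = table["pval_adj"] < alpha
    table = table.sort_values(
        ["pval", "exposure"], na_position="last", kind="mergesort"
    ).reset_index(drop=True)
    return table, details


def reverse_mr(
    outcome_as_exposure: SummaryStats,
    targets: list[SummaryStats],
    cfg: ScreenConfig,
    alpha: float | None = None,
    ld: LDInfo | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """IVW of the outcome on each target; significant targets are excluded.

    Instrument selection applies the same thresholds to the outcome GWAS.
    Returns the per-target table and the exclusion list.
    """
    alpha = cfg.alpha_reverse if alpha is None else alpha
    rows = []
    excluded: list[str] = []
    for target in targets:
        pr = analyze_pair(outcome_as_exposure, target, cfg, ld, sensitivity=False)
        primary = pr.primary()
        row = {"target": target.trait_id, "status": pr.status}
        if primary is not None:
            row.update(beta=primary["beta"], se=primary["se"], pval=primary["pval"])
            if primary["pval"] < alpha:
                excluded.append(target.trait_id)
        row["excluded"] = row.get("pval", float("nan")) < alpha
        rows.append(row)
    return pd.DataFrame(rows), excluded


def find_mediations(
    exposures: list[SummaryStats],
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    cfg: ScreenConfig,
    exposure_details: dict[str, PairResult] | None = None,
    mediator_details: dict[str, PairResult] | None = None,
    ld: LDInfo | None = None,
) -> tuple[pd.DataFrame, list[MediationResult]]:
    """Assemble mediation triples for every linked exposure-mediator pair.

    For each pair where the exposure-to-mediator IVW is significant at
    ``cfg.alpha_link``, the three path estimates (total, exposure->mediator,
    mediator->outcome) feed the product-of-coefficients decomposition.
    Pre-screened PairResult caches may be passed to avoid refitting the
    exposure->outcome and mediator->outcome paths.
    """
    exposure_details = exposure_details or {}
    mediator_details = mediator_details or {}
    results: list[MediationResult] = []
    rows = []
    for exp in exposures:
        eo = exposure_details.get(exp.trait_id) or analyze_pair(
            exp, outcome, cfg, ld, sensitivity=False
        )
        if eo.estimates is None:
            continue
        for med in mediators:
            if med.trait_id == exp.trait_id:
                continue  # self-pairs are meaningless as mediation
            em = analyze_pair(exp, med, cfg, ld, sensitivity=False)
            em_primary = em.primary()
            if em_primary is None or not em_primary["pval"] < cfg.alpha_link:
                continue
            mo = mediator_details.get(med.trait_id) or analyze_pair(
                med, outcome, cfg, ld, sensitivity=False
            )
            if mo.estimates is None:
                continue
            beta_all, beta1, beta2 = extract_path_betas(
                eo.estimates, em.estimates, mo.estimates
            )
            res = mediate(
                beta_all,
                beta1,
                beta2,
                seed=cfg.seed,
                exposure_id=exp.trait_id,
                mediator_id=med.trait_id,
                outcome_id=outcome.trait_id,
            )
            results.append(res)
            rows.append(res.to_row())
    table = pd.DataFrame(rows)
    return table, results


def run_all(
    exposures: list[SummaryStats],
    mediators: list[SummaryStats],
    outcome: SummaryStats,
    cfg: ScreenConfig,
    outdir: str | Path,
    ld: LDInfo | None = None,
    input_paths: list[str] | None = None,
) -> dict:
    """Full three-step run writing per-stage TSVs and a JSON manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage1, exp_details = screen_exposures(exposures, outcome, cfg)
    summary_io.write_results(stage1, outdir / "stage1_exposures.tsv")

    surviving_ids = list(stage1.loc[stage1["significant"], "exposure"])
    reverse_targets = [e for e in exposures if e.trait_id in surviving_ids]
    reverse_table, excluded = (pd.DataFrame(), [])
    if reverse_targets:
        reverse_table, excluded = reverse_mr(outcome, reverse_targets, cfg)
        summary_io.write_results(reverse_table, outdir / "reverse_mr.tsv")
    surviving = [e for e in exposures if e.trait_id in surviving_ids and e.trait_id not in excluded]

    stage2, med_details = screen_exposures(mediators, outcome, cfg, alpha=cfg.alpha_mediators)
    summary_io.write_results(stage2, outdir / "stage2_mediators.tsv")
    significant_meds = [
        m for m in mediators if m.trait_id in set(stage2.loc[stage2["significant"], "exposure"])
    ]

    mediation_table, mediation_results = find_mediations(
        surviving, significant_meds, outcome, cfg, exp_details, med_details
    )
    if len(mediation_table):
        summary_io.write_results(mediation_table, outdir / "mediation.tsv")

    sens_rows = [
        {"exposure": eid, **pr.sensitivity.to_row()}
        for eid, pr in exp_details.items()
        if pr.sensitivity is not None
    ]
    if sens_rows:
        summary_io.write_results(pd.DataFrame(sens_rows), outdir / "sensitivity.tsv")

    manifest = {
        "config": cfg.model_dump(),
        "n_exposures": len(exposures),
        "n_mediators": len(mediators),
        "outcome": outcome.trait_id,
        "surviving_exposures": [e.trait_id for e in surviving],
        "reverse_excluded": excluded,
        "significant_mediators": [m.trait_id for m in significant_meds],
        "n_mediation_triples": len(mediation_results),
        "input_digests": {
            p: hashlib.sha256(Path(p).read_bytes()).hexdigest() for p in (input_paths or [])
        },
    }
    summary_io.write_manifest(manifest, outdir / "manifest.json")
    return manifest
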