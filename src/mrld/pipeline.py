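"""End-to-end analysis: load -> QC -> harmonize -> select -> estimate -> report.

For each outcome dataset the pipeline harmonizes against the exposure and LD
inputs, re-selects instruments independently (variant availability differs
between outcomes), fits the correlated-IVW estimator — falling back to PC
stabilization when the outcome covariance is numerically singular — and
flags significance against a Bonferroni-corrected threshold over the
configured number of outcome families.  Cohorts carrying the same outcome
can be pooled by fixed-effect meta-analysis.

Every dropped variant and every fallback decision is logged with stage and
reason, so the exact variant set behind each estimate is auditable.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from . import estimators, qc, selection, summary_io

logger = logging.getLogger(__name__)


@dataclass
class OutcomeSpec:
    """One outcome summary-statistics file plus its labels."""

    path: str
    trait_scale: str = "log_odds"
    sex_stratum: str = "all"
    cohort: str = "cohort1"
    name: str | None = None


@dataclass
class AnalysisConfig:
    exposure_path: str = ""
    outcomes: list[OutcomeSpec] = field(default_factory=list)
    ld_path: str = ""
    region: str = "region1"
    selection: selection.SelectionConfig = field(
        default_factory=selection.SelectionConfig)
    estimator: str = "auto"  # "auto" | "ivw_correlated" | "pc_ivw"
    pc_variance: float = 0.99
    alpha: float = 0.05
    n_outcome_families: int = 7
    combine: list[str] = field(default_factory=list)
    counts_path: str | None = None
    confounders_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_outcome_families < 1:
            raise ValueError("n_outcome_families must be >= 1")
        if self.estimator not in ("auto", "ivw_correlated", "pc_ivw"):
            raise ValueError(f"unknown estimator {self.estimator!r}")


@dataclass
class ReportRow:
    outcome: str
    stratum: str
    cohort: str
    region: str
    method: str
    n_variants: int
    estimate: float | None
    se: float | None
    p: float | None
    or_point: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    significance: str = "none"  # "none" | "nominal" | "corrected"
    error: str | None = None


def flag_significance(p: float, alpha: float, n_families: int) -> str:
    """'corrected' if p < alpha/n_families, else 'nominal' if p < alpha."""
    threshold = qc.bonferroni_threshold(alpha, n_families)
    if p < threshold:
        return "corrected"
    if p < alpha:
        return "nominal"
    return "none"


def _estimate(h, config: AnalysisConfig) -> estimators.MREstimate:
    if config.estimator == "pc_ivw":
        return estimators.pc_ivw(h, variance_kept=config.pc_variance)
    try:
        if len(h) == 1:
            return estimators.wald_ratio(
                h.beta_exposure[0], h.beta_outcome[0], h.se_outcome[0])
        return estimators.ivw_correlated(h)
    except estimators.ConditionNumberError:
        if config.estimator == "ivw_correlated":
            raise
        est = estimators.pc_ivw(h, variance_kept=config.pc_variance)
        logger.info("estimator fallback to pc_ivw (k=%s components)", est.pc_k)
        return est


def _row_from_estimate(est, spec: OutcomeSpec, config: AnalysisConfig) -> ReportRow:
    row = ReportRow(
        outcome=spec.name or spec.path,
        stratum=spec.sex_stratum,
        cohort=spec.cohort,
        region=config.region,
        method=est.method,
        n_variants=est.n_variants,
        estimate=est.theta,
        se=est.se_theta,
        p=est.pvalue,
        significance=flag_significance(est.pvalue, config.alpha,
                                       config.n_outcome_families),
    )
    if spec.trait_scale == "log_odds":
        orr = estimators.to_odds_ratio(est)
        row.or_point, row.ci_low, row.ci_high = orr.or_point, orr.ci_low, orr.ci_high
    return row


def run_analysis(config: AnalysisConfig) -> list[ReportRow]:
    """Run the full pipeline; per-outcome failures yield failure rows."""
    exposure = summary_io.read_summary_tsv(
        config.exposure_path, trait_scale="log_transformed", trait_name="exposure")
    ld = summary_io.read_ld_matrix(config.ld_path)

    counts = (qc.read_counts_tsv(config.counts_path)
              if config.counts_path else None)
    confounders = (qc.read_confounder_tsv(config.confounders_path)
                   if config.confounders_path else None)
    report = qc.apply_qc_filters(exposure, counts=counts)
    for vid, reason in report.dropped:
        logger.info("qc: dropped %s (%s)", vid, reason)
    kept = report.kept
    if confounders is not None and kept:
        creport = qc.confounder_filter(exposure.subset(kept), confounders,
                                       alpha=config.alpha)
        for vid, reason in creport.dropped:
            logger.info("qc: dropped %s (%s)", vid, reason)
        kept = creport.kept
    if not kept:
        raise ValueError("no exposure variants survived QC")
    exposure = exposure.subset(kept)

    rows: list[ReportRow] = []
    pooled_inputs: dict[tuple[str, str], list] = {}
    for spec in config.outcomes:
        label = spec.name or spec.path
        try:
            outcome = summary_io.read_summary_tsv(
                spec.path, trait_scale=spec.trait_scale,
                sex_stratum=spec.sex_stratum, trait_name=label)
            h = summary_io.harmonize(exposure, outcome, ld)
            chosen = selection.select_instruments(h, config.selection)
            h_sel = h.subset(chosen)
            est = dataclasses.replace(_estimate(h_sel, config),
                                      trait_scale=spec.trait_scale)
        except (ValueError, KeyError) as exc:
            logger.error("outcome %s failed: %s", label, exc)
            rows.append(ReportRow(
                outcome=label, stratum=spec.sex_stratum, cohort=spec.cohort,
                region=config.region, method="failed", n_variants=0,
                estimate=None, se=None, p=None, error=str(exc)))
            continue
        rows.append(_row_from_estimate(est, spec, config))
        if spec.cohort in config.combine:
            key = (spec.sex_stratum, spec.trait_scale)
            pooled_inputs.setdefault(key, []).append((est, spec))

    for (stratum, scale), ests in pooled_inputs.items():
        if len(ests) < 2:
            continue
        pooled = estimators.meta_fixed_effect([e for e, _ in ests])
        spec = OutcomeSpec(
            path="", trait_scale=scale, sex_stratum=stratum,
            cohort="+".join(s.cohort for _, s in ests),
            name=" + ".join((s.name or s.path) for _, s in ests))
        rows.append(_row_from_estimate(pooled, spec, config))
    return rows


def report_to_frame(rows: Sequence[ReportRow]) -> pd.DataFrame:
    cols = ["outcome", "stratum", "cohort", "region", "method", "n_variants",
            "estimate", "se", "p", "or_point", "ci_low", "ci_high",
            "significance", "error"]
    return pd.DataFrame([dataclasses.asdict(r) for r in rows], columns=cols)


def write_report_tsv(rows: Sequence[ReportRow], path) -> None:
    df = report_to_frame(rows)
    for col in ("estimate", "se", "p", "or_point", "ci_low", "ci_high"):
        df[col] = df[col].map(lambda x: "NA" if pd.isna(x) else f"{x:.6g}")
    df["error"] = df["error"].fillna("")
    df.to_csv(path, sep="\t", index=False)


def config_from_yaml(path) -> AnalysisConfig:
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    outcomes = [OutcomeSpec(**o) for o in raw.pop("outcomes", [])]
    sel = raw.pop("selection", None)
    cfg = AnalysisConfig(outcomes=outcomes, **raw)
    if sel is not None:
        cfg.selection = selection.SelectionConfig(**sel)
    return cfg
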