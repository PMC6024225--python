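"""Variant-validity filters and multiple-testing threshold machinery.

Genotype-level QC mirrors standard array QC for an exposure GWAS: minor
allele frequency, call rate, Hardy-Weinberg equilibrium, imputation info
score.  A second, instrument-validity screen removes variants associated
with potential confounders (socio-economic position, lifestyle factors) at
Bonferroni-corrected significance, since such variants would violate the
instrumental-variable exchangeability assumption.

All thresholds use strict inequality, so boundary values survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .summary_io import SummaryDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenotypeCounts:
    """Counts of the three genotype classes at a biallelic variant."""

    n_AA: int
    n_Aa: int
    n_aa: int

    def __post_init__(self) -> None:
        if min(self.n_AA, self.n_Aa, self.n_aa) < 0:
            raise ValueError("genotype counts must be non-negative")
        if self.total == 0:
            raise ValueError("genotype counts must sum to a positive total")

    @property
    def total(self) -> int:
        return self.n_AA + self.n_Aa + self.n_aa


@dataclass
class QCReport:
    """Partition of the input variants into kept and dropped-with-reason."""

    kept: list[str]
    dropped: list[tuple[str, str]]

    @property
    def dropped_ids(self) -> list[str]:
        return [v for v, _ in self.dropped]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"variant_id": v, "status": "kept", "reason": ""} for v in self.kept]
        rows += [{"variant_id": v, "status": "dropped", "reason": r}
                 for v, r in self.dropped]
        return pd.DataFrame(rows, columns=["variant_id", "status", "reason"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def hwe_test(counts: GenotypeCounts) -> float:
    """Chi-square (1 df) goodness-of-fit test of Hardy-Weinberg equilibrium.

    Expected genotype counts use the estimated allele frequency
    p = (2 n_AA + n_Aa) / (2N); a monomorphic variant (any expected class
    zero) returns p-value 1.0.
    """
    n = counts.total
    p_hat = (2 * counts.n_AA + counts.n_Aa) / (2 * n)
    expected = np.array([p_hat**2, 2 * p_hat * (1 - p_hat), (1 - p_hat) ** 2]) * n
    if np.any(expected == 0):
        return 1.0
    observed = np.array([counts.n_AA, counts.n_Aa, counts.n_aa], dtype=float)
    stat = float(np.sum((observed - expected) ** 2 / expected))
    return float(chi2.sf(stat, df=1))


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance level alpha / n_tests."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def apply_qc_filters(
    dataset: SummaryDataset,
    counts: Mapping[str, GenotypeCounts] | None = None,
    maf_min: float = 0.01,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.001,
    info_min: float = 0.6,
    call_rates: Mapping[str, float] | None = None,
) -> QCReport:
    """Apply MAF / call-rate / HWE / info filters to a dataset.

    A criterion whose input is missing for a variant is skipped for that
    variant with a logged warning (a missing info score is treated as a
    genotyped variant, info = 1).  Drop reasons follow the fixed priority
    order maf, call_rate, hwe, info, so reports are deterministic.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    kept, dropped = [], []
    for row in dataset.table.itertuples(index=False):
        vid = row.variant_id
        reason = None
        if pd.isna(row.eaf):
            logger.warning("qc: %s has no eaf; MAF filter skipped", vid)
        else:
            maf = min(float(row.eaf), 1.0 - float(row.eaf))
            if maf < maf_min:
                reason = "maf"
        if reason is None and call_rates is not None:
            cr = call_rates.get(vid)
            if cr is None:
                logger.warning("qc: %s has no call rate; filter skipped", vid)
            elif cr < call_rate_min:
                reason = "call_rate"
        if reason is None and counts is not None:
            gc = counts.get(vid)
            if gc is None:
                logger.warning("qc: %s has no genotype counts; HWE filter skipped", vid)
            elif hwe_test(gc) < hwe_p_min:
                reason = "hwe"
        if reason is None:
            if pd.isna(row.info):
                logger.warning("qc: %s has no info score; treated as genotyped (info=1)", vid)
            elif float(row.info) < info_min:
                reason = "info"
        if reason is None:
            kept.append(vid)
        else:
            dropped.append((vid, reason))
    if not kept:
        logger.warning("qc: no variants survived filtering")
    return QCReport(kept, dropped)


def confounder_filter(
    dataset: SummaryDataset,
    confounders: Mapping[str, Mapping[str, float]],
    alpha: float = 0.05,
) -> QCReport:
    """Drop variants associated with any confounder at Bonferroni significance.

    ``confounders`` maps variant_id -> {confounder name -> association
    p-value}.  The Bonferroni threshold divides ``alpha`` by (number of
    variants x number of confounder traits); a variant absent from the table
    is kept with a warning.  Strict inequality: p exactly at the threshold
    survives.
    """
    ids = dataset.variant_ids
    traits = sorted({t for m in confounders.values() for t in m})
    n_tests = max(len(ids) * max(len(traits), 1), 1)
    threshold = bonferroni_threshold(alpha, n_tests)
    logger.info("confounder filter: threshold %.3g = %.2f / (%d variants x %d traits)",
                threshold, alpha, len(ids), len(traits))
    kept, dropped = [], []
    for vid in ids:
        pvals = confounders.get(vid)
        if pvals is None:
            logger.warning("confounder filter: %s absent from table; kept", vid)
            kept.append(vid)
            continue
        hit = next((t for t in traits if t in pvals and pvals[t] < threshold), None)
        if hit is None:
            kept.append(vid)
        else:
            dropped.append((vid, f"confounder:{hit}"))
    return QCReport(kept, dropped)


def read_counts_tsv(path) -> dict[str, GenotypeCounts]:
    """Read a variant_id / n_AA / n_Aa / n_aa table (case-sensitive counts)."""
    df = pd.read_csv(path, sep="\t")
    required = ["variant_id", "n_AA", "n_Aa", "n_aa"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return {
        str(row.variant_id): GenotypeCounts(int(row.n_AA), int(row.n_Aa), int(row.n_aa))
        for row in df.itertuples(index=False)
    }


def read_confounder_tsv(path) -> dict[str, dict[str, float]]:
    """Read a variant_id table with one p-value column per confounder."""
    df = pd.read_csv(path, sep="\t")
    if "variant_id" not in df.columns:
        raise ValueError(f"{path}: missing variant_id column")
    traits = [c for c in df.columns if c != "variant_id"]
    return {
        str(row["variant_id"]): {t: float(row[t]) for t in traits if pd.notna(row[t])}
        for _, row in df.iterrows()
    }
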