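"""Instrument selection per gene region.

Two strategies, mirroring common practice for densely fine-mapped regions:

* **stepwise**: greedy p-value ranked selection with pairwise r² pruning —
  take the variant most strongly associated with the exposure, then the next
  strongest whose squared correlation with *every* already-selected variant
  is below ``r2_max`` (default 0.4), and so on, yielding a set with low
  pairwise correlations.
* **conditional list**: a fixed, externally derived variant list (e.g. from
  a published conditional analysis), filtered to the variants available.

r² is the square of the signed, allele-aligned correlation, so allele
orientation cannot change the selection.  Ties in p-value break by ascending
genomic position, then lexicographic variant id, making the output
deterministic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .summary_io import HarmonizedSet

logger = logging.getLogger(__name__)


class SelectionError(ValueError):
    pass


@dataclass
class SelectionConfig:
    method: str = "stepwise"  # "stepwise" | "conditional_list"
    r2_max: float = 0.4
    variant_list: list[str] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("stepwise", "conditional_list"):
            raise ValueError(f"unknown selection method {self.method!r}")
        if not (0 < self.r2_max <= 1):
            raise ValueError("r2_max must lie in (0, 1]")
        if self.method == "conditional_list" and not self.variant_list:
            raise ValueError("conditional_list selection requires variant_list")


def stepwise_select(assocs: HarmonizedSet, r2_max: float = 0.4) -> list[str]:
    """Greedy p-value ranked selection under a pairwise r² ceiling.

    Variants are visited in ascending exposure p-value; a candidate is kept
    iff its r² with every already-kept variant is strictly below ``r2_max``.
    Returns the selection in visit order; the smallest-p variant is always
    first.
    """
    k = len(assocs)
    if k == 0:
        raise SelectionError("empty harmonized set")
    pos = assocs.pos if assocs.pos is not None else np.full(k, math.nan)
    order = sorted(
        range(k),
        key=lambda i: (
            assocs.p_exposure[i],
            pos[i] if not math.isnan(pos[i]) else math.inf,
            assocs.variant_ids[i],
        ),
    )
    r = assocs.ld.r
    if np.isnan(r).any():
        ii, jj = np.argwhere(np.isnan(r))[0]
        raise SelectionError(
            f"missing LD entry for pair "
            f"({assocs.variant_ids[ii]}, {assocs.variant_ids[jj]})"
        )
    selected: list[int] = []
    for i in order:
        if all(r[i, j] ** 2 < r2_max for j in selected):
            selected.append(i)
    chosen = [assocs.variant_ids[i] for i in selected]
    logger.info("stepwise selection kept %d of %d variants (r2 < %.2f)",
                len(chosen), k, r2_max)
    return chosen


def conditional_select(assocs: HarmonizedSet, variant_list: Sequence[str]) -> list[str]:
    """Restrict a fixed variant list to those present, preserving list order."""
    if not variant_list:
        raise SelectionError("empty conditional variant list")
    available = set(assocs.variant_ids)
    present = [v for v in variant_list if v in available]
    absent = [v for v in variant_list if v not in available]
    for v in absent:
        logger.info("conditional score: %s not available for this outcome", v)
    if not present:
        raise SelectionError("no conditional-score variants present in the data")
    return present


def select_instruments(assocs: HarmonizedSet, config: SelectionConfig) -> list[str]:
    if config.method == "stepwise":
        return stepwise_select(assocs, config.r2_max)
    return conditional_select(assocs, config.variant_list)


def read_variant_list(path) -> list[str]:
    """One variant id per line; blank lines and #-comments ignored."""
    with open(path) as fh:
        return [ln.strip() for ln in fh
                if ln.strip() and not ln.lstrip().startswith("#")]


def selection_to_frame(assocs: HarmonizedSet, chosen: Sequence[str]) -> pd.DataFrame:
    idx = {v: i for i, v in enumerate(assocs.variant_ids)}
    return pd.DataFrame({
        "rank": range(1, len(chosen) + 1),
        "variant_id": list(chosen),
        "p_exposure": [assocs.p_exposure[idx[v]] for v in chosen],
    })
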