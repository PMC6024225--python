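"""Reading, writing and harmonizing GWAS summary statistics and LD matrices.

Summary statistics arrive as tab-separated tables with one row per variant
(effect/other alleles, effect size, standard error, p-value, allele frequency,
optional imputation info score and sample size).  Linkage-disequilibrium (LD)
correlations arrive as a square matrix file with variant ids on the first row
and column and an optional ``ref_allele`` row anchoring the sign of each
correlation.

Harmonization aligns the outcome dataset's effect alleles (and the LD matrix's
sign convention) to the exposure dataset's effect alleles, so that every
effect direction refers to the same allele per variant.  Palindromic (A/T,
C/G) variants whose minor allele frequency is close to 0.5 are strand
ambiguous and are dropped; outside that band they are aligned by allele
frequency.  All drops and sign flips are logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical column order of the summary-statistics dialect.
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "info",
]
MANDATORY_COLUMNS = ["variant_id", "effect_allele", "other_allele", "beta", "se"]

TRAIT_SCALES = ("continuous_sd", "log_transformed", "log_odds")
SEX_STRATA = ("all", "men", "women")


class SummaryFormatError(ValueError):
    """A summary-statistics or LD file violates the expected dialect."""


class SummaryValidationError(ValueError):
    """Parsed values violate a field-level invariant (e.g. non-positive se)."""


class HarmonizationError(ValueError):
    """Exposure/outcome/LD inputs cannot be reconciled."""


def complement(allele: str) -> str:
    return _COMPLEMENT[allele]


def is_palindromic(effect_allele: str, other_allele: str) -> bool:
    """A/T and C/G pairs read the same on both strands."""
    return _COMPLEMENT.get(effect_allele) == other_allele


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's marginal association with one trait.

    ``beta`` is the per-effect-allele change in the trait (a log odds ratio
    for binary outcomes); ``se`` its standard error.  Optional fields use
    ``None``/NaN when missing.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pvalue: float | None = None
    n: int | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise SummaryValidationError(
                f"{self.variant_id}: alleles must be A/C/G/T, got "
                f"{self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise SummaryValidationError(
                f"{self.variant_id}: effect and other allele are identical"
            )
        if not (self.se > 0):
            raise SummaryValidationError(f"{self.variant_id}: se must be > 0")


@dataclass
class SummaryDataset:
    """An ordered set of variant associations for one trait.

    The table is held as a pandas DataFrame with the canonical columns of
    :data:`SUMMARY_COLUMNS`; ``variant_id`` is unique and row order is stable.
    """

    table: pd.DataFrame
    trait_name: str = ""
    trait_scale: str = "continuous_sd"
    sex_stratum: str = "all"

    def __post_init__(self) -> None:
        if self.trait_scale not in TRAIT_SCALES:
            raise ValueError(f"unknown trait_scale {self.trait_scale!r}")
        if self.sex_stratum not in SEX_STRATA:
            raise ValueError(f"unknown sex_stratum {self.sex_stratum!r}")
        df = self.table
        for col in SUMMARY_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        self.table = df[SUMMARY_COLUMNS].reset_index(drop=True)
        if self.table["variant_id"].duplicated().any():
            dups = self.table.loc[self.table["variant_id"].duplicated(), "variant_id"]
            raise SummaryValidationError(f"duplicate variant_id(s): {sorted(set(dups))}")
        bad = self.table[~(self.table["se"] > 0)]
        if len(bad):
            raise SummaryValidationError(
                f"non-positive se for variant(s): {list(bad['variant_id'])}"
            )

    @classmethod
    def from_records(
        cls,
        records: Sequence[VariantAssociation],
        trait_name: str = "",
        trait_scale: str = "continuous_sd",
        sex_stratum: str = "all",
    ) -> "SummaryDataset":
        rows = [
            {
                "variant_id": r.variant_id, "chrom": r.chrom, "pos": r.pos,
                "effect_allele": r.effect_allele, "other_allele": r.other_allele,
                "eaf": r.eaf, "beta": r.beta, "se": r.se, "pvalue": r.pvalue,
                "n": r.n, "info": r.info,
            }
            for r in records
        ]
        return cls(pd.DataFrame(rows), trait_name, trait_scale, sex_stratum)

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    def __len__(self) -> int:
        return len(self.table)

    def records(self) -> list[VariantAssociation]:
        out = []
        for row in self.table.itertuples(index=False):
            out.append(VariantAssociation(
                variant_id=row.variant_id,
                effect_allele=row.effect_allele,
                other_allele=row.other_allele,
                beta=float(row.beta),
                se=float(row.se),
                chrom=None if pd.isna(row.chrom) else str(row.chrom),
                pos=None if pd.isna(row.pos) else int(row.pos),
                eaf=None if pd.isna(row.eaf) else float(row.eaf),
                pvalue=None if pd.isna(row.pvalue) else float(row.pvalue),
                n=None if pd.isna(row.n) else int(row.n),
                info=None if pd.isna(row.info) else float(row.info),
            ))
        return out

    def subset(self, variant_ids: Sequence[str]) -> "SummaryDataset":
        """Restrict to ``variant_ids``, preserving the given order."""
        idx = self.table.set_index("variant_id")
        missing = [v for v in variant_ids if v not in idx.index]
        if missing:
            raise KeyError(f"variant(s) not in dataset: {missing}")
        sub = idx.loc[list(variant_ids)].reset_index()
        return replace(self, table=sub)


@dataclass
class LDMatrix:
    """Signed pairwise correlations r between variants, allele-anchored.

    ``reference_alleles[i]`` is the allele of variant i to which the sign of
    its correlations refers; ``None`` means the orientation is taken on trust
    (assumed aligned to whatever effect alleles the caller uses).
    """

    variant_ids: list[str]
    r: np.ndarray
    reference_alleles: list[str] | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise SummaryFormatError(
                f"LD matrix shape {self.r.shape} does not match {k} variant ids"
            )
        asym = np.max(np.abs(self.r - self.r.T)) if k else 0.0
        if asym > 1e-6:
            raise SummaryValidationError(f"LD matrix asymmetry {asym:.3g} exceeds 1e-6")
        self.r = (self.r + self.r.T) / 2.0
        if k and np.max(np.abs(np.diag(self.r) - 1.0)) > 1e-6:
            raise SummaryValidationError("LD matrix diagonal deviates from 1 by > 1e-6")
        self.r = np.clip(self.r, -1.0, 1.0)
        np.fill_diagonal(self.r, 1.0)
        if self.reference_alleles is not None and len(self.reference_alleles) != k:
            raise SummaryFormatError("reference_alleles length mismatch")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, variant_ids: Sequence[str]) -> "LDMatrix":
        pos = {v: i for i, v in enumerate(self.variant_ids)}
        missing = [v for v in variant_ids if v not in pos]
        if missing:
            raise KeyError(f"variant(s) not in LD matrix: {missing}")
        idx = [pos[v] for v in variant_ids]
        refs = None
        if self.reference_alleles is not None:
            refs = [self.reference_alleles[i] for i in idx]
        return LDMatrix(list(variant_ids), self.r[np.ix_(idx, idx)], refs)


@dataclass
class HarmonizedSet:
    """Exposure and outcome associations joined on variant, alleles aligned.

    All vectors and the LD matrix share one ordering and one per-variant
    effect allele; this is the direct input of the regression estimators.
    """

    variant_ids: list[str]
    beta_exposure: np.ndarray
    se_exposure: np.ndarray
    p_exposure: np.ndarray
    beta_outcome: np.ndarray
    se_outcome: np.ndarray
    ld: LDMatrix
    pos: np.ndarray | None = None  # used only for deterministic tie-breaks

    def __post_init__(self) -> None:
        k = len(self.variant_ids)
        for name in ("beta_exposure", "se_exposure", "p_exposure",
                     "beta_outcome", "se_outcome"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (k,):
                raise ValueError(f"{name} has shape {v.shape}, expected ({k},)")
            setattr(self, name, v)
        if len(self.ld) != k or self.ld.variant_ids != self.variant_ids:
            raise ValueError("LD matrix not aligned with variant_ids")
        if self.pos is not None:
            self.pos = np.asarray(self.pos, dtype=float)

    def __len__(self) -> int:
        return len(self.variant_ids)

    def subset(self, variant_ids: Sequence[str]) -> "HarmonizedSet":
        pos_map = {v: i for i, v in enumerate(self.variant_ids)}
        idx = [pos_map[v] for v in variant_ids]
        return HarmonizedSet(
            variant_ids=list(variant_ids),
            beta_exposure=self.beta_exposure[idx],
            se_exposure=self.se_exposure[idx],
            p_exposure=self.p_exposure[idx],
            beta_outcome=self.beta_outcome[idx],
            se_outcome=self.se_outcome[idx],
            ld=self.ld.subset(variant_ids),
            pos=None if self.pos is None else self.pos[idx],
        )


# ---------------------------------------------------------------------------
# TSV I/O


def _check_pvalue_consistency(df: pd.DataFrame, path: str) -> None:
    # Published tables round, so disagreement is a warning, never an error.
    from scipy.stats import norm

    have = df["pvalue"].notna() & df["beta"].notna() & df["se"].notna()
    if not have.any():
        return
    z = np.abs(df.loc[have, "beta"] / df.loc[have, "se"])
    implied = 2 * norm.sf(z)
    stated = df.loc[have, "pvalue"].to_numpy(float)
    with np.errstate(divide="ignore"):
        off = np.abs(np.log10(np.maximum(stated, 1e-300))
                     - np.log10(np.maximum(implied, 1e-300))) > 1.0
    for vid in df.loc[have].loc[off, "variant_id"]:
        logger.warning(
            "%s: stated p-value inconsistent with |beta/se| for %s "
            "(treated as rounding, not an error)", path, vid)


def read_summary_tsv(
    path, trait_scale: str = "continuous_sd", sex_stratum: str = "all",
    trait_name: str | None = None,
) -> SummaryDataset:
    """Read a tab-separated summary-statistics table.

    Header names are matched case-insensitively.  Mandatory columns are
    variant_id, effect_allele, other_allele, beta, se; eaf, pvalue, n, info,
    chrom, pos are optional and unparseable entries in them become missing.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA", "nan", ""])
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryFormatError(
            f"{path}: missing mandatory column(s): {', '.join(missing)}"
        )
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SUMMARY_COLUMNS]
    for col in ("eaf", "beta", "se", "pvalue", "info"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    if df["beta"].isna().any() or df["se"].isna().any():
        bad = df.loc[df["beta"].isna() | df["se"].isna(), "variant_id"]
        raise SummaryFormatError(f"{path}: unparseable beta/se for: {list(bad)}")
    df["effect_allele"] = df["effect_allele"].str.upper()
    df["other_allele"] = df["other_allele"].str.upper()
    _check_pvalue_consistency(df, str(path))
    return SummaryDataset(
        df, trait_name=trait_name or str(path), trait_scale=trait_scale,
        sex_stratum=sex_stratum,
    )


def write_summary_tsv(dataset: SummaryDataset, path) -> None:
    """Write the canonical tab-separated dialect; missing values as ``NA``."""
    if len(dataset) == 0:
        raise ValueError("refusing to write an empty dataset")
    df = dataset.table.copy()
    df["pos"] = df["pos"].astype("Int64")
    df["n"] = df["n"].astype("Int64")
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_ld_matrix(path) -> LDMatrix:
    """Read a square LD correlation matrix.

    The first row holds variant ids, the first column repeats them; an
    optional second row labelled ``ref_allele`` anchors the sign convention.
    Whitespace- or tab-delimited input is accepted.  Entries with |r|
    marginally above 1 are clipped; asymmetry above 1e-6 is an error,
    below it the matrix is symmetrized as (M + M')/2.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise SummaryFormatError(f"{path}: empty LD file")
    header = lines[0].split()
    ids = header[1:] if header[0].lower() in ("variant_id", "id", "rsid", "") else header
    refs = None
    body_start = 1
    if len(lines) > 1:
        second = lines[1].split()
        if second and second[0].lower() == "ref_allele":
            refs = [a.upper() for a in second[1:]]
            if len(refs) != len(ids):
                raise SummaryFormatError(f"{path}: ref_allele row length mismatch")
            body_start = 2
    rows = []
    row_ids = []
    for ln in lines[body_start:]:
        parts = ln.split()
        row_ids.append(parts[0])
        rows.append(parts[1:])
    if len(rows) != len(ids) or any(len(r) != len(ids) for r in rows):
        raise SummaryFormatError(
            f"{path}: LD block is not square ({len(rows)} rows, {len(ids)} ids)"
        )
    if row_ids != list(ids):
        raise SummaryFormatError(f"{path}: row ids do not match column ids")
    try:
        mat = np.array(rows, dtype=float)
    except ValueError as exc:
        raise SummaryFormatError(f"{path}: non-numeric LD entry ({exc})") from None
    return LDMatrix(list(ids), mat, refs)


def write_ld_matrix(ld: LDMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("variant_id\t" + "\t".join(ld.variant_ids) + "\n")
        if ld.reference_alleles is not None:
            fh.write("ref_allele\t" + "\t".join(ld.reference_alleles) + "\n")
        for vid, row in zip(ld.variant_ids, ld.r):
            fh.write(vid + "\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


# ---------------------------------------------------------------------------
# Harmonization


def align_ld_to_effect_alleles(
    ld: LDMatrix,
    effect_alleles: Mapping[str, str],
    other_alleles: Mapping[str, str] | None = None,
) -> LDMatrix:
    """Flip LD row/column signs so every r refers to the given effect alleles.

    For each variant whose effect allele differs from the matrix's reference
    allele (allowing for strand complement), its row and column are negated;
    the diagonal is unchanged.  When ``other_alleles`` is supplied, an effect
    allele matching neither reference nor other (including complements) is an
    error naming the variant.
    """
    if ld.reference_alleles is None:
        logger.warning("LD matrix carries no reference alleles; orientation taken on trust")
        return LDMatrix(list(ld.variant_ids), ld.r.copy(), None)
    signs = np.ones(len(ld))
    for i, (vid, ref) in enumerate(zip(ld.variant_ids, ld.reference_alleles)):
        ea = effect_alleles[vid]
        if ea == ref or _COMPLEMENT.get(ea) == ref:
            continue
        if other_alleles is not None:
            oa = other_alleles[vid]
            if not (oa == ref or _COMPLEMENT.get(oa) == ref):
                raise HarmonizationError(
                    f"{vid}: effect allele {ea} (other {oa}) matches neither "
                    f"LD reference allele {ref} nor its complement"
                )
        signs[i] = -1.0
        logger.info("LD sign flip for %s (ref %s -> effect %s)", vid, ref, ea)
    r = ld.r * np.outer(signs, signs)
    new_refs = [effect_alleles[v] for v in ld.variant_ids]
    return LDMatrix(list(ld.variant_ids), r, new_refs)


def _reconcile_alleles(ea_x, oa_x, ea_y, oa_y):
    """Return 'same', 'swap' or None for an outcome allele pair vs exposure."""
    if (ea_y, oa_y) == (ea_x, oa_x):
        return "same"
    if (ea_y, oa_y) == (oa_x, ea_x):
        return "swap"
    # strand-flipped records (only meaningful for non-palindromic variants)
    if not is_palindromic(ea_x, oa_x):
        if (ea_y, oa_y) == (complement(ea_x), complement(oa_x)):
            return "same"
        if (ea_y, oa_y) == (complement(oa_x), complement(ea_x)):
            return "swap"
    return None


def harmonize(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LDMatrix,
    palindromic_eaf_band: float = 0.08,
) -> HarmonizedSet:
    """Inner-join exposure and outcome on variant_id with alleles aligned.

    Outcome records whose alleles are swapped relative to the exposure have
    beta negated (and eaf reflected); the LD matrix is sign-aligned to the
    exposure effect alleles.  Palindromic variants with MAF within
    ``palindromic_eaf_band`` of 0.5 in either dataset are dropped; outside
    the band they are oriented by allele frequency.  Every drop is logged
    with its reason.
    """
    exp = exposure.table.set_index("variant_id")
    out = outcome.table.set_index("variant_id")
    ld_ids = set(ld.variant_ids)
    shared = [v for v in exposure.variant_ids if v in out.index and v in ld_ids]
    if not shared:
        raise HarmonizationError("no shared variants between exposure, outcome and LD")

    kept, bx, sx, px, by, sy, pos = [], [], [], [], [], [], []
    for vid in shared:
        ex, oc = exp.loc[vid], out.loc[vid]
        ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
        rel = _reconcile_alleles(ea_x, oa_x, oc["effect_allele"], oc["other_allele"])
        if rel is None:
            logger.info("harmonize: dropped %s (irreconcilable alleles %s/%s vs %s/%s)",
                        vid, ea_x, oa_x, oc["effect_allele"], oc["other_allele"])
            continue
        beta_y = float(oc["beta"]) if rel == "same" else -float(oc["beta"])
        if is_palindromic(ea_x, oa_x):
            eaf_x, eaf_y = ex["eaf"], oc["eaf"]
            if pd.isna(eaf_x) or pd.isna(eaf_y):
                logger.info("harmonize: dropped %s (palindromic, eaf missing)", vid)
                continue
            eaf_y_aligned = float(eaf_y) if rel == "same" else 1.0 - float(eaf_y)
            if (abs(float(eaf_x) - 0.5) < palindromic_eaf_band
                    or abs(eaf_y_aligned - 0.5) < palindromic_eaf_band):
                logger.info("harmonize: dropped %s (palindromic, MAF within %.2f of 0.5)",
                            vid, palindromic_eaf_band)
                continue
            if (float(eaf_x) < 0.5) != (eaf_y_aligned < 0.5):
                # frequencies disagree: the outcome record is on the other
                # strand orientation, so the sign flips once more
                beta_y = -beta_y
                logger.info("harmonize: %s palindromic, oriented by allele frequency", vid)
        kept.append(vid)
        bx.append(float(ex["beta"]))
        sx.append(float(ex["se"]))
        p = ex["pvalue"]
        if pd.isna(p):
            from scipy.stats import norm
            p = 2 * norm.sf(abs(float(ex["beta"]) / float(ex["se"])))
        px.append(float(p))
        by.append(beta_y)
        sy.append(float(oc["se"]))
        pos.append(float(ex["pos"]) if pd.notna(ex["pos"]) else math.nan)

    if not kept:
        raise HarmonizationError("all shared variants dropped during harmonization")

    effect = {v: exp.loc[v, "effect_allele"] for v in kept}
    other = {v: exp.loc[v, "other_allele"] for v in kept}
    ld_sub = align_ld_to_effect_alleles(ld.subset(kept), effect, other)
    return HarmonizedSet(
        variant_ids=kept,
        beta_exposure=np.array(bx), se_exposure=np.array(sx), p_exposure=np.array(px),
        beta_outcome=np.array(by), se_outcome=np.array(sy),
        ld=ld_sub, pos=np.array(pos),
    )
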