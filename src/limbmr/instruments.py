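"""Genetic instruments: weight tables, allele harmonization, risk scores.

A genetic risk score (GRS) is the weighted sum of allele dosages, with
weights taken from published GWAS effect sizes.  Because the allele a
published weight refers to (the *effect allele*) need not be the allele a
genotype file counts, weights must first be harmonized: sign-flipped when
the coding is swapped, strand-complemented when the file is on the opposite
strand, and dropped for palindromic (A/T, C/G) variants whose orientation
cannot be resolved from allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "InstrumentTable",
    "GeneticRiskScore",
    "InstrumentError",
    "load_instrument_table",
    "harmonize",
    "align_alleles",
    "compute_grs",
    "instrument_f_statistic",
]

VALID_BASES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Effect-allele-frequency distance from 0.5 below which a palindromic
#: variant's orientation is considered ambiguous (common convention).
PALINDROMIC_EAF_MARGIN = 0.08


class InstrumentError(ValueError):
    """Invalid instrument table or degenerate score."""


@dataclass
class InstrumentTable:
    """Per-variant published weights defining a genetic instrument."""

    table: pd.DataFrame  # id, effect_allele, other_allele, weight [, se, eaf, pathway_tag]

    def __post_init__(self) -> None:
        df = self.table
        required = {"id", "effect_allele", "other_allele", "weight"}
        missing = required - set(df.columns)
        if missing:
            raise InstrumentError(f"instrument table missing column(s) {sorted(missing)}")
        if len(df) == 0:
            raise InstrumentError("instrument table is empty")
        dup = df["id"][df["id"].duplicated()]
        if len(dup):
            raise InstrumentError(f"duplicate variant id(s): {sorted(dup.unique())}")
        for row in df.itertuples():
            ea, oa = str(row.effect_allele), str(row.other_allele)
            if ea not in VALID_BASES or oa not in VALID_BASES:
                raise InstrumentError(
                    f"variant {row.id}: alleles must be one of A/C/G/T (got {ea}/{oa})"
                )
            if ea == oa:
                raise InstrumentError(
                    f"variant {row.id}: effect and other allele are both {ea}"
                )

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneticRiskScore:
    values: np.ndarray  # z-scored across the cohort
    raw_values: np.ndarray  # sum_j w_j g_ij
    n_variants_used: int
    exclusions: list[tuple[str, str]] = field(default_factory=list)


def load_instrument_table(path) -> InstrumentTable:
    """Load a delimited instrument weight table (TSV or comma-separated)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if len(df) == 0:
        raise InstrumentError(f"instrument file {path} contains no variants")
    return InstrumentTable(df)


def _is_palindromic(a1: str, a2: str) -> bool:
    return COMPLEMENT[a1] == a2


def align_alleles(
    effect_allele: str,
    other_allele: str,
    counted_allele: str,
    counted_other: str,
    *,
    eaf_effect: float | None = None,
    eaf_counted: float | None = None,
) -> tuple[float, str]:
    """Orientation of a counted allele pair relative to an effect/other pair.

    Returns ``(sign, reason)``: sign +1 when the counted allele carries the
    published effect, -1 when the coding is swapped (weight must flip), and
    0 when the variant must be excluded (``reason`` says why).  Strand
    complements are tried when the raw alleles do not match.  Palindromic
    variants are resolved by comparing which side of 0.5 the effect-allele
    and counted-allele frequencies fall on, and only when both are at least
    ``PALINDROMIC_EAF_MARGIN`` away from 0.5.
    """
    pair = {effect_allele, other_allele}
    counted_pair = {counted_allele, counted_other}
    if _is_palindromic(effect_allele, other_allele):
        if counted_pair != pair:
            return 0.0, "allele mismatch"
        if eaf_effect is None or eaf_counted is None or not np.isfinite([eaf_effect, eaf_counted]).all():
            return 0.0, "palindromic, no EAF to resolve strand"
        if (
            abs(eaf_effect - 0.5) <= PALINDROMIC_EAF_MARGIN
            or abs(eaf_counted - 0.5) <= PALINDROMIC_EAF_MARGIN
        ):
            return 0.0, "palindromic, ambiguous"
        return (1.0 if (eaf_effect < 0.5) == (eaf_counted < 0.5) else -1.0), "palindromic, EAF-resolved"
    if counted_pair == pair:
        return (1.0 if counted_allele == effect_allele else -1.0), "direct match"
    comp_pair = {COMPLEMENT[counted_allele], COMPLEMENT[counted_other]}
    if comp_pair == pair:
        return (
            1.0 if COMPLEMENT[counted_allele] == effect_allele else -1.0
        ), "strand complement"
    return 0.0, "irreconcilable alleles"


def harmonize(
    instruments: InstrumentTable, genotype_coding: pd.DataFrame
) -> tuple[np.ndarray, list[tuple[str, str]]]:
    """Align published weights with a genotype file's counted alleles.

    ``genotype_coding`` has one row per genotype column: id, counted_allele,
    other_allele and optionally eaf (counted-allele frequency).  Returns a
    weight vector parallel to the coding rows (NaN where the column carries
    no usable instrument) plus an exclusion list of (id, reason) covering
    instruments that were dropped or not genotyped.
    """
    inst = instruments.table.set_index("id")
    weights = np.full(len(genotype_coding), np.nan)
    exclusions: list[tuple[str, str]] = []
    seen: set[str] = set()
    has_eaf = "eaf" in genotype_coding.columns
    for j, row in enumerate(genotype_coding.itertuples()):
        vid = str(row.id)
        if vid not in inst.index:
            continue
        seen.add(vid)
        rec = inst.loc[vid]
        sign, reason = align_alleles(
            str(rec["effect_allele"]),
            str(rec["other_allele"]),
            str(row.counted_allele),
            str(row.other_allele),
            eaf_effect=float(rec["eaf"]) if "eaf" in rec.index and pd.notna(rec["eaf"]) else None,
            eaf_counted=float(row.eaf) if has_eaf and pd.notna(row.eaf) else None,
        )
        if sign == 0.0:
            exclusions.append((vid, reason))
        else:
            weights[j] = sign * float(rec["weight"])
    for vid in inst.index:
        if str(vid) not in seen:
            exclusions.append((str(vid), "not genotyped"))
    return weights, exclusions


def compute_grs(
    genotypes: np.ndarray,
    aligned_weights: np.ndarray,
    exclusions: list[tuple[str, str]] | None = None,
) -> GeneticRiskScore:
    """Weighted allele score, mean-imputing missing dosages, then z-scored."""
    w = np.asarray(aligned_weights, dtype=float)
    usable = np.isfinite(w) & (w != 0.0)
    if not usable.any():
        raise InstrumentError("no usable instrument variants (all excluded or zero-weight)")
    g = np.array(genotypes[:, usable], dtype=float)
    if np.isnan(g).any():
        col_mean = np.nanmean(g, axis=0)
        nan_idx = np.where(np.isnan(g))
        g[nan_idx] = col_mean[nan_idx[1]]
    raw = g @ w[usable]
    sd = raw.std()
    if sd == 0:
        raise InstrumentError("genetic risk score is constant across the cohort")
    values = (raw - raw.mean()) / sd
    return GeneticRiskScore(
        values=values,
        raw_values=raw,
        n_variants_used=int(usable.sum()),
        exclusions=list(exclusions or []),
    )


def instrument_f_statistic(
    grs_values: np.ndarray,
    exposure: np.ndarray,
    covariates: np.ndarray | None = None,
) -> tuple[float, float]:
    """First-stage strength: F and incremental R^2 of the GRS term.

    F = (n - p - 2) * R2_partial / (1 - R2_partial) where p counts the
    covariates and R2_partial is the incremental R^2 of the GRS over the
    covariate-only model; this equals the squared t statistic of the GRS
    coefficient.
    """
    x = np.asarray(grs_values, dtype=float)
    y = np.asarray(exposure, dtype=float)
    n = y.shape[0]
    if covariates is None:
        covariates = np.empty((n, 0))
    covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
    if covariates.shape[0] != n:
        covariates = covariates.T
    p = covariates.shape[1]
    if n <= p + 2:
        raise InstrumentError(f"n={n} too small for {p} covariates plus the GRS term")

    base = np.column_stack([np.ones(n), covariates])
    full = np.column_stack([base, x])
    rss0 = _rss(y, base)
    rss1 = _rss(y, full)
    if rss0 <= 0:
        raise InstrumentError("exposure perfectly explained by covariates alone")
    r2_partial = (rss0 - rss1) / rss0
    r2_partial = min(max(r2_partial, 0.0), 1.0)
    if r2_partial >= 1.0:
        return float("inf"), 1.0
    f = (n - p - 2) * r2_partial / (1.0 - r2_partial)
    return float(f), float(r2_partial)


def _rss(y: np.ndarray, design: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    return float(resid @ resid)
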