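"""Containers and I/O for GWAS summary statistics.

Summary associations travel as tab-separated tables with one row per variant.
Effect sizes follow the usual two-sample MR conventions: per-allele change in
SD units for continuous traits, per-allele change in log-odds for binary
traits. Only biallelic SNPs (single-base A/C/G/T alleles) are modelled;
indels and multi-allelic records are rejected at read time.

The harmonisation logic aligns an exposure and an outcome record onto a
common effect allele, correcting unambiguous strand or order mismatches and
using effect-allele frequencies to resolve palindromic (A/T, C/G) variants.
Ambiguous palindromes — missing frequencies, or frequencies too close to 0.5
to be informative — are dropped.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset({"A", "C", "G", "T"})
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC_SETS = (frozenset({"A", "T"}), frozenset({"C", "G"}))

#: canonical column order of the summary-statistic TSV
SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]
MANDATORY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pval",
]

#: common header aliases accepted out of the box (case-sensitive)
DEFAULT_COLUMN_ALIASES: Mapping[str, str] = {
    "SNP": "variant_id",
    "rsid": "variant_id",
    "chr": "chrom",
    "bp": "pos",
    "position": "pos",
    "A1": "effect_allele",
    "A2": "other_allele",
    "freq": "eaf",
    "frequency": "eaf",
    "effect_allele_frequency": "eaf",
    "b": "beta",
    "p": "pval",
    "pvalue": "pval",
    "p_value": "pval",
    "samplesize": "n",
    "N": "n",
}


class SummaryStatsFormatError(ValueError):
    """A summary-statistic file is malformed (missing columns, no data)."""


class HarmonisationError(ValueError):
    """Exposure/outcome records cannot be paired as requested."""


def is_palindromic(allele_a: str, allele_b: str) -> bool:
    """True for A/T or C/G variants, whose strand cannot be read off the labels."""
    return frozenset({allele_a, allele_b}) in _PALINDROMIC_SETS


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the effect per copy of ``effect_allele`` (SD units for
    continuous traits, log-odds for binary traits); ``eaf`` is the effect
    allele frequency and may be missing.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float | None
    beta: float
    se: float
    pval: float
    n: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            raise ValueError(
                f"{self.variant_id}: alleles must be single uppercase A/C/G/T, "
                f"got {self.effect_allele!r}/{self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant_id}: effect and other allele are identical")
        if self.pos < 1:
            raise ValueError(f"{self.variant_id}: positions are 1-based, got {self.pos}")
        if not (self.se > 0 and math.isfinite(self.se)):
            raise ValueError(f"{self.variant_id}: se must be finite and > 0, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValueError(f"{self.variant_id}: pval must lie in (0, 1], got {self.pval}")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValueError(f"{self.variant_id}: eaf must lie in [0, 1], got {self.eaf}")

    @property
    def zscore(self) -> float:
        return self.beta / self.se


@dataclass(frozen=True)
class TraitInfo:
    """Identity and scale convention of one trait.

    ``trait_type`` fixes the beta scale: SD units for ``continuous``,
    log-odds for ``binary``.
    """

    trait_id: str
    label: str = ""
    trait_type: str = "continuous"
    n_cases: int | None = None
    n_controls: int | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValueError(f"trait_type must be continuous|binary, got {self.trait_type!r}")


@dataclass(frozen=True)
class HarmonisedInstrument:
    """An exposure/outcome SNP pair expressed on a shared effect allele.

    ``action`` records what harmonisation did: ``kept`` (no change),
    ``flipped`` (outcome beta negated, EAF complemented),
    ``palindromic_resolved`` (palindrome kept as listed after the frequency
    check) or ``dropped`` (excluded from estimation, see ``drop_reason``).
    ``proxy_of`` names the original outcome variant when an LD proxy was
    substituted.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    exposure_beta: float
    exposure_se: float
    exposure_eaf: float | None
    outcome_beta: float
    outcome_se: float
    outcome_eaf: float | None
    action: str
    drop_reason: str = ""
    proxy_of: str = ""

    def __post_init__(self) -> None:
        if self.action not in ("kept", "flipped", "palindromic_resolved", "dropped"):
            raise ValueError(f"unknown harmonisation action {self.action!r}")
        if self.action == "dropped" and not self.drop_reason:
            raise ValueError("dropped instruments require a drop_reason")

    @property
    def usable(self) -> bool:
        return self.action != "dropped"


# ---------------------------------------------------------------------------
# I/O


def _resolve_columns(df: pd.DataFrame, column_map: Mapping[str, str] | None) -> pd.DataFrame:
    aliases = dict(DEFAULT_COLUMN_ALIASES)
    if column_map:
        aliases.update(column_map)
    renames = {src: dst for src, dst in aliases.items() if src in df.columns and dst not in df.columns}
    return df.rename(columns=renames)


def read_summary_stats(
    path,
    trait: TraitInfo | None = None,
    column_map: Mapping[str, str] | None = None,
) -> list[VariantAssociation]:
    """Read a tab-separated summary-statistic table into association records.

    Rows with non-ACGT alleles, non-positive SEs or otherwise invalid fields
    are skipped with a logged count; row order is preserved. ``column_map``
    maps file headers onto the canonical names (e.g. ``{"MarkerName":
    "variant_id"}``); common aliases are recognised automatically.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", dtype={"chrom": str, "chr": str}, float_precision="round_trip"
        )
    except pd.errors.EmptyDataError as exc:
        raise SummaryStatsFormatError(f"{path}: empty file") from exc
    df = _resolve_columns(df, column_map)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(f"{path}: missing mandatory column(s) {missing}")
    if df.empty:
        raise SummaryStatsFormatError(f"{path}: no data rows")

    records: list[VariantAssociation] = []
    n_skipped = 0
    has_eaf = "eaf" in df.columns
    has_n = "n" in df.columns
    for row in df.itertuples(index=False):
        d = row._asdict()
        try:
            eaf = float(d["eaf"]) if has_eaf and pd.notna(d["eaf"]) else None
            n = float(d["n"]) if has_n and pd.notna(d["n"]) else None
            records.append(
                VariantAssociation(
                    variant_id=str(d["variant_id"]),
                    chrom=str(d["chrom"]),
                    pos=int(d["pos"]),
                    effect_allele=str(d["effect_allele"]).upper(),
                    other_allele=str(d["other_allele"]).upper(),
                    eaf=eaf,
                    beta=float(d["beta"]),
                    se=float(d["se"]),
                    pval=float(d["pval"]),
                    n=n,
                )
            )
        except (ValueError, TypeError):
            n_skipped += 1
    if n_skipped:
        logger.info("%s: skipped %d invalid row(s)", path, n_skipped)
    return records


def write_summary_stats(assocs: Iterable[VariantAssociation], path) -> None:
    """Write association records as a canonical tab-separated table.

    Inverse of :func:`read_summary_stats`: fixed column order, full float
    precision, empty cells for missing ``eaf``/``n``.
    """
    rows = [
        {
            "variant_id": a.variant_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "effect_allele": a.effect_allele,
            "other_allele": a.other_allele,
            "eaf": "" if a.eaf is None else repr(float(a.eaf)),
            "beta": repr(float(a.beta)),
            "se": repr(float(a.se)),
            "pval": repr(float(a.pval)),
            "n": "" if a.n is None else repr(float(a.n)),
        }
        for a in assocs
    ]
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Instrument selection and harmonisation


def select_instruments(
    assocs: Sequence[VariantAssociation], p_threshold: float = 5e-8
) -> list[VariantAssociation]:
    """Keep records with ``pval`` strictly below the genome-wide threshold.

    Output is sorted by ascending p-value, ties broken by variant id.
    """
    if not (0 < p_threshold < 1):
        raise ValueError(f"p_threshold must lie in (0, 1), got {p_threshold}")
    hits = [a for a in assocs if a.pval < p_threshold]
    hits.sort(key=lambda a: (a.pval, a.variant_id))
    return hits


def _dropped(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    reason: str,
    proxy_of: str,
) -> HarmonisedInstrument:
    return HarmonisedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=exposure.effect_allele,
        other_allele=exposure.other_allele,
        exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        exposure_eaf=exposure.eaf,
        outcome_beta=outcome.beta,
        outcome_se=outcome.se,
        outcome_eaf=outcome.eaf,
        action="dropped",
        drop_reason=reason,
        proxy_of=proxy_of,
    )


def harmonise_pair(
    exposure: VariantAssociation,
    outcome: VariantAssociation,
    palindrome_eaf_window: float = 0.08,
    proxy_of: str = "",
) -> HarmonisedInstrument:
    """Align one outcome record onto the exposure record's effect allele.

    Non-palindromic variants are matched directly or after strand
    complementation; a swapped allele order flips the outcome (beta negated,
    EAF complemented). Palindromic variants are resolved by requiring both
    effect-allele frequencies to fall outside ``0.5 ± palindrome_eaf_window``
    and to agree on the same side of 0.5 after alignment; otherwise the pair
    is dropped as ``ambiguous_palindrome``. Incompatible allele sets drop as
    ``allele_mismatch``. The operation is idempotent on its kept/flipped
    outputs.
    """
    if exposure.variant_id != outcome.variant_id and not proxy_of:
        raise HarmonisationError(
            f"variant ids differ ({exposure.variant_id} vs {outcome.variant_id}) "
            "and no proxy substitution was declared"
        )
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    x_set = {ea_x, oa_x}
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele

    if is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != x_set:
            return _dropped(exposure, outcome, "allele_mismatch", proxy_of)
        lo, hi = 0.5 - palindrome_eaf_window, 0.5 + palindrome_eaf_window
        if exposure.eaf is None or outcome.eaf is None:
            return _dropped(exposure, outcome, "ambiguous_palindrome", proxy_of)
        if lo <= exposure.eaf <= hi or lo <= outcome.eaf <= hi:
            return _dropped(exposure, outcome, "ambiguous_palindrome", proxy_of)
        n_flips = 0
        eaf_aligned = outcome.eaf
        if ea_y != ea_x:  # listed order is swapped relative to the exposure
            n_flips += 1
            eaf_aligned = 1.0 - eaf_aligned
        if (exposure.eaf < 0.5) != (eaf_aligned < 0.5):  # strand disagreement
            n_flips += 1
        flip = n_flips % 2 == 1
        action = "flipped" if flip else "palindromic_resolved"
    else:
        comp = {COMPLEMENT[ea_y], COMPLEMENT[oa_y]}
        if {ea_y, oa_y} == x_set:
            flip = ea_y != ea_x
        elif comp == x_set:
            flip = COMPLEMENT[ea_y] != ea_x
        else:
            return _dropped(exposure, outcome, "allele_mismatch", proxy_of)
        action = "flipped" if flip else "kept"

    out_beta = -outcome.beta if flip else outcome.beta
    out_eaf = outcome.eaf
    if flip and out_eaf is not None:
        out_eaf = 1.0 - out_eaf
    return HarmonisedInstrument(
        variant_id=exposure.variant_id,
        effect_allele=ea_x,
        other_allele=oa_x,
        exposure_beta=exposure.beta,
        exposure_se=exposure.se,
        exposure_eaf=exposure.eaf,
        outcome_beta=out_beta,
        outcome_se=outcome.se,
        outcome_eaf=out_eaf,
        action=action,
        proxy_of=proxy_of,
    )


def outcome_record(inst: HarmonisedInstrument, chrom: str = "1", pos: int = 1) -> VariantAssociation:
    """Rebuild the outcome side of a harmonised instrument as an association.

    Convenience for re-harmonising (idempotence checks) and for writing the
    aligned outcome back out. The p-value is recomputed from beta/se.
    """
    from scipy.stats import norm

    pval = float(2 * norm.sf(abs(inst.outcome_beta) / inst.outcome_se)) if inst.outcome_beta else 1.0
    return VariantAssociation(
        variant_id=inst.variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=inst.effect_allele,
        other_allele=inst.other_allele,
        eaf=inst.outcome_eaf,
        beta=inst.outcome_beta,
        se=inst.outcome_se,
        pval=max(pval, 5e-324),
        n=None,
    )
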