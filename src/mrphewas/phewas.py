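"""Phenome-wide MR screening, multiple-testing correction and reverse MR.

``run_screen`` chains instrument selection, LD clumping, harmonisation (with
LD-proxy substitution for instruments missing from the outcome GWAS) and
estimation for every exposure in a batch, never letting one failing exposure
abort the rest. The significance threshold divides alpha by the effective
number of independent traits, estimated by spectral decomposition of the
trait-trait correlation matrix (Nyholt's spectral method or the Li–Ji
variant); with a single trait or too little shared data the Bonferroni
threshold is used. ``reverse_screen`` swaps the roles to test whether the
disease drives the putative exposures instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .gwas_data import (
    HarmonisedInstrument,
    TraitInfo,
    VariantAssociation,
    harmonise_pair,
    read_summary_stats,
    select_instruments,
)
from .ld_reference import ReferencePanel, clump, find_proxy
from .mr_core import (
    EstimationError,
    InsufficientInstrumentsError,
    MREstimate,
    MRInput,
    Z95,
    cochran_q,
    egger,
    ivw,
    max_likelihood,
    wald_ratio,
)

logger = logging.getLogger(__name__)

#: the TSV columns a screen emits (machine-readable analogue of a results table)
SCREEN_COLUMNS = [
    "exposure_id", "outcome_id", "method", "nsnp", "beta", "se", "ci_low",
    "ci_high", "pval", "q_pval", "ml_het_pval", "egger_intercept",
    "egger_intercept_pval", "passes_threshold", "harmonisation_failed",
]


class DataError(ValueError):
    """Input data cannot support the requested computation."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds governing a phenome-wide screen."""

    p_instrument: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    proxy_r2: float = 0.8
    palindrome_eaf_window: float = 0.08
    alpha: float = 0.05
    correction_method: str = "nyholt_spd"  # nyholt_spd | li_ji
    significance_threshold: float | None = None  # overrides Meff estimation
    reverse_threshold: float | None = None  # defaults to the forward threshold


@dataclass(frozen=True)
class MeffResult:
    """Effective number of independent tests among correlated traits."""

    m_traits: int
    eigenvalues: tuple[float, ...]
    meff: float
    threshold: float
    method: str


@dataclass
class ScreenRow:
    """One exposure's result in the screen (or its failure record)."""

    exposure_id: str
    outcome_id: str
    method: str | None = None
    nsnp: int = 0
    beta: float | None = None
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    pval: float | None = None
    q_pval: float | None = None
    ml_het_pval: float | None = None
    egger_intercept: float | None = None
    egger_intercept_pval: float | None = None
    passes_threshold: bool = False
    harmonisation_failed: bool = False
    error: str = ""
    instruments: list[HarmonisedInstrument] = field(default_factory=list)


@dataclass
class ScreenResult:
    """All rows of a screen plus the multiple-testing bookkeeping."""

    rows: list[ScreenRow]
    threshold: float
    meff: MeffResult | None
    outcome_id: str

    @property
    def hits(self) -> list[ScreenRow]:
        return [r for r in self.rows if r.passes_threshold]

    def to_frame(self) -> pd.DataFrame:
        recs = []
        for r in self.rows:
            recs.append({c: getattr(r, c) for c in SCREEN_COLUMNS})
        return pd.DataFrame(recs, columns=SCREEN_COLUMNS)


# ---------------------------------------------------------------------------
# Effective number of tests


def effective_tests(
    z_table, method: str = "nyholt_spd", alpha: float = 0.05
) -> MeffResult:
    """Effective number of independent traits from a z-score matrix.

    ``z_table`` holds per-trait z-scores over shared, approximately
    independent variants (rows: variants, columns: traits). The trait-trait
    correlation matrix is the Pearson correlation of its columns; its
    eigenvalues feed either Nyholt's spectral estimator
    ``meff = 1 + (M - 1) (1 - var(lambda) / M)`` or the Li–Ji estimator
    ``meff = sum I(lambda >= 1) + frac(lambda)``. The corrected threshold is
    ``alpha / meff``.
    """
    z = np.asarray(z_table, dtype=float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise DataError("effective_tests needs a 2-D table with >= 2 trait columns")
    if z.shape[0] < 30:
        logger.warning(
            "effective_tests: only %d shared variants; correlation estimate is noisy",
            z.shape[0],
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(z, rowvar=False)
    if not np.all(np.isfinite(corr)):
        raise DataError("non-finite trait correlations (constant z column?)")
    lam = np.linalg.eigvalsh(corr)[::-1]
    m = z.shape[1]
    if method == "nyholt_spd":
        meff = 1.0 + (m - 1) * (1.0 - float(np.var(lam, ddof=1)) / m)
    elif method == "li_ji":
        meff = float(np.sum((lam >= 1).astype(float) + (lam - np.floor(lam))))
    else:
        raise ValueError(f"unknown correction method {method!r}")
    meff = min(max(meff, 1.0), float(m))
    return MeffResult(
        m_traits=m,
        eigenvalues=tuple(float(v) for v in lam),
        meff=meff,
        threshold=alpha / meff,
        method=method,
    )


# ---------------------------------------------------------------------------
# Screening machinery


def _load_source(source, trait: TraitInfo | None = None) -> list[VariantAssociation]:
    if isinstance(source, (str,)) or hasattr(source, "__fspath__"):
        return read_summary_stats(source, trait=trait)
    return list(source)


def _proxy_outcome_record(
    panel: ReferencePanel,
    target_id: str,
    proxy: VariantAssociation,
    r: float,
) -> VariantAssociation | None:
    """Re-express a proxy's outcome association at the missing target variant.

    The proxy record is first aligned to the panel's dosage-counted allele
    (allele_b) of the proxy variant, then the sign of the LD correlation
    carries the effect over to the target's allele_b. The target's EAF is
    taken from the panel. This is bookkeeping, not re-estimation: beta/se
    magnitudes are reused as-is.
    """
    from .gwas_data import COMPLEMENT

    pinfo = panel.info(proxy.variant_id)
    pa, pb = str(pinfo["allele_a"]), str(pinfo["allele_b"])
    ea, oa = proxy.effect_allele, proxy.other_allele
    if {ea, oa} == {pa, pb}:
        aligned_effect = ea
    elif {COMPLEMENT[ea], COMPLEMENT[oa]} == {pa, pb}:
        aligned_effect = COMPLEMENT[ea]
    else:
        logger.info("proxy %s: alleles do not match panel; skipped", proxy.variant_id)
        return None
    beta = proxy.beta
    if aligned_effect != pb:
        beta = -beta
    if r < 0:
        beta = -beta
    tinfo = panel.info(target_id)
    z = abs(beta) / proxy.se
    pval = max(float(2 * stats.norm.sf(z)), 5e-324)
    return VariantAssociation(
        variant_id=target_id,
        chrom=str(tinfo["chrom"]),
        pos=int(tinfo["pos"]),
        effect_allele=str(tinfo["allele_b"]),
        other_allele=str(tinfo["allele_a"]),
        eaf=panel.allele_b_frequency(target_id),
        beta=beta,
        se=proxy.se,
        pval=pval,
        n=proxy.n,
    )


def harmonise_against_outcome(
    instruments: Sequence[VariantAssociation],
    outcome_by_id: Mapping[str, VariantAssociation],
    panel: ReferencePanel,
    config: ScreenConfig,
) -> list[HarmonisedInstrument]:
    """Harmonise instruments, substituting LD proxies for missing variants."""
    out: list[HarmonisedInstrument] = []
    for a in instruments:
        if a.variant_id in outcome_by_id:
            out.append(
                harmonise_pair(
                    a, outcome_by_id[a.variant_id], config.palindrome_eaf_window
                )
            )
            continue
        proxy_pair = None
        if a.variant_id in panel:
            window_bp = config.clump_window_kb * 1000.0
            candidates = [
                vid
                for vid, rec in outcome_by_id.items()
                if vid in panel
                and rec.chrom == a.chrom
                and abs(rec.pos - a.pos) <= window_bp
            ]
            proxy_pair = find_proxy(panel, a.variant_id, candidates, config.proxy_r2)
        if proxy_pair is None:
            out.append(
                HarmonisedInstrument(
                    variant_id=a.variant_id,
                    effect_allele=a.effect_allele,
                    other_allele=a.other_allele,
                    exposure_beta=a.beta,
                    exposure_se=a.se,
                    exposure_eaf=a.eaf,
                    outcome_beta=0.0,
                    outcome_se=1.0,
                    outcome_eaf=None,
                    action="dropped",
                    drop_reason="no_outcome_variant",
                )
            )
            continue
        proxy_id, ld = proxy_pair
        oriented = _proxy_outcome_record(panel, a.variant_id, outcome_by_id[proxy_id], ld.r)
        if oriented is None:
            out.append(
                HarmonisedInstrument(
                    variant_id=a.variant_id,
                    effect_allele=a.effect_allele,
                    other_allele=a.other_allele,
                    exposure_beta=a.beta,
                    exposure_se=a.se,
                    exposure_eaf=a.eaf,
                    outcome_beta=0.0,
                    outcome_se=1.0,
                    outcome_eaf=None,
                    action="dropped",
                    drop_reason="proxy_allele_mismatch",
                )
            )
            continue
        out.append(
            harmonise_pair(
                a, oriented, config.palindrome_eaf_window, proxy_of=proxy_id
            )
        )
    return out


def _estimate_row(
    row: ScreenRow,
    exposure: TraitInfo,
    outcome: TraitInfo,
    kept: Sequence[HarmonisedInstrument],
) -> None:
    mr_input = MRInput(exposure, outcome, kept)
    est: MREstimate = wald_ratio(kept[0]) if len(kept) == 1 else ivw(mr_input)
    row.method = est.method
    row.nsnp = est.nsnp
    row.beta, row.se = est.beta, est.se
    row.ci_low, row.ci_high = est.ci_low, est.ci_high
    row.pval = est.pval
    if len(kept) >= 2:
        try:
            row.q_pval = cochran_q(mr_input).pval
        except EstimationError:
            row.q_pval = None
        try:
            _, het = max_likelihood(mr_input)
            row.ml_het_pval = het.pval
        except EstimationError:
            row.ml_het_pval = None
    if len(kept) >= 3:
        try:
            eg = egger(mr_input)
            row.egger_intercept = eg.intercept
            row.egger_intercept_pval = eg.intercept_pval
        except EstimationError:
            pass


def analyse_exposure(
    exposure: TraitInfo,
    exposure_assocs: Sequence[VariantAssociation],
    outcome: TraitInfo,
    outcome_by_id: Mapping[str, VariantAssociation],
    panel: ReferencePanel,
    config: ScreenConfig,
) -> ScreenRow:
    """Select, clump, harmonise and estimate for a single exposure."""
    row = ScreenRow(exposure_id=exposure.trait_id, outcome_id=outcome.trait_id)
    try:
        selected = select_instruments(exposure_assocs, config.p_instrument)
        clumped = clump(selected, panel, config.clump_r2, config.clump_window_kb)
        harmonised = harmonise_against_outcome(clumped, outcome_by_id, panel, config)
        row.instruments = harmonised
        kept = [h for h in harmonised if h.usable]
        if not kept:
            row.harmonisation_failed = True
            return row
        _estimate_row(row, exposure, outcome, kept)
    except Exception as exc:  # per-row capture; the batch must not abort
        row.error = f"{type(exc).__name__}: {exc}"
        logger.warning("screen: exposure %s failed: %s", exposure.trait_id, row.error)
    return row


def _shared_z_table(
    full_stats: Mapping[str, Mapping[str, VariantAssociation]],
    instrument_ids: set[str],
) -> np.ndarray | None:
    """z-score matrix over instruments present in every exposure's GWAS."""
    if len(full_stats) < 2:
        return None
    shared = sorted(
        vid
        for vid in instrument_ids
        if all(vid in stats_map for stats_map in full_stats.values())
    )
    if len(shared) < 2:
        return None
    cols = []
    for trait_id in sorted(full_stats):
        stats_map = full_stats[trait_id]
        cols.append([stats_map[v].zscore for v in shared])
    return np.array(cols, dtype=float).T


def run_screen(
    exposures: Sequence[tuple[TraitInfo, object]],
    outcome: tuple[TraitInfo, object],
    panel: ReferencePanel,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Batch MR screen of many exposures against one outcome.

    ``exposures`` pairs each trait with its summary-statistic source (a path
    or an in-memory association list); likewise for ``outcome``. Exposures
    whose every instrument drops during harmonisation are reported with
    ``harmonisation_failed`` set. Rows come back sorted by p-value, and
    ``passes_threshold`` compares against the Meff-corrected (or configured)
    threshold.
    """
    outcome_trait, outcome_source = outcome
    outcome_assocs = _load_source(outcome_source, outcome_trait)
    outcome_by_id = {a.variant_id: a for a in outcome_assocs}

    rows: list[ScreenRow] = []
    full_stats: dict[str, dict[str, VariantAssociation]] = {}
    instrument_ids: set[str] = set()
    for trait, source in exposures:
        assocs = _load_source(source, trait)
        full_stats[trait.trait_id] = {a.variant_id: a for a in assocs}
        row = analyse_exposure(trait, assocs, outcome_trait, outcome_by_id, panel, config)
        instrument_ids.update(h.variant_id for h in row.instruments if h.usable)
        rows.append(row)

    meff: MeffResult | None = None
    if config.significance_threshold is not None:
        threshold = config.significance_threshold
    else:
        z = _shared_z_table(full_stats, instrument_ids)
        if z is not None:
            try:
                meff = effective_tests(z, config.correction_method, config.alpha)
                threshold = meff.threshold
            except DataError:
                threshold = config.alpha / max(len(exposures), 1)
                logger.info("screen: Meff failed, Bonferroni threshold %.3g", threshold)
        else:
            threshold = config.alpha / max(len(exposures), 1)
            logger.info(
                "screen: too few shared variants for Meff, Bonferroni threshold %.3g",
                threshold,
            )

    for r in rows:
        r.passes_threshold = r.pval is not None and r.pval < threshold
    rows.sort(key=lambda r: (r.pval is None, r.pval if r.pval is not None else 0.0, r.exposure_id))
    return ScreenResult(rows=rows, threshold=threshold, meff=meff, outcome_id=outcome_trait.trait_id)


def reverse_screen(
    outcome_as_exposure: tuple[TraitInfo, object],
    former_exposures: Sequence[tuple[TraitInfo, object]],
    panel: ReferencePanel,
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """MR with roles swapped: the disease instruments each former exposure.

    Each returned row's ``exposure_id`` names the trait being tested as a
    downstream outcome of the disease. The same selection/clumping/
    harmonisation machinery applies.
    """
    disease_trait, disease_source = outcome_as_exposure
    disease_assocs = _load_source(disease_source, disease_trait)

    rows: list[ScreenRow] = []
    for trait, source in former_exposures:
        target_assocs = _load_source(source, trait)
        target_by_id = {a.variant_id: a for a in target_assocs}
        row = analyse_exposure(
            disease_trait, disease_assocs, trait, target_by_id, panel, config
        )
        row.exposure_id = trait.trait_id  # the trait under reverse test
        row.outcome_id = disease_trait.trait_id
        rows.append(row)

    threshold = (
        config.reverse_threshold
        if config.reverse_threshold is not None
        else (config.significance_threshold or config.alpha / max(len(former_exposures), 1))
    )
    for r in rows:
        r.passes_threshold = r.pval is not None and r.pval < threshold
    rows.sort(key=lambda r: (r.pval is None, r.pval if r.pval is not None else 0.0, r.exposure_id))
    return ScreenResult(
        rows=rows, threshold=threshold, meff=None, outcome_id=disease_trait.trait_id
    )


def flag_reverse_causation(
    forward: ScreenResult, reverse: ScreenResult
) -> list[str]:
    """Trait ids that pass forward AND reverse thresholds (possible reverse causation)."""
    reverse_pass = {r.exposure_id for r in reverse.rows if r.passes_threshold}
    return sorted(
        r.exposure_id for r in forward.rows if r.passes_threshold and r.exposure_id in reverse_pass
    )
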