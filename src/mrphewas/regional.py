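"""Per-region Bayesian colocalization and a conditional scan for secondary signals.

Colocalization follows the approximate-Bayes-factor construction: each
variant's association evidence is summarised by a Wakefield log-ABF, and the
per-variant ABFs are combined over the five causal configurations of a
region pair — no causal variant (H0), a causal variant for one trait only
(H1/H2), two distinct causal variants (H3), or one shared causal variant
(H4). All sums run in log space.

The conditional scan approximates a summary-statistic joint model: given an
index variant, every other variant's z-score is residualised on the index
through the reference-panel LD correlation, flagging any region that retains
a genome-wide-significant signal after conditioning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .gwas_data import VariantAssociation
from .ld_reference import PanelLookupError, ReferencePanel, ld_r

logger = logging.getLogger(__name__)

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


class RegionDataError(ValueError):
    """Regional inputs cannot support the analysis (e.g. empty intersection)."""


@dataclass(frozen=True)
class ColocPriors:
    """Per-variant causal priors and prior effect variances.

    ``p1``/``p2`` are the prior probabilities that a given variant is causal
    for trait 1 / trait 2 only; ``p12`` that it is causal for both. ``w1``/
    ``w2`` are the prior variances of true effect sizes (0.2^2 on both trait
    scales by default).
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w1: float = 0.04
    w2: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2) < 1):
            raise ValueError("priors must satisfy 0 < p12 <= min(p1, p2) < 1")
        if self.w1 <= 0 or self.w2 <= 0:
            raise ValueError("prior effect variances must be positive")


@dataclass(frozen=True)
class ColocResult:
    """Posterior probabilities of the five colocalization hypotheses."""

    pp: dict[str, float]
    nsnp: int
    priors: ColocPriors


@dataclass(frozen=True)
class ConditionalResult:
    """Per-variant association statistics conditional on an index variant."""

    index: str
    table: pd.DataFrame  # variant_id, pos, z_marginal, z_conditional, p_conditional
    secondary_signal: bool
    skipped: tuple[str, ...]  # |r| >= 0.99 vs the index; not testable


def wakefield_abf(z: float, se: float, w: float) -> float:
    """Wakefield's approximate log Bayes factor in favour of association.

    With sampling variance ``V = se^2`` and shrinkage ``lambda = w/(V+w)``:
    ``log ABF = 0.5 * (log(1 - lambda) + z^2 * lambda)``; monotone increasing
    in ``|z|``.
    """
    if se <= 0 or w <= 0:
        raise ValueError(f"se and w must be positive, got se={se}, w={w}")
    v = se * se
    lam = w / (v + w)
    return 0.5 * (math.log1p(-lam) + z * z * lam)


def _log_abfs(assocs: Sequence[VariantAssociation], w: float) -> np.ndarray:
    return np.array([wakefield_abf(a.beta / a.se, a.se, w) for a in assocs])


def coloc_abf(
    region1: Sequence[VariantAssociation],
    region2: Sequence[VariantAssociation],
    priors: ColocPriors = ColocPriors(),
) -> ColocResult:
    """Approximate-Bayes-factor colocalization of two traits over one region.

    The analysis is restricted to variants present in both regions
    (matched on variant id); ``nsnp`` reports the intersection size. The
    unnormalised hypothesis masses are ``[1, p1*S1, p2*S2,
    p1*p2*(S1*S2 - S12), p12*S12]`` with ``S1 = sum exp(lbf1)``,
    ``S2 = sum exp(lbf2)`` and ``S12 = sum exp(lbf1 + lbf2)``, all computed
    in log space; a (numerically) negative H3 mass is guarded to zero.
    """
    by_id2 = {a.variant_id: a for a in region2}
    pairs = [(a, by_id2[a.variant_id]) for a in region1 if a.variant_id in by_id2]
    if not pairs:
        raise RegionDataError("regions share no variants; colocalization undefined")
    r1 = [p[0] for p in pairs]
    r2 = [p[1] for p in pairs]
    lbf1 = _log_abfs(r1, priors.w1)
    lbf2 = _log_abfs(r2, priors.w2)

    log_s1 = float(logsumexp(lbf1))
    log_s2 = float(logsumexp(lbf2))
    log_s12 = float(logsumexp(lbf1 + lbf2))

    log_masses = np.full(5, -np.inf)
    log_masses[0] = 0.0
    log_masses[1] = math.log(priors.p1) + log_s1
    log_masses[2] = math.log(priors.p2) + log_s2
    log_cross = log_s1 + log_s2
    if log_cross > log_s12:
        # log(S1*S2 - S12) via the complementary log-sum trick
        log_h3 = log_cross + math.log1p(-math.exp(log_s12 - log_cross))
        log_masses[3] = math.log(priors.p1) + math.log(priors.p2) + log_h3
    else:
        logger.warning("coloc: S1*S2 <= S12 numerically; H3 mass set to zero")
    log_masses[4] = math.log(priors.p12) + log_s12

    log_total = float(logsumexp(log_masses))
    pp = np.exp(log_masses - log_total)
    return ColocResult(
        pp={h: float(p) for h, p in zip(HYPOTHESES, pp)},
        nsnp=len(pairs),
        priors=priors,
    )


def conditional_scan(
    region: Sequence[VariantAssociation],
    panel: ReferencePanel,
    index: str = "auto",
    window_kb: float = 1_000,
    p_secondary: float = 5e-8,
) -> ConditionalResult:
    """Scan a region for association signals left after conditioning on an index.

    ``index="auto"`` picks the variant with the largest |z| (smallest
    marginal p) within the window. For each variant with panel LD ``r`` to
    the index, the conditional z is ``(z - r * z_index) / sqrt(1 - r^2)``;
    variants in near-perfect LD (``|r| >= 0.99``) are reported as skipped
    rather than errored, and variants absent from the panel are left out with
    a log entry. ``secondary_signal`` is true when any non-index, non-skipped
    variant stays below ``p_secondary`` after conditioning.
    """
    if not region:
        raise RegionDataError("empty region")
    region = list(region)
    half_window_bp = window_kb * 1000.0 / 2.0

    if index == "auto":
        index = max(region, key=lambda a: abs(a.zscore)).variant_id
    if index not in panel:
        raise PanelLookupError(f"index variant {index!r} not in reference panel")
    by_id = {a.variant_id: a for a in region}
    if index not in by_id:
        raise RegionDataError(f"index variant {index!r} not in the region")
    idx_assoc = by_id[index]
    z_index = idx_assoc.zscore

    rows = []
    skipped: list[str] = []
    n_unmapped = 0
    for a in region:
        if abs(a.pos - idx_assoc.pos) > half_window_bp:
            continue
        z = a.zscore
        if a.variant_id == index:
            rows.append((a.variant_id, a.pos, z, 0.0, 1.0, True))
            continue
        if a.variant_id not in panel:
            n_unmapped += 1
            continue
        r = ld_r(panel, index, a.variant_id).r
        if abs(r) >= 0.99:
            skipped.append(a.variant_id)
            continue
        z_cond = (z - r * z_index) / math.sqrt(1.0 - r * r)
        p_cond = float(2 * norm.sf(abs(z_cond)))
        rows.append((a.variant_id, a.pos, z, z_cond, p_cond, False))
    if n_unmapped:
        logger.info("conditional_scan: %d region variant(s) not in panel", n_unmapped)

    table = pd.DataFrame(
        rows,
        columns=["variant_id", "pos", "z_marginal", "z_conditional", "p_conditional", "is_index"],
    )
    non_index = table.loc[~table["is_index"]]
    secondary = bool((non_index["p_conditional"] < p_secondary).any())
    return ConditionalResult(
        index=index,
        table=table,
        secondary_signal=secondary,
        skipped=tuple(skipped),
    )


def region_scatter(
    region: Sequence[VariantAssociation],
    panel: ReferencePanel,
    index: str,
) -> pd.DataFrame:
    """Plain regional scatter table: position, -log10 p, and r^2 vs the index.

    A text stand-in for a regional association plot; p-values are recomputed
    from beta/se.
    """
    rows = []
    for a in region:
        p = max(float(2 * norm.sf(abs(a.zscore))), 5e-324)
        r2 = np.nan
        if a.variant_id in panel and index in panel:
            r2 = ld_r(panel, index, a.variant_id).r2
        rows.append((a.variant_id, a.pos, -math.log10(p), r2))
    return pd.DataFrame(rows, columns=["variant_id", "pos", "neglog10_p", "r2_index"])
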