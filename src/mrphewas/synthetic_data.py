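"""Simulated GWAS cohorts with known causal structure.

Every pipeline stage is testable without external downloads: the generator
draws individual-level two-sample cohorts (disjoint exposure and outcome
samples, plus a held-out reference panel), runs per-SNP regressions, and
returns standard summary-statistic records together with a truth record of
all generative parameters.

Defaults mirror the study setting the package targets: cohorts of 20,000,
100 SNPs of which 30 instrument the exposure (h2 = 0.3), a causal effect of
0.4 on the outcome's log-odds, an unmeasured confounder acting on both
traits, and a binary outcome at 2% prevalence fitted by per-SNP logistic
regression. The mediator block reproduces a BMI->protein->outcome design
(step1 = 0.17, step2 = 0.42, direct = 0.33), and the regional block builds
an AR(1)-correlated LD block with shared or distinct causal variants at a
target association z of about 8.

Randomness comes exclusively from ``numpy.random.default_rng`` (PCG64), so a
fixed seed reproduces outputs bit-for-bit across platforms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize, stats
from scipy.special import expit, logit

from .gwas_data import TraitInfo, VariantAssociation
from .ld_reference import ReferencePanel

import pandas as pd

logger = logging.getLogger(__name__)

#: non-palindromic allele pairs assigned to simulated SNPs (allele_a, allele_b)
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))


class ConfigurationError(ValueError):
    """A simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class MediatorBlock:
    """Generative parameters of the exposure -> mediator -> outcome path.

    ``step1`` scales the exposure's contribution to the mediator; ``step2``
    the mediator's contribution to the outcome; ``direct`` is the residual
    direct exposure effect. The mediator also carries its own independent
    genetic component (``m_snps`` SNPs explaining ``h2`` of its variance) so
    that it can be instrumented in its own right. The generative proportion
    mediated is ``step1*step2 / (step1*step2 + direct)``.
    """

    step1: float = 0.17
    step2: float = 0.42
    direct: float = 0.33
    m_snps: int = 10
    h2: float = 0.2


@dataclass(frozen=True)
class RegionBlock:
    """Generative parameters of an LD-structured region pair."""

    m_variants: int = 100
    rho: float = 0.9  # latent AR(1) correlation between adjacent variants
    sharing: str = "shared"  # shared | distinct | none
    spacing_bp: int = 5_000
    z_target: float = 8.0
    n_sample: int = 10_000

    def __post_init__(self) -> None:
        if self.sharing not in ("shared", "distinct", "none"):
            raise ConfigurationError(f"unknown sharing mode {self.sharing!r}")
        if not (0 <= self.rho < 1):
            raise ConfigurationError("rho must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationConfig:
    """Full generative configuration for the two-sample simulators."""

    seed: int = 0
    n_exposure_sample: int = 20_000
    n_outcome_sample: int = 20_000
    n_panel: int = 1_000
    m_snps: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_instruments: int = 30
    h2_exposure: float = 0.3
    theta: float = 0.4
    confounder_effect_exposure: float = 0.3
    confounder_effect_outcome: float = 0.2
    pleiotropy: str = "none"  # none | balanced | directional
    pleiotropy_magnitude: float = 0.1
    outcome_type: str = "binary"
    prevalence: float = 0.02
    #: outcome-specific risk loci (disjoint from the exposure's instruments),
    #: emulating a disease with its own genetic architecture so the reverse
    #: direction can be instrumented; per-allele effect on the outcome's
    #: linear predictor (log-odds for a binary outcome)
    n_outcome_snps: int = 10
    outcome_snp_beta: float = 0.8
    mediator: MediatorBlock = field(default_factory=MediatorBlock)
    region: RegionBlock = field(default_factory=RegionBlock)

    def __post_init__(self) -> None:
        if not (0 < self.h2_exposure < 1):
            raise ConfigurationError("h2_exposure must lie in (0, 1)")
        if not (0 < self.prevalence < 0.5):
            raise ConfigurationError("prevalence must lie in (0, 0.5)")
        if self.n_causal_instruments + self.n_outcome_snps > self.m_snps:
            raise ConfigurationError(
                "causal instruments plus outcome-specific SNPs exceed m_snps"
            )
        if self.h2_exposure + self.confounder_effect_exposure**2 >= 1:
            raise ConfigurationError("h2 + confounder variance exceed the exposure variance")
        if self.pleiotropy not in ("none", "balanced", "directional"):
            raise ConfigurationError(f"unknown pleiotropy mode {self.pleiotropy!r}")
        if self.outcome_type not in ("continuous", "binary"):
            raise ConfigurationError(f"unknown outcome_type {self.outcome_type!r}")


@dataclass
class TwoSampleDataset:
    exposure: list[VariantAssociation]
    outcome: list[VariantAssociation]
    truth: dict
    panel: ReferencePanel
    exposure_trait: TraitInfo
    outcome_trait: TraitInfo


@dataclass
class MediationDataset:
    exposure: list[VariantAssociation]
    mediator: list[VariantAssociation]
    outcome: list[VariantAssociation]
    truth: dict
    panel: ReferencePanel


@dataclass
class RegionPairDataset:
    trait1: list[VariantAssociation]
    trait2: list[VariantAssociation]
    panel: ReferencePanel
    truth: dict


# ---------------------------------------------------------------------------
# Per-SNP association machinery (vectorised across SNPs)


def _draw_genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray) -> np.ndarray:
    return rng.binomial(2, mafs, size=(n, len(mafs))).astype(float)


def linear_gwas(genotypes: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simple linear regression of ``y`` on each dosage column.

    Closed-form slope/SE per SNP (equivalent to per-column OLS with an
    intercept); p-values from the t distribution on n - 2 df.
    """
    n = len(y)
    gc = genotypes - genotypes.mean(axis=0)
    yc = y - y.mean()
    ssg = np.sum(gc * gc, axis=0)
    if np.any(ssg == 0):
        raise ConfigurationError("constant genotype column in GWAS cohort")
    beta = gc.T @ yc / ssg
    rss = np.sum(yc * yc) - beta**2 * ssg
    sigma2 = np.maximum(rss, 0.0) / (n - 2)
    se = np.sqrt(sigma2 / ssg)
    tstat = beta / se
    pval = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    return beta, se, np.maximum(pval, 5e-324)


def logistic_gwas(
    genotypes: np.ndarray,
    y: np.ndarray,
    max_iter: int = 25,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP logistic regression (intercept + dosage), Newton-iterated.

    All SNPs are fitted simultaneously: each column's 2x2 information matrix
    is accumulated and inverted in closed form. Betas are log-odds per
    allele; SEs from the inverse information; p-values two-sided normal.
    """
    n, m = genotypes.shape
    ybar = float(np.clip(y.mean(), 1e-10, 1 - 1e-10))
    a = np.full(m, logit(ybar))
    b = np.zeros(m)
    yv = y.astype(float)[:, None]
    for _ in range(max_iter):
        eta = a[None, :] + genotypes * b[None, :]
        p = expit(eta)
        resid = yv - p
        ga = resid.sum(axis=0)
        gb = np.sum(genotypes * resid, axis=0)
        wgt = p * (1.0 - p)
        saa = wgt.sum(axis=0)
        sab = np.sum(wgt * genotypes, axis=0)
        sbb = np.sum(wgt * genotypes * genotypes, axis=0)
        det = saa * sbb - sab * sab
        da = (sbb * ga - sab * gb) / det
        db = (saa * gb - sab * ga) / det
        a += da
        b += db
        if max(np.max(np.abs(da)), np.max(np.abs(db))) < tol:
            break
    eta = a[None, :] + genotypes * b[None, :]
    p = expit(eta)
    wgt = p * (1.0 - p)
    saa = wgt.sum(axis=0)
    sab = np.sum(wgt * genotypes, axis=0)
    sbb = np.sum(wgt * genotypes * genotypes, axis=0)
    det = saa * sbb - sab * sab
    se = np.sqrt(saa / det)
    z = b / se
    pval = 2 * stats.norm.sf(np.abs(z))
    return b, se, np.maximum(pval, 5e-324)


def _solve_intercept(linear_predictor: np.ndarray, prevalence: float) -> float:
    """Intercept making the mean Bernoulli probability hit the prevalence."""

    def gap(alpha: float) -> float:
        return float(expit(alpha + linear_predictor).mean() - prevalence)

    try:
        return optimize.brentq(gap, -30.0, 30.0)
    except ValueError as exc:
        raise ConfigurationError(
            f"no intercept achieves prevalence {prevalence} with the chosen effects"
        ) from exc


def _variant_table(rng: np.random.Generator, m: int, chrom: str | None = None,
                   start: int = 100_000, spacing: int = 100_000,
                   prefix: str = "rs") -> pd.DataFrame:
    """Variant metadata for ``m`` simulated SNPs.

    With ``chrom=None`` (unlinked SNPs) variants cycle over 22 autosomes and
    same-chromosome neighbours sit 20 Mb apart — outside any standard clump
    window, as independent GWAS instruments are in practice. A fixed
    ``chrom`` lays variants out contiguously (used for LD-block regions).
    """
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    idx = np.arange(m)
    if chrom is None:
        chroms = [str(1 + i % 22) for i in idx]
        pos = 1_000_000 + 20_000_000 * (idx // 22)
    else:
        chroms = [chrom] * m
        pos = start + spacing * idx
    return pd.DataFrame(
        {
            "variant_id": [f"{prefix}{i + 1}" for i in idx],
            "chrom": chroms,
            "pos": pos,
            "allele_a": [_ALLELE_PAIRS[i][0] for i in pair_idx],
            "allele_b": [_ALLELE_PAIRS[i][1] for i in pair_idx],
        }
    )


def _assocs(
    variants: pd.DataFrame,
    genotypes: np.ndarray,
    beta: np.ndarray,
    se: np.ndarray,
    pval: np.ndarray,
    n: int,
) -> list[VariantAssociation]:
    eaf = genotypes.mean(axis=0) / 2.0
    out = []
    for i, row in enumerate(variants.itertuples(index=False)):
        out.append(
            VariantAssociation(
                variant_id=row.variant_id,
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=row.allele_b,
                other_allele=row.allele_a,
                eaf=float(eaf[i]),
                beta=float(beta[i]),
                se=float(se[i]),
                pval=float(min(max(pval[i], 5e-324), 1.0)),
                n=float(n),
            )
        )
    return out


def _instrument_effects(
    rng: np.random.Generator, mafs: np.ndarray, causal_idx: np.ndarray, h2: float
) -> np.ndarray:
    """Per-allele effects on the causal SNPs, scaled to explain ``h2``.

    Each causal SNP explains an equal share ``h2 / k`` of the trait variance
    (random effect direction), so instrument strength is controlled by the
    configuration rather than left to chance.
    """
    b = np.zeros(len(mafs))
    k = len(causal_idx)
    var_g = 2.0 * mafs[causal_idx] * (1.0 - mafs[causal_idx])
    signs = rng.choice([-1.0, 1.0], size=k)
    b[causal_idx] = signs * np.sqrt((h2 / k) / var_g)
    return b


def _pleiotropy_effects(
    rng: np.random.Generator, config: SimulationConfig, causal_idx: np.ndarray, m: int
) -> np.ndarray:
    a = np.zeros(m)
    if config.pleiotropy == "balanced":
        a[causal_idx] = rng.normal(0.0, config.pleiotropy_magnitude, size=len(causal_idx))
    elif config.pleiotropy == "directional":
        a[causal_idx] = np.abs(
            rng.normal(0.0, config.pleiotropy_magnitude, size=len(causal_idx))
        )
    return a


# ---------------------------------------------------------------------------
# Simulators


def simulate_two_sample(config: SimulationConfig = SimulationConfig()) -> TwoSampleDataset:
    """Two non-overlapping GWAS cohorts with a known exposure -> outcome effect.

    The exposure is a unit-variance continuous trait built from its causal
    SNPs, a standard-normal confounder and noise; the outcome is either
    continuous or a Bernoulli draw from a logistic model whose intercept is
    solved numerically for the target prevalence. Summary statistics come
    from per-SNP linear (exposure cohort) and logistic or linear (outcome
    cohort) regressions; a held-out sample forms the reference panel.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    mafs = rng.uniform(*config.maf_range, size=m)
    variants = _variant_table(rng, m)
    both = rng.choice(m, size=config.n_causal_instruments + config.n_outcome_snps, replace=False)
    causal_idx = np.sort(both[: config.n_causal_instruments])
    outcome_idx = np.sort(both[config.n_causal_instruments :])
    b = _instrument_effects(rng, mafs, causal_idx, config.h2_exposure)
    a = _pleiotropy_effects(rng, config, causal_idx, m)
    d = np.zeros(m)  # outcome-specific risk loci
    if len(outcome_idx):
        d[outcome_idx] = config.outcome_snp_beta * rng.choice([-1.0, 1.0], size=len(outcome_idx))

    gx, cx = config.confounder_effect_exposure, config.confounder_effect_outcome
    resid_x = 1.0 - config.h2_exposure - gx**2

    # exposure cohort
    g1 = _draw_genotypes(rng, config.n_exposure_sample, mafs)
    conf1 = rng.normal(size=config.n_exposure_sample)
    x1 = g1 @ b + gx * conf1 + rng.normal(0, np.sqrt(resid_x), size=config.n_exposure_sample)
    bx, sx, px = linear_gwas(g1, x1)
    exposure = _assocs(variants, g1, bx, sx, px, config.n_exposure_sample)

    # outcome cohort (exposure itself unobserved there)
    g2 = _draw_genotypes(rng, config.n_outcome_sample, mafs)
    conf2 = rng.normal(size=config.n_outcome_sample)
    x2 = g2 @ b + gx * conf2 + rng.normal(0, np.sqrt(resid_x), size=config.n_outcome_sample)
    lin = config.theta * x2 + cx * conf2 + g2 @ a + g2 @ d
    if config.outcome_type == "binary":
        alpha = _solve_intercept(lin, config.prevalence)
        y = rng.binomial(1, expit(alpha + lin)).astype(float)
        by, sy, py = logistic_gwas(g2, y)
        outcome_trait = TraitInfo(
            "outcome", "simulated disease", "binary",
            n_cases=int(y.sum()), n_controls=int(len(y) - y.sum()),
        )
    else:
        resid_y = max(1.0 - config.theta**2 - cx**2, 0.05)
        y = lin + rng.normal(0, np.sqrt(resid_y), size=config.n_outcome_sample)
        by, sy, py = linear_gwas(g2, y)
        outcome_trait = TraitInfo("outcome", "simulated quantitative outcome", "continuous")
    outcome = _assocs(variants, g2, by, sy, py, config.n_outcome_sample)

    panel = ReferencePanel(variants, _draw_genotypes(rng, config.n_panel, mafs))
    truth = {
        "config": asdict(config),
        "mafs": mafs.tolist(),
        "causal_variant_ids": variants["variant_id"].iloc[causal_idx].tolist(),
        "outcome_snp_ids": variants["variant_id"].iloc[outcome_idx].tolist(),
        "instrument_effects": b.tolist(),
        "outcome_snp_effects": d.tolist(),
        "pleiotropy_effects": a.tolist(),
        "theta": config.theta,
        "realized_prevalence": float(np.mean(y)) if config.outcome_type == "binary" else None,
    }
    exposure_trait = TraitInfo("exposure", "simulated exposure", "continuous")
    return TwoSampleDataset(exposure, outcome, truth, panel, exposure_trait, outcome_trait)


def simulate_mediation_triplet(config: SimulationConfig = SimulationConfig()) -> MediationDataset:
    """Three cohorts instrumenting an exposure -> mediator -> outcome chain.

    The mediator is ``step1 * exposure`` plus its own independent genetic
    component and noise; the outcome combines the direct exposure effect and
    ``step2 * mediator``. Exposure, mediator and outcome GWAS each come from
    a separate cohort over the union of exposure SNPs and mediator SNPs.
    """
    med = config.mediator
    rng = np.random.default_rng(config.seed)
    m_x = config.m_snps
    m_total = m_x + med.m_snps
    mafs = rng.uniform(*config.maf_range, size=m_total)
    variants = _variant_table(rng, m_total)
    causal_x = np.sort(rng.choice(m_x, size=config.n_causal_instruments, replace=False))
    b = _instrument_effects(rng, mafs, causal_x, config.h2_exposure)
    med_idx = np.arange(m_x, m_total)
    c = _instrument_effects(rng, mafs, med_idx, med.h2)

    gx, cy = config.confounder_effect_exposure, config.confounder_effect_outcome
    resid_x = 1.0 - config.h2_exposure - gx**2
    resid_m = max(1.0 - med.step1**2 - med.h2, 0.05)

    def draw_cohort(n: int):
        g = _draw_genotypes(rng, n, mafs)
        conf = rng.normal(size=n)
        x = g @ b + gx * conf + rng.normal(0, np.sqrt(resid_x), size=n)
        mediator = med.step1 * x + g @ c + rng.normal(0, np.sqrt(resid_m), size=n)
        return g, conf, x, mediator

    g1, _, x1, _ = draw_cohort(config.n_exposure_sample)
    bx, sx, px = linear_gwas(g1, x1)
    exposure = _assocs(variants, g1, bx, sx, px, config.n_exposure_sample)

    g2, _, _, m2 = draw_cohort(config.n_exposure_sample)
    bm, sm, pm = linear_gwas(g2, m2)
    mediator_stats = _assocs(variants, g2, bm, sm, pm, config.n_exposure_sample)

    g3, conf3, x3, m3 = draw_cohort(config.n_outcome_sample)
    lin = med.direct * x3 + med.step2 * m3 + cy * conf3
    if config.outcome_type == "binary":
        alpha = _solve_intercept(lin, config.prevalence)
        y = rng.binomial(1, expit(alpha + lin)).astype(float)
        by, sy, py = logistic_gwas(g3, y)
    else:
        y = lin + rng.normal(0, 1.0, size=config.n_outcome_sample)
        by, sy, py = linear_gwas(g3, y)
    outcome = _assocs(variants, g3, by, sy, py, config.n_outcome_sample)

    panel = ReferencePanel(variants, _draw_genotypes(rng, config.n_panel, mafs))
    indirect = med.step1 * med.step2
    truth = {
        "config": asdict(config),
        "exposure_causal_ids": variants["variant_id"].iloc[causal_x].tolist(),
        "mediator_own_ids": variants["variant_id"].iloc[med_idx].tolist(),
        "step1": med.step1,
        "step2": med.step2,
        "direct": med.direct,
        "total": indirect + med.direct,
        "generative_proportion_pct": 100.0 * indirect / (indirect + med.direct),
    }
    return MediationDataset(exposure, mediator_stats, outcome, truth, panel)


def _ar1_dosages(rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    """Dosages with AR(1) latent LD: adjacent-variant latent correlation rho."""
    m = len(mafs)
    hap = np.empty((2 * n, m))
    hap[:, 0] = rng.normal(size=2 * n)
    scale = np.sqrt(1.0 - rho**2)
    for j in range(1, m):
        hap[:, j] = rho * hap[:, j - 1] + scale * rng.normal(size=2 * n)
    thresholds = stats.norm.ppf(mafs)
    alleles = (hap < thresholds[None, :]).astype(float)
    return alleles[:n] + alleles[n:]


def simulate_region_pair(config: SimulationConfig = SimulationConfig()) -> RegionPairDataset:
    """LD-structured regional summary statistics for two traits.

    One causal variant per trait (the same one iff ``sharing = "shared"``,
    none if ``"none"``), with the effect size set so the causal variant's
    expected association z is ``z_target``. Both traits are quantitative;
    each has its own cohort, and a held-out cohort forms the LD panel.
    """
    rc = config.region
    rng = np.random.default_rng(config.seed)
    m = rc.m_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    variants = _variant_table(
        rng, m, chrom="1", start=1_000_000, spacing=rc.spacing_bp, prefix="rv"
    )

    if rc.sharing == "shared":
        causal1 = causal2 = m // 2
    elif rc.sharing == "distinct":
        causal1, causal2 = m // 4, (3 * m) // 4
    else:
        causal1 = causal2 = None

    def trait_stats(causal: int | None):
        g = _ar1_dosages(rng, rc.n_sample, mafs, rc.rho)
        y = rng.normal(size=rc.n_sample)
        if causal is not None:
            gc = g[:, causal]
            sd_g = gc.std()
            beta = rc.z_target / (sd_g * np.sqrt(rc.n_sample))
            y = y + beta * gc
        b, s, p = linear_gwas(g, y)
        return _assocs(variants, g, b, s, p, rc.n_sample)

    trait1 = trait_stats(causal1)
    trait2 = trait_stats(causal2)
    panel = ReferencePanel(variants, _ar1_dosages(rng, config.n_panel, mafs, rc.rho))
    truth = {
        "sharing": rc.sharing,
        "causal1": variants["variant_id"].iloc[causal1] if causal1 is not None else None,
        "causal2": variants["variant_id"].iloc[causal2] if causal2 is not None else None,
        "z_target": rc.z_target,
        "rho": rc.rho,
        "n_sample": rc.n_sample,
    }
    return RegionPairDataset(trait1, trait2, panel, truth)


def simulate_phewas_screen(
    seed: int = 0,
    n_exposures: int = 20,
    n_causal_exposures: int = 3,
    theta: float = 0.4,
    snps_per_exposure: int = 10,
    h2_per_exposure: float = 0.4,
    n_sample: int = 2_000,
    n_panel: int = 500,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> tuple[list[tuple[TraitInfo, list[VariantAssociation]]], tuple[TraitInfo, list[VariantAssociation]], ReferencePanel, dict]:
    """A multi-exposure screening scenario with known causal exposures.

    Each exposure owns a disjoint block of causal SNPs; the first
    ``n_causal_exposures`` exposures affect a shared continuous outcome with
    effect ``theta``, the rest are null. One cohort measures all exposures,
    a second the outcome, and a third forms the panel.
    """
    rng = np.random.default_rng(seed)
    m = n_exposures * snps_per_exposure
    mafs = rng.uniform(*maf_range, size=m)
    variants = _variant_table(rng, m)
    blocks = [
        np.arange(k * snps_per_exposure, (k + 1) * snps_per_exposure)
        for k in range(n_exposures)
    ]
    effects = [_instrument_effects(rng, mafs, blk, h2_per_exposure) for blk in blocks]
    resid_x = 1.0 - h2_per_exposure

    g1 = _draw_genotypes(rng, n_sample, mafs)
    g2 = _draw_genotypes(rng, n_sample, mafs)
    exposures: list[tuple[TraitInfo, list[VariantAssociation]]] = []
    lin_outcome = np.zeros(n_sample)
    for k in range(n_exposures):
        x1 = g1 @ effects[k] + rng.normal(0, np.sqrt(resid_x), size=n_sample)
        b, s, p = linear_gwas(g1, x1)
        trait = TraitInfo(f"exposure_{k:02d}", f"simulated exposure {k}", "continuous")
        exposures.append((trait, _assocs(variants, g1, b, s, p, n_sample)))
        if k < n_causal_exposures:
            x2 = g2 @ effects[k] + rng.normal(0, np.sqrt(resid_x), size=n_sample)
            lin_outcome = lin_outcome + theta * x2
    y = lin_outcome + rng.normal(size=n_sample)
    by, sy, py = linear_gwas(g2, y)
    outcome_trait = TraitInfo("outcome", "simulated outcome", "continuous")
    outcome = (outcome_trait, _assocs(variants, g2, by, sy, py, n_sample))

    panel = ReferencePanel(variants, _draw_genotypes(rng, n_panel, mafs))
    truth = {
        "causal_exposures": [f"exposure_{k:02d}" for k in range(n_causal_exposures)],
        "theta": theta,
    }
    return exposures, outcome, panel, truth
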