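"""Shared fixtures and factories for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from mrphewas.gwas_data import HarmonisedInstrument, TraitInfo, VariantAssociation
from mrphewas.ld_reference import ReferencePanel
from mrphewas.mr_core import MRInput


def make_assoc(
    variant_id: str = "rs1",
    chrom: str = "1",
    pos: int = 1000,
    effect_allele: str = "A",
    other_allele: str = "G",
    eaf: float | None = 0.3,
    beta: float = 0.1,
    se: float = 0.05,
    pval: float | None = None,
    n: float | None = 10000.0,
) -> VariantAssociation:
    if pval is None:
        pval = max(float(2 * norm.sf(abs(beta) / se)), 5e-324)
    return VariantAssociation(
        variant_id=variant_id, chrom=chrom, pos=pos,
        effect_allele=effect_allele, other_allele=other_allele,
        eaf=eaf, beta=beta, se=se, pval=pval, n=n,
    )


def make_instrument(
    variant_id: str = "rs1",
    exposure_beta: float = 0.1,
    exposure_se: float = 0.02,
    outcome_beta: float = 0.05,
    outcome_se: float = 0.02,
    action: str = "kept",
) -> HarmonisedInstrument:
    return HarmonisedInstrument(
        variant_id=variant_id, effect_allele="A", other_allele="G",
        exposure_beta=exposure_beta, exposure_se=exposure_se, exposure_eaf=0.3,
        outcome_beta=outcome_beta, outcome_se=outcome_se, outcome_eaf=0.3,
        action=action,
    )


def mr_input_from(bx, sx, by, sy) -> MRInput:
    """Build an MRInput directly from effect/SE arrays."""
    instruments = [
        make_instrument(f"rs{i + 1}", float(b), float(s), float(y), float(t))
        for i, (b, s, y, t) in enumerate(zip(bx, sx, by, sy))
    ]
    return MRInput(TraitInfo("x"), TraitInfo("y", trait_type="binary"), instruments)


def ar1_panel(seed: int = 0, n: int = 500, m: int = 8, rho: float = 0.8) -> ReferencePanel:
    """Small LD panel with AR(1)-correlated dosage columns on one chromosome."""
    rng = np.random.default_rng(seed)
    hap = np.empty((2 * n, m))
    hap[:, 0] = rng.normal(size=2 * n)
    for j in range(1, m):
        hap[:, j] = rho * hap[:, j - 1] + np.sqrt(1 - rho**2) * rng.normal(size=2 * n)
    alleles = (hap < norm.ppf(0.4)).astype(float)
    dosages = alleles[:n] + alleles[n:]
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{i + 1}" for i in range(m)],
            "chrom": "1",
            "pos": 10_000 + 5_000 * np.arange(m),
            "allele_a": "A",
            "allele_b": "G",
        }
    )
    return ReferencePanel(variants, dosages)


@pytest.fixture
def panel() -> ReferencePanel:
    return ar1_panel()
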