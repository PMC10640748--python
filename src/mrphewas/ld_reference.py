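"""Reference-panel genotypes: pairwise LD, greedy clumping and proxy search.

LD is computed as the Pearson correlation of unphased allele dosages over a
reference cohort — the same quantity PLINK-style clumping uses. The panel is
either simulated or user-supplied; no external download is performed, and the
population match between panel and GWAS cohorts is the caller's
responsibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gwas_data import VariantAssociation

logger = logging.getLogger(__name__)

PANEL_VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "allele_a", "allele_b"]


class PanelLookupError(KeyError):
    """A variant id is not present in the reference panel."""


class DegenerateVariantError(ValueError):
    """A dosage column has zero variance and no correlation is defined."""


@dataclass(frozen=True)
class LDResult:
    """Signed dosage correlation between two variants; ``r2 = r**2``."""

    r: float
    r2: float


class ReferencePanel:
    """Genotype dosages (individuals x variants) plus variant metadata.

    ``dosages[i, j]`` counts copies of ``allele_b`` of variant ``j`` carried
    by individual ``i`` (0..2). Constant (zero-variance) columns are dropped
    at construction with a log entry, so every retained variant supports LD
    computation.
    """

    def __init__(self, variants: pd.DataFrame, dosages: np.ndarray):
        variants = variants.reset_index(drop=True)
        dosages = np.asarray(dosages, dtype=float)
        if dosages.ndim != 2 or dosages.shape[1] != len(variants):
            raise ValueError(
                f"dosage matrix has {dosages.shape} entries for {len(variants)} variants"
            )
        missing = [c for c in PANEL_VARIANT_COLUMNS if c not in variants.columns]
        if missing:
            raise ValueError(f"panel variant table missing column(s) {missing}")
        keep = dosages.std(axis=0) > 0
        if not keep.all():
            dropped = variants.loc[~keep, "variant_id"].tolist()
            logger.info("panel: dropped %d constant variant column(s): %s", len(dropped), dropped[:10])
            variants = variants.loc[keep].reset_index(drop=True)
            dosages = dosages[:, keep]
        self.variants = variants.assign(
            chrom=variants["chrom"].astype(str), pos=variants["pos"].astype(int)
        )
        self.dosages = dosages
        self._index: dict[str, int] = {v: i for i, v in enumerate(self.variants["variant_id"])}

    # -- basic access -------------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def column(self, variant_id: str) -> np.ndarray:
        try:
            return self.dosages[:, self._index[variant_id]]
        except KeyError:
            raise PanelLookupError(f"variant {variant_id!r} not in reference panel") from None

    def info(self, variant_id: str):
        try:
            return self.variants.iloc[self._index[variant_id]]
        except KeyError:
            raise PanelLookupError(f"variant {variant_id!r} not in reference panel") from None

    def allele_b_frequency(self, variant_id: str) -> float:
        return float(self.column(variant_id).mean() / 2.0)

    # -- persistence ---------------------------------------------------------

    @classmethod
    def from_files(cls, variant_path, dosage_path) -> "ReferencePanel":
        variants = pd.read_csv(variant_path, sep="\t", dtype={"chrom": str})
        dosages = pd.read_csv(dosage_path, sep="\t")
        # dosage header carries variant ids; order them by the variant table
        dosages = dosages[variants["variant_id"].tolist()]
        return cls(variants, dosages.to_numpy(dtype=float))

    def to_files(self, variant_path, dosage_path) -> None:
        self.variants[PANEL_VARIANT_COLUMNS].to_csv(variant_path, sep="\t", index=False)
        pd.DataFrame(self.dosages, columns=self.variants["variant_id"].tolist()).to_csv(
            dosage_path, sep="\t", index=False
        )


def ld_r(panel: ReferencePanel, id_a: str, id_b: str) -> LDResult:
    """Pearson correlation of the two variants' dosage columns."""
    a = panel.column(id_a)
    b = panel.column(id_b)
    if a.std() == 0 or b.std() == 0:
        raise DegenerateVariantError(f"zero dosage variance for {id_a!r}/{id_b!r}")
    r = float(np.corrcoef(a, b)[0, 1])
    r = min(1.0, max(-1.0, r))
    return LDResult(r=r, r2=r * r)


def clump(
    assocs: Sequence[VariantAssociation],
    panel: ReferencePanel,
    r2_threshold: float = 0.001,
    window_kb: float = 10_000,
) -> list[VariantAssociation]:
    """Greedy LD pruning to an approximately independent instrument set.

    Repeatedly retain the remaining record with the smallest p-value (ties:
    lexicographic variant id) and discard all remaining records on the same
    chromosome within ``window_kb`` whose dosage ``r^2`` with it exceeds
    ``r2_threshold``. Variants absent from the panel cannot be tested; they
    are retained untouched and logged.
    """
    window_bp = window_kb * 1000.0
    order = sorted(assocs, key=lambda a: (a.pval, a.variant_id))
    retained: list[VariantAssociation] = []
    n_unmappable = 0
    while order:
        index = order.pop(0)
        retained.append(index)
        if index.variant_id not in panel:
            n_unmappable += 1
            continue
        survivors = []
        for a in order:
            if (
                a.chrom == index.chrom
                and abs(a.pos - index.pos) <= window_bp
                and a.variant_id in panel
                and ld_r(panel, index.variant_id, a.variant_id).r2 > r2_threshold
            ):
                continue
            survivors.append(a)
        order = survivors
    if n_unmappable:
        logger.info("clump: %d variant(s) not in panel, retained untested", n_unmappable)
    return retained


def find_proxy(
    panel: ReferencePanel,
    target: str,
    candidates: Sequence[str],
    r2_min: float = 0.8,
) -> tuple[str, LDResult] | None:
    """Best LD proxy for ``target`` among ``candidates``.

    Returns the candidate with maximal ``r^2`` strictly above ``r2_min``
    (ties: closest base-pair position, then lexicographic id) together with
    the signed ``r`` used to orient the proxy's alleles, or ``None`` if no
    candidate qualifies. Candidates missing from the panel are skipped.
    """
    if target not in panel:
        raise PanelLookupError(f"proxy target {target!r} not in reference panel")
    target_pos = int(panel.info(target)["pos"])
    best_key = None
    best: tuple[str, LDResult] | None = None
    n_missing = 0
    for cid in candidates:
        if cid not in panel:
            n_missing += 1
            continue
        res = ld_r(panel, target, cid)
        if res.r2 <= r2_min:
            continue
        key = (-res.r2, abs(int(panel.info(cid)["pos"]) - target_pos), cid)
        if best_key is None or key < best_key:
            best_key = key
            best = (cid, res)
    if n_missing:
        logger.debug("find_proxy(%s): %d candidate(s) not in panel", target, n_missing)
    return best
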