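"""Configuration-driven orchestration of the full screening study.

A single YAML file names the inputs (exposure manifest, outcome GWAS,
reference panel, mediator manifest), the thresholds, and which stages to
run. Stages execute in a fixed order — forward screen, reverse screen,
mediation, regional follow-up (conditional scan + colocalization for
single-instrument hits) — with each stage's failure recorded without
aborting the independent stages that follow. Outputs are plain TSV/JSON
files plus a summary report and a log capturing the exclusion tallies
(un-harmonisable exposures, dropped palindromes, proxy substitutions).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from .gwas_data import TraitInfo, read_summary_stats, select_instruments
from .ld_reference import ReferencePanel, clump
from .mediation import two_step_mediation
from .mr_core import MREstimate, MRInput, ivw, wald_ratio
from .phewas import (
    ScreenConfig,
    ScreenResult,
    flag_reverse_causation,
    harmonise_against_outcome,
    reverse_screen,
    run_screen,
)
from .regional import ColocPriors, coloc_abf, conditional_scan, region_scatter

logger = logging.getLogger(__name__)

_THRESHOLD_KEYS = {
    "p_instrument": 5e-8,
    "clump_r2": 0.001,
    "clump_window_kb": 10_000,
    "proxy_r2": 0.8,
    "palindrome_eaf_window": 0.08,
    "alpha": 0.05,
    "correction_method": "nyholt_spd",
    "significance_threshold": None,
    "reverse_threshold": None,
    "mediation_family_size": 15,
    "coloc_window_kb": 500,
    "conditional_window_kb": 1_000,
}
_STAGE_KEYS = {"screen": True, "reverse": True, "mediate": True, "coloc": True, "conditional": True}
_PATH_KEYS = {
    "exposure_manifest": None,
    "outcome": None,
    "panel_prefix": None,
    "mediator_manifest": None,
    "out_dir": None,
}
_OUTCOME_KEYS = {"trait_id": "outcome", "label": "", "trait_type": "binary"}


class ConfigError(ValueError):
    """The run configuration is invalid (unknown keys, bad values)."""


def _merge_section(name: str, defaults: dict, given: dict | None) -> dict:
    given = dict(given or {})
    unknown = set(given) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r} section: {sorted(unknown)}")
    out = dict(defaults)
    out.update(given)
    return out


@dataclass
class RunConfig:
    """Validated run configuration; every default mirrors a study-standard value."""

    paths: dict = field(default_factory=lambda: dict(_PATH_KEYS))
    thresholds: dict = field(default_factory=lambda: dict(_THRESHOLD_KEYS))
    stages: dict = field(default_factory=lambda: dict(_STAGE_KEYS))
    outcome: dict = field(default_factory=lambda: dict(_OUTCOME_KEYS))
    mediation_exposure_id: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {"paths", "thresholds", "stages", "outcome", "mediation_exposure_id", "seed"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")
        cfg = cls(
            paths=_merge_section("paths", _PATH_KEYS, raw.get("paths")),
            thresholds=_merge_section("thresholds", _THRESHOLD_KEYS, raw.get("thresholds")),
            stages=_merge_section("stages", _STAGE_KEYS, raw.get("stages")),
            outcome=_merge_section("outcome", _OUTCOME_KEYS, raw.get("outcome")),
            mediation_exposure_id=raw.get("mediation_exposure_id"),
            seed=int(raw.get("seed", 0)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        t = self.thresholds
        if not (0 < t["p_instrument"] < 1):
            raise ConfigError("p_instrument must lie in (0, 1)")
        if not (0 <= t["clump_r2"] <= 1) or not (0 <= t["proxy_r2"] <= 1):
            raise ConfigError("r2 thresholds must lie in [0, 1]")
        if not (0 < t["alpha"] < 1):
            raise ConfigError("alpha must lie in (0, 1)")
        if t["correction_method"] not in ("nyholt_spd", "li_ji"):
            raise ConfigError(f"unknown correction_method {t['correction_method']!r}")
        if int(t["mediation_family_size"]) < 1:
            raise ConfigError("mediation_family_size must be >= 1")

    def screen_config(self) -> ScreenConfig:
        t = self.thresholds
        return ScreenConfig(
            p_instrument=t["p_instrument"],
            clump_r2=t["clump_r2"],
            clump_window_kb=t["clump_window_kb"],
            proxy_r2=t["proxy_r2"],
            palindrome_eaf_window=t["palindrome_eaf_window"],
            alpha=t["alpha"],
            correction_method=t["correction_method"],
            significance_threshold=t["significance_threshold"],
            reverse_threshold=t["reverse_threshold"],
        )


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Family-wise threshold ``alpha / n_tests``."""
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    return alpha / n_tests


def round_sig(x: float, sig: int = 1) -> float:
    """Round to ``sig`` significant figures (for display)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass
class PipelineResult:
    out_dir: Path
    report: dict
    failures: dict[str, str]

    @property
    def ok(self) -> bool:
        return not self.failures


def _read_manifest(path) -> list[tuple[TraitInfo, str]]:
    df = pd.read_csv(path, sep="\t")
    needed = {"trait_id", "path", "trait_type"}
    missing = needed - set(df.columns)
    if missing:
        raise ConfigError(f"exposure manifest missing column(s) {sorted(missing)}")
    base = Path(path).parent
    out = []
    excluded = 0
    for row in df.itertuples(index=False):
        if "exclude" in df.columns and bool(getattr(row, "exclude", False)):
            excluded += 1
            continue
        label = str(getattr(row, "label", row.trait_id))
        trait = TraitInfo(str(row.trait_id), label, str(row.trait_type))
        p = Path(str(row.path))
        out.append((trait, str(p if p.is_absolute() else base / p)))
    if excluded:
        logger.info("manifest: honoured exclusion list, %d trait(s) removed", excluded)
    return out


def _total_effect_for(
    exposure_id: str, screen: ScreenResult | None
) -> MREstimate | None:
    if screen is None:
        return None
    for row in screen.rows:
        if row.exposure_id == exposure_id and row.beta is not None:
            return MREstimate.from_beta_se(row.method or "ivw", row.beta, row.se, row.nsnp)
    return None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the enabled stages and write a versioned run directory.

    Stage order: forward screen, reverse screen, mediation, regional
    follow-up. Single-instrument hits of the forward screen are queued for
    the conditional scan and colocalization automatically. Returns a result
    whose ``failures`` dict is empty on full success.
    """
    out_dir = Path(config.paths["out_dir"] or "mrphewas_run")
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("mrphewas")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    logger.info("run configuration: %s", json.dumps(asdict(config), default=str))

    failures: dict[str, str] = {}
    report: dict = {"stages_run": [], "seed": config.seed}
    scfg = config.screen_config()

    panel = None
    if config.paths["panel_prefix"]:
        prefix = config.paths["panel_prefix"]
        panel = ReferencePanel.from_files(f"{prefix}.variants.tsv", f"{prefix}.dosages.tsv")

    outcome_trait = TraitInfo(
        config.outcome["trait_id"], config.outcome["label"], config.outcome["trait_type"]
    )
    exposures = (
        _read_manifest(config.paths["exposure_manifest"])
        if config.paths["exposure_manifest"]
        else []
    )

    screen_result: ScreenResult | None = None
    if config.stages["screen"]:
        try:
            screen_result = run_screen(
                exposures, (outcome_trait, config.paths["outcome"]), panel, scfg
            )
            screen_result.to_frame().to_csv(out_dir / "screen.tsv", sep="\t", index=False, na_rep="NA")
            meff_report = {
                "threshold": screen_result.threshold,
                "meff": None if screen_result.meff is None else asdict(screen_result.meff),
            }
            (out_dir / "meff.json").write_text(json.dumps(meff_report, indent=2))
            n_failed = sum(r.harmonisation_failed for r in screen_result.rows)
            logger.info(
                "screen: %d exposures, %d hits, %d un-harmonisable",
                len(screen_result.rows), len(screen_result.hits), n_failed,
            )
            report["screen"] = {
                "n_exposures": len(screen_result.rows),
                "n_hits": len(screen_result.hits),
                "n_harmonisation_failed": n_failed,
                "threshold": screen_result.threshold,
                "hits": [r.exposure_id for r in screen_result.hits],
            }
            report["stages_run"].append("screen")
        except Exception as exc:
            failures["screen"] = f"{type(exc).__name__}: {exc}"
            logger.exception("screen stage failed")

    if config.stages["reverse"]:
        try:
            targets = exposures
            if screen_result is not None:
                hit_ids = {r.exposure_id for r in screen_result.hits}
                targets = [(t, p) for t, p in exposures if t.trait_id in hit_ids]
            rcfg = scfg
            if rcfg.reverse_threshold is None and screen_result is not None:
                rcfg = ScreenConfig(**{**asdict(scfg), "reverse_threshold": screen_result.threshold})
            rev = reverse_screen(
                (outcome_trait, config.paths["outcome"]), targets, panel, rcfg
            )
            rev.to_frame().to_csv(out_dir / "reverse.tsv", sep="\t", index=False, na_rep="NA")
            flagged = (
                flag_reverse_causation(screen_result, rev) if screen_result is not None else []
            )
            report["reverse"] = {
                "n_tested": len(rev.rows),
                "threshold": rev.threshold,
                "possible_reverse_causation": flagged,
            }
            report["stages_run"].append("reverse")
        except Exception as exc:
            failures["reverse"] = f"{type(exc).__name__}: {exc}"
            logger.exception("reverse stage failed")

    if config.stages["mediate"] and config.paths["mediator_manifest"]:
        try:
            report["mediation"] = _mediation_stage(config, outcome_trait, panel, scfg, screen_result, out_dir)
            report["stages_run"].append("mediate")
        except Exception as exc:
            failures["mediate"] = f"{type(exc).__name__}: {exc}"
            logger.exception("mediation stage failed")

    if config.stages["coloc"] or config.stages["conditional"]:
        try:
            report["regional"] = _regional_stage(
                config, exposures, outcome_trait, panel, screen_result, out_dir
            )
            report["stages_run"].append("regional")
        except Exception as exc:
            failures["regional"] = f"{type(exc).__name__}: {exc}"
            logger.exception("regional stage failed")

    report["failures"] = failures
    (out_dir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    root.removeHandler(handler)
    handler.close()
    return PipelineResult(out_dir=out_dir, report=report, failures=failures)


def _estimate_trait_on_outcome(
    trait: TraitInfo,
    stats_path: str,
    outcome_trait: TraitInfo,
    outcome_by_id: dict,
    panel: ReferencePanel,
    scfg: ScreenConfig,
) -> tuple[MREstimate | None, int]:
    assocs = read_summary_stats(stats_path, trait=trait)
    instruments = clump(
        select_instruments(assocs, scfg.p_instrument), panel, scfg.clump_r2, scfg.clump_window_kb
    )
    harmonised = harmonise_against_outcome(instruments, outcome_by_id, panel, scfg)
    kept = [h for h in harmonised if h.usable]
    if not kept:
        return None, 0
    mr_input = MRInput(trait, outcome_trait, kept)
    est = wald_ratio(kept[0]) if len(kept) == 1 else ivw(mr_input)
    return est, len(kept)


def _mediation_stage(config, outcome_trait, panel, scfg, screen_result, out_dir) -> dict:
    mdf = pd.read_csv(config.paths["mediator_manifest"], sep="\t")
    needed = {"mediator_id", "step1_beta", "step1_se", "path"}
    missing = needed - set(mdf.columns)
    if missing:
        raise ConfigError(f"mediator manifest missing column(s) {sorted(missing)}")
    total = _total_effect_for(config.mediation_exposure_id, screen_result)
    if total is None:
        raise ConfigError(
            "mediation requires a screened total effect; set mediation_exposure_id "
            "to an exposure with a forward estimate"
        )
    family = int(config.thresholds["mediation_family_size"])
    threshold = bonferroni_threshold(family, config.thresholds["alpha"])
    outcome_by_id = {
        a.variant_id: a
        for a in read_summary_stats(config.paths["outcome"], trait=outcome_trait)
    }
    base = Path(config.paths["mediator_manifest"]).parent
    rows = []
    consistent_ids = []
    for rec in mdf.itertuples(index=False):
        mtrait = TraitInfo(str(rec.mediator_id), str(rec.mediator_id), "continuous")
        p = Path(str(rec.path))
        est, nsnp = _estimate_trait_on_outcome(
            mtrait, str(p if p.is_absolute() else base / p),
            outcome_trait, outcome_by_id, panel, scfg,
        )
        if est is None:
            rows.append({"mediator_id": mtrait.trait_id, "status": "no_instruments"})
            continue
        passes = est.pval < threshold
        row = {
            "mediator_id": mtrait.trait_id,
            "status": "ok",
            "nsnp": nsnp,
            "step2_beta": est.beta,
            "step2_se": est.se,
            "step2_pval": est.pval,
            "passes_bonferroni": passes,
        }
        if passes:
            res = two_step_mediation(total, float(rec.step1_beta), float(rec.step1_se), est)
            row.update(
                indirect=res.indirect,
                indirect_se=res.indirect_se,
                proportion_pct=res.proportion_pct,
                consistent=res.consistent,
                note=res.label,
            )
            if res.consistent:
                consistent_ids.append(mtrait.trait_id)
        rows.append(row)
    pd.DataFrame(rows).to_csv(out_dir / "mediation.tsv", sep="\t", index=False, na_rep="NA")
    return {
        "n_mediators": len(rows),
        "bonferroni_threshold": round_sig(threshold, 1),
        "consistent_mediators": consistent_ids,
        "total_effect_exposure": config.mediation_exposure_id,
        "total_effect_beta": total.beta,
    }


def _regional_stage(config, exposures, outcome_trait, panel, screen_result, out_dir) -> dict:
    if screen_result is None:
        return {"skipped": "no forward screen to pick single-instrument hits from"}
    single_hits = [
        r for r in screen_result.rows if r.passes_threshold and r.nsnp == 1
    ]
    by_id = {t.trait_id: p for t, p in exposures}
    outcome_assocs = read_summary_stats(config.paths["outcome"], trait=outcome_trait)
    coloc_half = config.thresholds["coloc_window_kb"] * 1000 / 2
    out: dict = {"n_single_instrument_hits": len(single_hits), "colocalizing": [], "secondary_signals": []}
    for row in single_hits:
        inst = next(h for h in row.instruments if h.usable)
        exp_assocs = read_summary_stats(by_id[row.exposure_id])
        anchor = next((a for a in exp_assocs if a.variant_id == inst.variant_id), None)
        if anchor is None:
            continue
        region_exp = [
            a for a in exp_assocs
            if a.chrom == anchor.chrom and abs(a.pos - anchor.pos) <= coloc_half
        ]
        region_out = [
            a for a in outcome_assocs
            if a.chrom == anchor.chrom and abs(a.pos - anchor.pos) <= coloc_half
        ]
        if config.stages["coloc"]:
            coloc = coloc_abf(region_exp, region_out, ColocPriors())
            payload = {"pp": coloc.pp, "nsnp": coloc.nsnp, "priors": asdict(coloc.priors)}
            (out_dir / f"coloc_{row.exposure_id}.json").write_text(json.dumps(payload, indent=2))
            if coloc.pp["H4"] > 0.8:
                out["colocalizing"].append(row.exposure_id)
        if config.stages["conditional"]:
            cond = conditional_scan(
                region_exp, panel, index=inst.variant_id,
                window_kb=config.thresholds["conditional_window_kb"],
            )
            cond.table.to_csv(
                out_dir / f"conditional_{row.exposure_id}.tsv", sep="\t", index=False
            )
            if cond.secondary_signal:
                out["secondary_signals"].append(row.exposure_id)
        region_scatter(region_exp, panel, inst.variant_id).to_csv(
            out_dir / f"region_{row.exposure_id}.tsv", sep="\t", index=False
        )
    return out
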