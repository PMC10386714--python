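"""Reproducible end-to-end runs: config, stage orchestration, manifest.

A :class:`RunConfig` (YAML-backed, unknown keys rejected) drives
simulate -> classify -> diff -> cleave -> screen -> polysome on synthetic
inputs, writing every intermediate as TSV/FASTQ/FASTA plus a ``manifest.json``
that echoes the seed, all parameters and per-stage row counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .cleavage import call_m7g_sites, cleavage_matrix, read_profiles, write_profiles
from .diffabund import call_enriched, nb_wald_test
from .fragmentio import align_fragments, count_fragments, write_fastq
from .reference import write_reference
from .screens import polysome_fc, rmp_screen
from .synthdata import (
    CleavageDesign,
    CohortDesign,
    FragmentDesign,
    PlantedGene,
    PlantedTOG,
    make_trna_reference,
    simulate_cleavage_profiles,
    simulate_expression_cohorts,
    simulate_fragment_reads,
    simulate_polysome_profile,
)
from .trf import ClassifyParams, class_composition, classify_table, filter_low_counts

log = logging.getLogger("trfscope")

ALL_STAGES = ("simulate", "classify", "diff", "cleave", "screen", "polysome")

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "ALL_STAGES"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _build(cls, section: dict, name: str):
    try:
        return cls(**section)
    except TypeError as exc:
        raise ValueError(f"invalid key in config section {name!r}: {exc}") from exc


@dataclass
class RunConfig:
    """Validated pipeline configuration (every field echoes into the manifest)."""

    outdir: str = "trfscope_run"
    seed: int = 0
    log_level: str = "INFO"
    stages: tuple[str, ...] = ALL_STAGES
    reference: dict = field(
        default_factory=lambda: {"n_species": 4, "n_m7g_targets": 2, "length": 76}
    )
    fragments: dict = field(default_factory=dict)
    cleavage: dict = field(default_factory=dict)
    cohorts: dict = field(default_factory=dict)
    polysome: dict = field(default_factory=lambda: {"n_transcripts": 20})
    classify: dict = field(default_factory=dict)
    diff: dict = field(default_factory=lambda: {"lfc_min": 2.0, "p_max": 0.05})
    cleave: dict = field(default_factory=dict)
    screen: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _fragment_design(cfg: RunConfig, ref) -> FragmentDesign:
    section = dict(cfg.fragments)
    planted = section.pop("planted_togs", None)
    if planted is None:
        # default: plant on the species that actually carry a 5' G run
        planted = [
            {"species_id": sp.id}
            for sp in ref
            if sp.sequence.startswith("GGGG")
        ][:2]
    togs = tuple(
        _build(PlantedTOG, {**p, "lengths": tuple(p.get("lengths", (20, 30)))}, "planted_togs")
        for p in planted
    )
    section.setdefault("seed", cfg.seed)
    design = _build(FragmentDesign, section, "fragments")
    design.planted_togs = togs
    design.__post_init__()
    return design


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the requested stages; returns the manifest dictionary."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    state: dict[str, Any] = {}

    for stage in config.stages:
        log.info("stage %s", stage)
        try:
            counts = _STAGE_FUNCS[stage](config, outdir, state)
        except Exception as exc:  # noqa: BLE001 - named stage failure contract
            raise PipelineError(stage, exc) from exc
        manifest["stages"][stage] = counts

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _stage_simulate(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    ref = make_trna_reference(seed=cfg.seed, **cfg.reference)
    state["ref"] = ref
    write_reference(ref, outdir / "reference.fasta", outdir / "reference.tsv")

    design = _fragment_design(cfg, ref)
    reads = simulate_fragment_reads(ref, design)
    state["reads"] = reads
    state["fragment_design"] = design
    for sample, rs in reads.items():
        write_fastq(rs, outdir / f"reads_{sample}.fastq", prefix=sample)

    cleav = dict(cfg.cleavage)
    cleav.setdefault("seed", cfg.seed)
    profiles = simulate_cleavage_profiles(ref, _build(CleavageDesign, cleav, "cleavage"))
    state["profiles"] = profiles
    write_profiles(profiles, outdir / "cleavage_profiles.tsv")

    coh = dict(cfg.cohorts)
    coh.setdefault("seed", cfg.seed)
    planted = coh.pop("planted", None)
    cdesign = _build(CohortDesign, coh, "cohorts")
    if planted:
        cdesign.planted = tuple(
            _build(PlantedGene, {**p, "groups": tuple(p.get("groups", ("P", "M")))}, "planted")
            for p in planted
        )
    cohorts = simulate_expression_cohorts(cdesign)
    state["cohorts"] = cohorts
    for c in cohorts:
        c.expr.to_csv(outdir / f"cohort_{c.name}.tsv", sep="\t")
        pd.Series(list(c.labels), index=c.expr.columns, name="group").to_csv(
            outdir / f"cohort_{c.name}_labels.tsv", sep="\t"
        )

    poly_cfg = dict(cfg.polysome)
    poly_cfg.setdefault("seed", cfg.seed)
    profile = simulate_polysome_profile(**poly_cfg)
    state["polysome"] = profile
    profile.abundance.to_csv(outdir / "polysome.tsv", sep="\t")

    return {
        "n_species": len(ref),
        "n_samples": len(reads),
        "n_reads": int(sum(len(r) for r in reads.values())),
        "n_profiles": len(profiles),
        "n_cohorts": len(cohorts),
    }


def _stage_classify(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    ref = state["ref"]
    reads = state["reads"]
    aligned = {s: align_fragments(rs, ref) for s, rs in reads.items()}
    table = count_fragments(aligned)
    section = dict(cfg.classify)
    min_total = section.pop("min_total", 10)
    pseudocount = section.pop("pseudocount", 1)
    policy = section.pop("ambiguous_policy", "ambiguous")
    params = _build(ClassifyParams, section, "classify")
    classified = filter_low_counts(
        classify_table(table, ref, params, policy), min_total, pseudocount
    )
    state["classified"] = classified
    classified.to_frame().to_csv(outdir / "classified.tsv", sep="\t")
    comp = class_composition(classified)
    comp.to_csv(outdir / "class_composition.tsv", sep="\t")
    return {"n_fragments": int(classified.counts.shape[0])}


def _stage_diff(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    classified = state["classified"]
    groups = [s.rsplit("_", 1)[0] for s in classified.counts.columns]
    section = dict(cfg.diff)
    lfc_min = section.pop("lfc_min", 2.0)
    p_max = section.pop("p_max", 0.05)
    use_adjusted = section.pop("use_adjusted", False)
    results = nb_wald_test(classified.counts, groups, **section)
    flagged = call_enriched(results, lfc_min, p_max, use_adjusted)
    flagged = flagged.join(state["classified"].annotations)
    state["diff"] = flagged
    flagged.to_csv(outdir / "diff.tsv", sep="\t")
    enriched = flagged[flagged["flag_enriched"]]
    if len(enriched):
        class_composition(state["classified"], enriched.index).to_csv(
            outdir / "diff_class_composition.tsv", sep="\t"
        )
    return {"n_tested": int(len(flagged)), "n_enriched": int(flagged["flag_enriched"].sum())}


def _stage_cleave(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    ref = state["ref"]
    profiles = state.get("profiles")
    if profiles is None:
        profiles = read_profiles(outdir / "cleavage_profiles.tsv")
    wt = [p for p in profiles if p.condition == "WT"]
    ko = [p for p in profiles if p.condition != "WT"]
    calls = call_m7g_sites(wt, ko, ref, **cfg.cleave)
    calls.to_csv(outdir / "site_calls.tsv", sep="\t", index=False)
    matrix = cleavage_matrix(ref, profiles, offset=cfg.cleave.get("offset", 1))
    matrix.to_csv(outdir / "cleavage_matrix.tsv", sep="\t")
    return {"n_called": int(calls["called"].sum()) if len(calls) else 0}


def _stage_screen(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    result = rmp_screen(state["cohorts"], **cfg.screen)
    result.to_csv(outdir / "screen.tsv", sep="\t")
    return {"n_genes": int(len(result)), "n_hits": int(result["hit"].sum())}


def _stage_polysome(cfg: RunConfig, outdir: Path, state: dict) -> dict:
    fc = polysome_fc(state["polysome"])
    fc.rename("polysome_fc").to_csv(outdir / "polysome_fc.tsv", sep="\t")
    return {"n_transcripts": int(len(fc))}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "diff": _stage_diff,
    "cleave": _stage_cleave,
    "screen": _stage_screen,
    "polysome": _stage_polysome,
}
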