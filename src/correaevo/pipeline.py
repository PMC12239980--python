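"""Command-line orchestration of the full Correa-cascade analysis.

Thin layer over the library: a YAML run configuration (validated with
pydantic) drives subcommands for simulation, variant filtering, the
cohort mutational landscape, similarity matrices, trajectory calls,
genomic-instability indices, and marker validation — or ``all`` for the
end-to-end run. Outputs are TSV with fixed column order so reruns under
the same seed are byte-identical; every run writes a manifest recording
inputs, configuration hash, and package version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path
from typing import Optional

import click
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from . import landscape as landscape_mod
from . import markers as markers_mod
from . import similarity as similarity_mod
from . import stats as stats_kit
from .indices import index_panel
from .presence import PresenceModelConfig
from .simulate import (SimConfig, simulate_cohort, simulate_marker_cohort,
                       simulate_segments)
from .variant_model import (FilterConfig, LesionSample, Patient, STAGES,
                            apply_filter_cascade, read_variants,
                            rejected_report, write_variants_tsv,
                            write_variants_vcf)

log = logging.getLogger("correaevo")


class FilterBlock(BaseModel):
    min_vaf: float = 0.02
    min_depth: int = 20
    min_base_quality: float = 15.0
    min_alt_reads: int = 5
    require_both_strands: bool = True
    min_minor_strand_fraction: float = 0.10
    max_pop_af: float = 0.01

    def to_config(self) -> FilterConfig:
        return FilterConfig(**self.model_dump())


class PresenceBlock(BaseModel):
    prior_present: float = 0.5
    error_rate: float = 0.005
    vaf_prior_low: float = 0.05
    vaf_prior_high: float = 0.5
    grid_points: int = 200

    def to_config(self) -> PresenceModelConfig:
        return PresenceModelConfig(**self.model_dump())


class SimilarityBlock(BaseModel):
    subtract_normal: bool = True
    tier_threshold: float = 20.0
    independent_floor: float = 0.15


class SimulationBlock(BaseModel):
    n_patients: int = 14
    trajectory_mix: tuple[int, int, int] = (8, 3, 3)
    n_variants_mean: float = 150.0
    depth_mean: float = 300.0
    purity: float = 0.8
    error_rate: float = 0.005
    marker_n_progressed: int = 14
    marker_n_stable: int = 25

    def to_config(self, seed: int) -> SimConfig:
        return SimConfig(
            n_patients=self.n_patients, trajectory_mix=self.trajectory_mix,
            n_variants_mean=self.n_variants_mean, depth_mean=self.depth_mean,
            purity=self.purity, error_rate=self.error_rate, seed=seed)


class IndexBlock(BaseModel):
    callable_mb: float = 35.0
    cis_cutoff: float = 0.2


class RunConfig(BaseModel):
    """Validated run configuration (YAML)."""

    manifest: dict[str, dict[str, str]] = Field(default_factory=dict)
    filters: FilterBlock = Field(default_factory=FilterBlock)
    presence_model: PresenceBlock = Field(default_factory=PresenceBlock)
    similarity: SimilarityBlock = Field(default_factory=SimilarityBlock)
    simulation: SimulationBlock = Field(default_factory=SimulationBlock)
    indices: IndexBlock = Field(default_factory=IndexBlock)
    seed: int = 0

    def validate_manifest(self) -> None:
        for pid, stages in self.manifest.items():
            unknown = set(stages) - set(STAGES)
            if unknown:
                raise ValueError(
                    f"manifest for {pid} names unknown stage(s) {sorted(unknown)}")


def load_config(path: Optional[str], seed: Optional[int]) -> RunConfig:
    raw = {}
    if path:
        raw = yaml.safe_load(Path(path).read_text()) or {}
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        raise click.ClickException(f"invalid configuration:\n{exc}") from exc
    if seed is not None:
        cfg = cfg.model_copy(update={"seed": seed})
    cfg.validate_manifest()
    return cfg


def _write_manifest(outdir: Path, cfg: RunConfig, command: str) -> None:
    payload = cfg.model_dump()
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"command": command, "version": __version__,
                "config_sha256": digest, "seed": cfg.seed,
                "config": payload}
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")


def _load_cohort_from_manifest(cfg: RunConfig) -> list[Patient]:
    """Read per-stage variant files named in the manifest into Patients.

    A patient missing a stage file is still loaded; downstream steps that
    require the stage exclude the patient with a logged reason.
    """
    patients = []
    for pid, stage_paths in sorted(cfg.manifest.items()):
        samples = {}
        for stage, path in stage_paths.items():
            p = Path(path)
            if not p.exists():
                log.warning("patient %s: missing %s file %s; stage skipped",
                            pid, stage, path)
                continue
            fmt = "vcf" if p.suffix == ".vcf" else "tsv"
            samples[stage] = LesionSample(
                patient_id=pid, stage=stage,
                variants=read_variants(p, format=fmt))
        patients.append(Patient(patient_id=pid, samples=samples))
    return patients


# ---------------------------------------------------------------------------
# analysis steps shared by subcommands
# ---------------------------------------------------------------------------

def run_simulate(cfg: RunConfig, outdir: Path) -> tuple[list[Patient], object]:
    sim_cfg = cfg.simulation.to_config(cfg.seed)
    cohort, truth = simulate_cohort(sim_cfg)
    sim_dir = outdir / "simulated"
    sim_dir.mkdir(parents=True, exist_ok=True)
    truth_rows = []
    for patient in cohort:
        for stage, sample in sorted(patient.samples.items()):
            write_variants_vcf(sample.variants,
                               sim_dir / f"{patient.patient_id}_{stage}.vcf",
                               sample_name=f"{patient.patient_id}_{stage}")
        truth_rows.append({"patient_id": patient.patient_id,
                           "model": truth.models[patient.patient_id]})
    pd.DataFrame(truth_rows, columns=["patient_id", "model"]).to_csv(
        sim_dir / "truth_models.tsv", sep="\t", index=False,
        lineterminator="\n")
    log.info("simulated %d patients into %s", len(cohort), sim_dir)
    return cohort, truth


def run_filter(cohort: list[Patient], cfg: RunConfig,
               outdir: Path) -> list[Patient]:
    fc = cfg.filters.to_config()
    filtered = []
    rej_dir = outdir / "filtered"
    rej_dir.mkdir(parents=True, exist_ok=True)
    for patient in cohort:
        new_samples = {}
        for stage, sample in patient.samples.items():
            kept, rejected = apply_filter_cascade(sample.variants, fc)
            new_samples[stage] = LesionSample(
                patient_id=patient.patient_id, stage=stage, variants=kept,
                cnv_events=sample.cnv_events,
                depth_pre_dedup=sample.depth_pre_dedup,
                depth_post_dedup=sample.depth_post_dedup,
                oscore=sample.oscore)
            rejected_report(
                rejected,
                rej_dir / f"{patient.patient_id}_{stage}_rejected.tsv")
        filtered.append(Patient(patient_id=patient.patient_id,
                                samples=new_samples,
                                clinical=patient.clinical))
    return filtered


def run_landscape(cohort: list[Patient], outdir: Path) -> None:
    rows = []
    for stage in ("IM", "LGIN", "HGIN", "EGC"):
        df = landscape_mod.mutation_frequency(cohort, stage, top_n=25)
        df.insert(0, "stage", stage)
        rows.append(df)
    pd.concat(rows, ignore_index=True).to_csv(
        outdir / "mutation_frequency.tsv", sep="\t", index=False,
        lineterminator="\n")
    pathways = landscape_mod.oncogenic_pathways()
    abn_rows = []
    for patient in cohort:
        for stage in ("IM", "LGIN", "HGIN", "EGC"):
            if stage not in patient.samples:
                continue
            abn = landscape_mod.pathway_abnormality(
                patient.samples[stage], pathways)
            for pathway in sorted(abn):
                abn_rows.append({"patient_id": patient.patient_id,
                                 "stage": stage, "pathway": pathway,
                                 "abnormal": int(abn[pathway])})
    pd.DataFrame(abn_rows, columns=["patient_id", "stage", "pathway",
                                    "abnormal"]).to_csv(
        outdir / "pathway_abnormality.tsv", sep="\t", index=False,
        lineterminator="\n")


def _complete_patients(cohort: list[Patient], stages: tuple[str, ...]
                       ) -> list[Patient]:
    usable = []
    for p in cohort:
        missing = [s for s in stages if s not in p.samples]
        if missing:
            log.warning("patient %s excluded: missing stage(s) %s",
                        p.patient_id, missing)
        else:
            usable.append(p)
    return usable


def run_similarity(cohort: list[Patient], cfg: RunConfig,
                   outdir: Path) -> pd.DataFrame:
    usable = _complete_patients(cohort, ("IM", "LGIN", "HGIN", "EGC"))
    sim_rows, conc_rows, tier_rows = [], [], []
    for patient in usable:
        result = similarity_mod.patient_similarity(
            patient, level="mutation",
            subtract_normal=cfg.similarity.subtract_normal)
        for (a, b), j in sorted(result.pairwise_jaccard.items()):
            if a < b:
                sim_rows.append({
                    "patient_id": patient.patient_id, "stage_a": a,
                    "stage_b": b, "jaccard": j,
                    "genetic_distance": result.genetic_distance[(a, b)]})
        conc_rows.append({"patient_id": patient.patient_id,
                          **result.concordance_with_egc})
        tier = similarity_mod.assign_tier(
            result.concordance_with_egc,
            threshold=cfg.similarity.tier_threshold,
            patient_id=patient.patient_id)
        tier_rows.append({"patient_id": patient.patient_id,
                          "tier": tier.tier,
                          "n_similar_stages": tier.n_similar_stages})
    pd.DataFrame(sim_rows, columns=["patient_id", "stage_a", "stage_b",
                                    "jaccard", "genetic_distance"]).to_csv(
        outdir / "pairwise_similarity.tsv", sep="\t", index=False,
        lineterminator="\n")
    conc = pd.DataFrame(conc_rows,
                        columns=["patient_id", "IM", "LGIN", "HGIN"])
    conc.to_csv(outdir / "concordance_matrix.tsv", sep="\t", index=False,
                lineterminator="\n")
    pd.DataFrame(tier_rows, columns=["patient_id", "tier",
                                     "n_similar_stages"]).to_csv(
        outdir / "concordance_tiers.tsv", sep="\t", index=False,
        lineterminator="\n")
    if len(conc) >= 2:
        matrix = conc.set_index("patient_id")
        cluster = similarity_mod.cluster_cases(matrix)
        newick = similarity_mod.linkage_to_newick(
            cluster.linkage, list(matrix.index))
        (outdir / "concordance_dendrogram.nwk").write_text(newick + "\n")
    return conc


def run_trajectory(cohort: list[Patient], cfg: RunConfig,
                   outdir: Path) -> pd.DataFrame:
    usable = _complete_patients(cohort, ("LGIN", "HGIN", "EGC"))
    rows = []
    for patient in usable:
        result = similarity_mod.patient_similarity(
            patient, level="mutation",
            subtract_normal=cfg.similarity.subtract_normal)
        j_le, j_he, j_lh = result.triple()
        call = similarity_mod.classify_trajectory(
            j_le, j_he, j_lh, floor=cfg.similarity.independent_floor,
            patient_id=patient.patient_id)
        rows.append({"patient_id": patient.patient_id, "model": call.model,
                     "j_lgin_egc": j_le, "j_hgin_egc": j_he,
                     "j_lgin_hgin": j_lh,
                     "floor": call.egc_similarity_floor})
    df = pd.DataFrame(rows, columns=["patient_id", "model", "j_lgin_egc",
                                     "j_hgin_egc", "j_lgin_hgin", "floor"])
    df.to_csv(outdir / "trajectory_calls.tsv", sep="\t", index=False,
              lineterminator="\n")
    return df


def run_indices(cohort: list[Patient], cfg: RunConfig,
                outdir: Path) -> None:
    sim_cfg = cfg.simulation.to_config(cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)
    rows = []
    for patient in cohort:
        for stage in ("IM", "LGIN", "HGIN", "EGC"):
            if stage not in patient.samples:
                continue
            segs = simulate_segments(sim_cfg, stage, rng)
            panel = index_panel(
                patient.samples[stage], cfg.indices.callable_mb,
                cnv_segments=[(s[0], s[1]) for s in segs],
                loh_segments=[(s[0], s[2]) for s in segs],
                cis_cutoff=cfg.indices.cis_cutoff)
            rows.append({"patient_id": patient.patient_id, "stage": stage,
                         "tmb": panel.tmb, "cis": panel.cis,
                         "loh_fraction": panel.loh_fraction,
                         "ith_math": "" if panel.ith is None else panel.ith,
                         "definitions": "tmb=nonsyn/Mb;cis=|log2|>=cutoff;"
                                        "loh=minorCN0;ith=MATH"})
    pd.DataFrame(rows, columns=["patient_id", "stage", "tmb", "cis",
                                "loh_fraction", "ith_math",
                                "definitions"]).to_csv(
        outdir / "index_panel.tsv", sep="\t", index=False,
        lineterminator="\n")


def run_validate(cfg: RunConfig, outdir: Path) -> None:
    rng = np.random.default_rng(cfg.seed + 2)
    records = simulate_marker_cohort(
        cfg.simulation.marker_n_progressed, cfg.simulation.marker_n_stable,
        rates={"TP53": (6 / 14, 23 / 25), "PRKDC": (7 / 14, 23 / 25),
               "PCLO": (4 / 14, 22 / 25)},
        rng=rng)
    markers_mod.write_marker_records(records, outdir / "marker_records.tsv")
    rows = []
    for rule in ("TP53", "PRKDC", "PCLO", "TP53 or PRKDC"):
        ev = markers_mod.evaluate_marker(records, rule)
        rows.append({"rule": rule, "sensitivity": ev.sensitivity,
                     "specificity": ev.specificity,
                     "fisher_p": ev.fisher_p})
    pd.DataFrame(rows, columns=["rule", "sensitivity", "specificity",
                                "fisher_p"]).to_csv(
        outdir / "marker_evaluation.tsv", sep="\t", index=False,
        lineterminator="\n")


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.command()
@click.argument("subcommand",
                type=click.Choice(["simulate", "filter", "landscape",
                                   "similarity", "trajectory", "indices",
                                   "validate", "all"]))
@click.option("--config", "config_path", type=click.Path(exists=True),
              default=None, help="YAML run configuration.")
@click.option("--seed", type=int, default=None,
              help="Random seed (overrides the config).")
@click.option("--outdir", type=click.Path(), default="correaevo_out",
              show_default=True)
@click.option("--log-level", default="INFO", show_default=True)
def main(subcommand: str, config_path: Optional[str], seed: Optional[int],
         outdir: str, log_level: str) -> None:
    """Run one analysis step (or ``all``) of the Correa-cascade pipeline."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")
    cfg = load_config(config_path, seed)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_manifest(out, cfg, subcommand)

    needs_cohort = subcommand in ("filter", "landscape", "similarity",
                                  "trajectory", "indices")
    cohort: list[Patient] = []
    if subcommand in ("simulate", "all"):
        cohort, _ = run_simulate(cfg, out)
    elif needs_cohort:
        if not cfg.manifest:
            raise click.ClickException(
                f"subcommand {subcommand!r} needs an input manifest in the config")
        cohort = _load_cohort_from_manifest(cfg)

    if subcommand in ("filter", "all") or (needs_cohort and subcommand != "filter"):
        cohort = run_filter(cohort, cfg, out)
    if subcommand in ("landscape", "all"):
        run_landscape(cohort, out)
    if subcommand in ("similarity", "all"):
        run_similarity(cohort, cfg, out)
    if subcommand in ("trajectory", "all"):
        run_trajectory(cohort, cfg, out)
    if subcommand in ("indices", "all"):
        run_indices(cohort, cfg, out)
    if subcommand in ("validate", "all"):
        run_validate(cfg, out)
    log.info("done: %s -> %s", subcommand, out)


if __name__ == "__main__":  # pragma: no cover
    main()
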