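"""Seedable simulator of multi-stage Correa-cascade cohorts with known truth.

The generator emulates the structure of the study cohort the pipeline is
built for: 14 patients, each contributing matched IM/LGIN/HGIN/EGC lesions
plus an NM (normal mucosa) control, with per-patient evolutionary
trajectories drawn from an 8/3/3 linear/punctuated/independent mixture.
Variant sharing between stages follows the generating model:

* linear — a truncal set runs through LGIN/HGIN/EGC and HGIN shares an
  extra private branch with EGC, so J(HGIN,EGC) > J(LGIN,EGC);
* punctuated — the extra branch joins LGIN and EGC instead;
* independent — LGIN and HGIN share a large set while EGC overlaps both
  only marginally.

IM is essentially private (its small EGC overlap mirrors the ~2%
concordance seen in real cascades). Every variant carries simulated read
evidence — depth ~ Poisson(mean coverage), alt reads ~ Binomial(depth,
VAF x purity) — plus background error sites at the per-base error rate,
so the filter cascade and the presence posterior see realistic inputs.
Substitutions are C>T-dominant. A fixed seed makes the entire cohort,
including emitted VCF bytes, reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .markers import MarkerRecord
from .variant_model import CNVEvent, LesionSample, Patient, VariantCall

__all__ = [
    "SimConfig",
    "CohortTruth",
    "PatientTruth",
    "simulate_patient",
    "simulate_cohort",
    "simulate_marker_cohort",
    "simulate_filter_variants",
    "background_pileup",
]

LESION_STAGES = ("IM", "LGIN", "HGIN", "EGC")

#: Pairwise-sharing composition per trajectory model, as fractions of the
#: per-stage variant budget: truncal (LGIN+HGIN+EGC), LGIN-HGIN,
#: LGIN-EGC and HGIN-EGC pair branches. Chosen well-separated so each
#: model's expected Jaccard ordering is unambiguous.
MODEL_SHARING: dict[str, dict[str, float]] = {
    "linear": {"trunk": 0.30, "lh": 0.05, "le": 0.02, "he": 0.25},
    "punctuated": {"trunk": 0.30, "lh": 0.05, "le": 0.25, "he": 0.02},
    "independent": {"trunk": 0.02, "lh": 0.40, "le": 0.03, "he": 0.03},
}

#: Substitution spectrum; C>T transitions dominate, as in aged gastric
#: mucosa.
_SUBSTITUTIONS = (("C", "T"), ("G", "A"), ("C", "A"), ("C", "G"),
                  ("T", "C"), ("T", "A"), ("T", "G"), ("A", "G"))
_SUB_WEIGHTS = (0.40, 0.20, 0.08, 0.07, 0.10, 0.05, 0.05, 0.05)

_EFFECTS = ("missense", "nonsense", "frameshift", "splice_site",
            "inframe_indel", "synonymous")
_EFFECT_WEIGHTS = (0.55, 0.06, 0.07, 0.05, 0.05, 0.22)
_DRIVER_EFFECTS = ("missense", "nonsense", "frameshift")
_DRIVER_EFFECT_WEIGHTS = (0.7, 0.2, 0.1)

#: Synthetic exome: seven contigs of 5 Mb tiled by 50 kb gene bins.
_N_CONTIGS = 7
_CONTIG_MB = 5.0
_GENE_BIN_BP = 50_000
EXOME_MB = _N_CONTIGS * _CONTIG_MB

#: Per-stage driver mutation probabilities (IM, LGIN, HGIN, EGC), seeded
#: from the stage frequencies reported for these genes in gastric
#: carcinogenesis cohorts.
DEFAULT_DRIVER_GENES: dict[str, tuple[float, float, float, float]] = {
    "TP53": (0.0, 0.43, 0.50, 0.57),
    "PRKDC": (0.0, 0.14, 0.21, 0.36),
    "PCLO": (0.07, 0.21, 0.29, 0.43),
    "DNAH5": (0.14, 0.36, 0.0, 0.14),
    "APC": (0.07, 0.29, 0.14, 0.14),
}


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_patients: int = 14
    trajectory_mix: tuple[int, int, int] = (8, 3, 3)  # linear/punctuated/independent
    n_variants_mean: float = 150.0
    n_variants_dispersion: float = 10.0  # negative-binomial size parameter
    im_egc_overlap: float = 0.01
    depth_mean: float = 300.0
    purity: float = 0.8
    error_rate: float = 0.005
    driver_genes: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DRIVER_GENES))
    n_cnv_mean: float = 40.0
    n_segments: int = 50
    cnv_alteration_prob: tuple[float, float, float, float] = (0.08, 0.15, 0.20, 0.28)
    loh_prob: tuple[float, float, float, float] = (0.05, 0.10, 0.15, 0.22)
    n_artifact_variants: float = 5.0  # NM-shared sites removed by NM subtraction
    n_error_sites: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("im_egc_overlap", "purity"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0,1]")
        if not (0.0 < self.error_rate <= 0.05):
            raise ValueError("error_rate must be in (0, 0.05]")
        for model, parts in MODEL_SHARING.items():
            if sum(parts.values()) > 1.0:
                raise ValueError(f"sharing fractions for {model} exceed 1")


@dataclass
class PatientTruth:
    patient_id: str
    model: str
    # variant key -> set of lesion stages truly carrying it
    presence: dict[tuple[str, int, str, str], frozenset[str]]


@dataclass
class CohortTruth:
    models: dict[str, str]
    patients: dict[str, PatientTruth]


def gene_for_position(chrom: str, pos: int,
                      drivers: Sequence[str] = tuple(DEFAULT_DRIVER_GENES)) -> str:
    """Gene label for a synthetic-exome coordinate (50 kb tiling bins).

    The first bins of chr1 are reserved for the configured driver genes;
    every other bin gets a systematic filler symbol.
    """
    contig_idx = int(chrom.removeprefix("chr")) - 1
    bin_idx = contig_idx * int(_CONTIG_MB * 1e6 / _GENE_BIN_BP) \
        + (pos - 1) // _GENE_BIN_BP
    if bin_idx < len(drivers):
        return list(drivers)[bin_idx]
    return f"GENE{bin_idx:04d}"


def _driver_bin(gene_idx: int) -> tuple[str, int, int]:
    start = gene_idx * _GENE_BIN_BP + 1
    return "chr1", start, start + _GENE_BIN_BP - 1


def _random_positions(rng: np.random.Generator, n: int,
                      skip_driver_bins: int) -> list[tuple[str, int]]:
    """Unique random exome positions outside the reserved driver bins."""
    out: set[tuple[str, int]] = set()
    reserved_end = skip_driver_bins * _GENE_BIN_BP
    while len(out) < n:
        chrom_idx = int(rng.integers(0, _N_CONTIGS))
        pos = int(rng.integers(1, int(_CONTIG_MB * 1e6) + 1))
        if chrom_idx == 0 and pos <= reserved_end:
            continue
        out.add((f"chr{chrom_idx + 1}", pos))
    return sorted(out)


def _draw_effect(rng: np.random.Generator, driver: bool = False) -> str:
    if driver:
        return str(rng.choice(_DRIVER_EFFECTS, p=_DRIVER_EFFECT_WEIGHTS))
    return str(rng.choice(_EFFECTS, p=_EFFECT_WEIGHTS))


def _draw_substitution(rng: np.random.Generator) -> tuple[str, str]:
    i = int(rng.choice(len(_SUBSTITUTIONS), p=_SUB_WEIGHTS))
    return _SUBSTITUTIONS[i]


def _negbin(rng: np.random.Generator, mean: float, size_param: float) -> int:
    """Negative-binomial draw parameterised by mean and size (dispersion)."""
    if mean <= 0:
        return 0
    p = size_param / (size_param + mean)
    return int(rng.negative_binomial(size_param, p))


def _read_evidence(rng: np.random.Generator, true_vaf: float,
                   depth_mean: float) -> tuple[int, int, int, int, float]:
    """(depth, alt, alt_fwd, alt_rev, mean_bq) for one site."""
    depth = max(1, int(rng.poisson(depth_mean)))
    alt = int(rng.binomial(depth, min(true_vaf, 1.0)))
    fwd = int(rng.binomial(alt, 0.5)) if alt else 0
    # one decimal, stored as float32: survives the VCF text round trip exactly
    bq = float(np.float32(round(float(np.clip(rng.normal(32.0, 2.5), 10.0, 45.0)), 1)))
    return depth, alt, fwd, alt - fwd, bq


def _call_from_evidence(chrom: str, pos: int, ref: str, alt_allele: str,
                        gene: str, effect: str,
                        evidence: tuple[int, int, int, int, float]
                        ) -> VariantCall:
    depth, alt, fwd, rev, bq = evidence
    return VariantCall.from_evidence(
        chrom=chrom, pos=pos, ref=ref, alt=alt_allele, gene=gene,
        effect=effect, depth=depth, alt_reads=alt, mean_base_quality=bq,
        alt_fwd=fwd, alt_rev=rev)


@dataclass
class _ProtoVariant:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: str
    base_vaf: float
    stages: frozenset[str]

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


def simulate_patient(config: SimConfig, model: str,
                     rng: np.random.Generator,
                     patient_id: str = "P01") -> tuple[Patient, PatientTruth]:
    """One patient with NM control and four lesion stages under ``model``."""
    if model not in MODEL_SHARING:
        raise ValueError(f"model must be one of {sorted(MODEL_SHARING)}")
    drivers = list(config.driver_genes)
    parts = MODEL_SHARING[model]
    n = config.n_variants_mean
    counts = {
        "trunk": _negbin(rng, parts["trunk"] * n, config.n_variants_dispersion),
        "lh": _negbin(rng, parts["lh"] * n, config.n_variants_dispersion),
        "le": _negbin(rng, parts["le"] * n, config.n_variants_dispersion),
        "he": _negbin(rng, parts["he"] * n, config.n_variants_dispersion),
        "ie": _negbin(rng, config.im_egc_overlap * n,
                      config.n_variants_dispersion),
    }
    shared_total = counts["trunk"] + counts["lh"] + counts["le"] + counts["he"]
    privates = {}
    for stage in LESION_STAGES:
        target = _negbin(rng, n, config.n_variants_dispersion)
        already = counts["trunk"] if stage != "IM" else counts["ie"]
        if stage == "LGIN":
            already += counts["lh"] + counts["le"]
        elif stage == "HGIN":
            already += counts["lh"] + counts["he"]
        elif stage == "EGC":
            already += counts["le"] + counts["he"] + counts["ie"]
        privates[stage] = max(0, target - already)

    memberships: list[frozenset[str]] = []
    memberships += [frozenset({"LGIN", "HGIN", "EGC"})] * counts["trunk"]
    memberships += [frozenset({"LGIN", "HGIN"})] * counts["lh"]
    memberships += [frozenset({"LGIN", "EGC"})] * counts["le"]
    memberships += [frozenset({"HGIN", "EGC"})] * counts["he"]
    memberships += [frozenset({"IM", "EGC"})] * counts["ie"]
    for stage in LESION_STAGES:
        memberships += [frozenset({stage})] * privates[stage]
    n_artifacts = int(rng.poisson(config.n_artifact_variants))
    memberships += [frozenset({"NM", *LESION_STAGES})] * n_artifacts

    positions = _random_positions(rng, len(memberships), len(drivers))
    protos: list[_ProtoVariant] = []
    for (chrom, pos), stages in zip(positions, memberships):
        ref, alt = _draw_substitution(rng)
        base_vaf = float(rng.uniform(0.45, 0.55)) if "NM" in stages \
            else float(rng.uniform(0.10, 0.40))
        protos.append(_ProtoVariant(
            chrom=chrom, pos=pos, ref=ref, alt=alt,
            gene=gene_for_position(chrom, pos, drivers),
            effect=_draw_effect(rng), base_vaf=base_vaf, stages=stages))

    # driver genes: independent per-stage Bernoulli at the configured rates
    for gi, (gene, probs) in enumerate(config.driver_genes.items()):
        chrom, start, end = _driver_bin(gi)
        for stage, prob in zip(LESION_STAGES, probs):
            if rng.random() < prob:
                pos = int(rng.integers(start, end + 1))
                ref, alt = _draw_substitution(rng)
                protos.append(_ProtoVariant(
                    chrom=chrom, pos=pos, ref=ref, alt=alt, gene=gene,
                    effect=_draw_effect(rng, driver=True),
                    base_vaf=float(rng.uniform(0.15, 0.40)),
                    stages=frozenset({stage})))

    # resolve the rare position collision among driver draws
    seen: dict[tuple[str, int, str, str], _ProtoVariant] = {}
    for p in protos:
        if p.key in seen:
            seen[p.key] = dataclasses.replace(
                seen[p.key], stages=seen[p.key].stages | p.stages)
        else:
            seen[p.key] = p
    protos = list(seen.values())

    cnv_by_stage = _simulate_cnv_events(config, model, rng)
    samples: dict[str, LesionSample] = {}
    for stage in ("NM", *LESION_STAGES):
        calls = []
        for p in protos:
            if stage not in p.stages:
                continue
            purity = 1.0 if stage == "NM" else config.purity
            evidence = _read_evidence(rng, p.base_vaf * purity,
                                      config.depth_mean)
            calls.append(_call_from_evidence(
                p.chrom, p.pos, p.ref, p.alt, p.gene, p.effect, evidence))
        # background error sites present only as sequencing noise
        n_err = int(rng.poisson(config.n_error_sites))
        taken = {p.key[:2] for p in protos}
        for chrom, pos in _random_positions(rng, n_err, len(drivers)):
            if (chrom, pos) in taken:
                continue
            ref, alt_allele = _draw_substitution(rng)
            evidence = _read_evidence(rng, config.error_rate,
                                      config.depth_mean)
            calls.append(_call_from_evidence(
                chrom, pos, ref, alt_allele,
                gene_for_position(chrom, pos, drivers), "missense", evidence))
        samples[stage] = LesionSample(
            patient_id=patient_id, stage=stage, variants=calls,
            cnv_events=cnv_by_stage.get(stage, []),
            depth_pre_dedup=float(rng.normal(500.0, 40.0)),
            depth_post_dedup=float(rng.normal(140.0, 15.0)),
            oscore=float(rng.uniform(38.0, 55.0)))

    truth = PatientTruth(
        patient_id=patient_id, model=model,
        presence={p.key: p.stages & frozenset(LESION_STAGES)
                  for p in protos if p.stages & frozenset(LESION_STAGES)})
    return Patient(patient_id=patient_id, samples=samples), truth


def _simulate_cnv_events(config: SimConfig, model: str,
                         rng: np.random.Generator
                         ) -> dict[str, list[CNVEvent]]:
    """Gene-level CNV event sets with the same sharing skeleton as mutations."""
    parts = MODEL_SHARING[model]
    n = config.n_cnv_mean
    groups = {
        frozenset({"LGIN", "HGIN", "EGC"}): _negbin(rng, parts["trunk"] * n, 8),
        frozenset({"LGIN", "HGIN"}): _negbin(rng, parts["lh"] * n, 8),
        frozenset({"LGIN", "EGC"}): _negbin(rng, parts["le"] * n, 8),
        frozenset({"HGIN", "EGC"}): _negbin(rng, parts["he"] * n, 8),
        frozenset({"IM", "EGC"}): _negbin(rng, config.im_egc_overlap * n, 8),
    }
    for stage in LESION_STAGES:
        groups[frozenset({stage})] = _negbin(rng, 0.5 * n, 8)
    by_stage: dict[str, list[CNVEvent]] = {s: [] for s in LESION_STAGES}
    used: set[tuple[str, str]] = set()
    gene_counter = 0
    for stages, count in groups.items():
        for _ in range(count):
            gene = f"GENE{5000 + gene_counter:05d}"
            gene_counter += 1
            direction = "gain" if rng.random() < 0.5 else "loss"
            if (gene, direction) in used:
                continue
            used.add((gene, direction))
            magnitude = float(rng.normal(0.7, 0.15))
            log2 = abs(magnitude) if direction == "gain" else -abs(magnitude)
            event = CNVEvent(gene=gene, direction=direction, log2_ratio=log2)
            for s in stages:
                by_stage[s].append(event)
    return by_stage


def simulate_segments(config: SimConfig, stage: str,
                      rng: np.random.Generator
                      ) -> list[tuple[float, float, int]]:
    """(length_bp, log2_ratio, minor_cn) segment triples for one stage.

    Alteration and LOH probabilities rise along the cascade, giving the
    simulated cohorts the increasing CIS/LOH trends seen in progression.
    """
    stage_idx = LESION_STAGES.index(stage)
    p_alt = config.cnv_alteration_prob[stage_idx]
    p_loh = config.loh_prob[stage_idx]
    segments = []
    for _ in range(config.n_segments):
        length = float(rng.uniform(2e5, 2e6))
        if rng.random() < p_alt:
            log2 = float(rng.normal(0.7, 0.15)) * (1 if rng.random() < 0.5 else -1)
        else:
            log2 = float(rng.normal(0.0, 0.03))
        minor_cn = 0 if rng.random() < p_loh else 1
        segments.append((length, log2, minor_cn))
    return segments


def simulate_cohort(config: SimConfig) -> tuple[list[Patient], CohortTruth]:
    """A full cohort under the configured trajectory mixture."""
    rng = np.random.default_rng(config.seed)
    n_lin, n_punct, n_indep = config.trajectory_mix
    labels = (["linear"] * n_lin + ["punctuated"] * n_punct
              + ["independent"] * n_indep)
    if len(labels) < config.n_patients:
        raise ValueError("trajectory_mix counts fewer patients than n_patients")
    labels = labels[:config.n_patients]
    patients: list[Patient] = []
    truth = CohortTruth(models={}, patients={})
    for i, model in enumerate(labels, start=1):
        pid = f"P{i:02d}"
        patient, pt = simulate_patient(config, model, rng, patient_id=pid)
        patients.append(patient)
        truth.models[pid] = model
        truth.patients[pid] = pt
    return patients, truth


def background_pileup(truth: PatientTruth, config: SimConfig,
                      rng: np.random.Generator
                      ) -> dict[tuple[str, tuple[str, int, str, str]],
                                tuple[int, int]]:
    """Simulated site coverage for (stage, variant) cells where the variant
    is truly absent: depth ~ Poisson(mean), alt reads at the error rate."""
    pileup = {}
    for key, stages in truth.presence.items():
        for stage in LESION_STAGES:
            if stage in stages:
                continue
            depth = max(1, int(rng.poisson(config.depth_mean)))
            alt = int(rng.binomial(depth, config.error_rate))
            pileup[(stage, key)] = (depth, alt)
    return pileup


def simulate_marker_cohort(n_progressed: int, n_stable: int,
                           rates: Mapping[str, tuple[float, float]],
                           rng: np.random.Generator | int = 0
                           ) -> list[MarkerRecord]:
    """Validation-cohort records with Bernoulli marker statuses.

    ``rates`` maps each marker (TP53, PRKDC, PCLO) to its target
    (sensitivity, specificity): the positive rate is the sensitivity among
    progressed patients and one minus the specificity among stable ones.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    for marker, (sens, spec) in rates.items():
        if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
            raise ValueError(f"rates for {marker} outside [0,1]")
    records = []
    for outcome, count in (("progressed", n_progressed), ("stable", n_stable)):
        for i in range(count):
            status = {}
            for marker in ("TP53", "PRKDC", "PCLO"):
                sens, spec = rates.get(marker, (0.0, 1.0))
                p_pos = sens if outcome == "progressed" else 1.0 - spec
                status[marker] = rng.random() < p_pos
            records.append(MarkerRecord(
                patient_id=f"V{outcome[0].upper()}{i + 1:03d}",
                tp53_status="MT" if status["TP53"] else "WT",
                prkdc_status="positive" if status["PRKDC"] else "negative",
                pclo_status="positive" if status["PCLO"] else "negative",
                outcome=outcome))
    return records


def simulate_filter_variants(n: int, rng: np.random.Generator | int = 0
                             ) -> list[VariantCall]:
    """Random candidate calls spanning every filter rule's failure region.

    Field distributions straddle each threshold (depth around 20, base
    quality around 15, VAF down to the error floor, strand split from
    balanced to one-sided, occasional population-frequency hits and
    blacklist flags), so a filter run rejects a substantial share of the
    calls for every rule.
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    positions = _random_positions(rng, n, len(DEFAULT_DRIVER_GENES))
    calls = []
    for chrom, pos in positions:
        ref, alt_allele = _draw_substitution(rng)
        depth = int(rng.integers(1, 400))
        vaf_true = float(rng.uniform(0.003, 0.30))
        alt = int(rng.binomial(depth, vaf_true))
        p_fwd = float(rng.uniform(0.0, 1.0))
        fwd = int(rng.binomial(alt, p_fwd)) if alt else 0
        bq = float(np.float32(round(float(rng.uniform(5.0, 40.0)), 1)))
        def _pop_af() -> float | None:
            if rng.random() < 0.15:
                return float(rng.uniform(0.0, 0.05))
            return None
        calls.append(VariantCall.from_evidence(
            chrom=chrom, pos=pos, ref=ref, alt=alt_allele,
            gene=gene_for_position(chrom, pos), effect="missense",
            depth=depth, alt_reads=alt, mean_base_quality=bq,
            alt_fwd=fwd, alt_rev=alt - fwd,
            pop_af_1kg=_pop_af(), pop_af_exac_all=_pop_af(),
            pop_af_exac_eas=_pop_af(),
            blacklist=bool(rng.random() < 0.10)))
    return calls
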