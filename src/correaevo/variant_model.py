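"""Domain types and somatic-variant plumbing for multi-stage gastric lesion genomes.

This module holds the core records of the pipeline — a somatic variant call
with its read-level evidence, a copy-number event, a lesion sample, and a
patient with matched lesions across the Correa cascade (NM, IM, LGIN, HGIN,
EGC) — together with readers/writers for VCF and MAF-like TSV tables, the
seven-rule somatic filter cascade applied after candidate calling, and
sample-level sequencing-depth / DNA-damage quality control.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pysam

__all__ = [
    "STAGES",
    "LESION_STAGES",
    "VariantCall",
    "CNVEvent",
    "LesionSample",
    "Patient",
    "FilterConfig",
    "QCVerdict",
    "VcfFieldMap",
    "DataIntegrityError",
    "SchemaError",
    "VariantParseError",
    "read_variants",
    "write_variants_tsv",
    "write_variants_vcf",
    "read_seg",
    "read_cnv_events",
    "apply_filter_cascade",
    "qc_sample",
]

#: Correa-cascade stage labels in histological order. NM is the matched
#: normal-mucosa control; the four lesion stages are sampled per patient.
STAGES: tuple[str, ...] = ("NM", "IM", "LGIN", "HGIN", "EGC")
LESION_STAGES: tuple[str, ...] = ("IM", "LGIN", "HGIN", "EGC")


class DataIntegrityError(ValueError):
    """Raised when read-level evidence is internally inconsistent."""


class SchemaError(ValueError):
    """Raised when a tabular input lacks a mandatory column."""


class VariantParseError(ValueError):
    """Raised when a variant record cannot be parsed; names the line."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantCall:
    """One somatic candidate with genomic coordinates and read evidence.

    Coordinates are 1-based, fully closed (VCF convention). Identity of a
    variant within a sample is ``(chrom, pos, ref, alt)``; gene and effect
    annotations are carried metadata, never part of identity. Population
    allele frequencies of ``None`` mean the variant is absent from the
    database (how novel somatic variants present).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str = ""
    effect: str = ""
    depth: int = 0
    alt_reads: int = 0
    vaf: float = 0.0
    mean_base_quality: float = 0.0
    alt_fwd: int = 0
    alt_rev: int = 0
    pop_af_1kg: float | None = None
    pop_af_exac_all: float | None = None
    pop_af_exac_eas: float | None = None
    blacklist: bool = False

    def __post_init__(self) -> None:
        if self.depth < 0 or self.alt_reads < 0:
            raise DataIntegrityError(
                f"negative read counts at {self.chrom}:{self.pos}")
        if self.alt_reads > self.depth:
            raise DataIntegrityError(
                f"alt_reads ({self.alt_reads}) > depth ({self.depth}) "
                f"at {self.chrom}:{self.pos}")
        if self.alt_fwd + self.alt_rev != self.alt_reads:
            raise DataIntegrityError(
                f"strand counts {self.alt_fwd}+{self.alt_rev} != alt_reads "
                f"{self.alt_reads} at {self.chrom}:{self.pos}")
        if not (0.0 <= self.vaf <= 1.0):
            raise DataIntegrityError(f"VAF {self.vaf} outside [0,1]")
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) >= 1e-9:
            raise DataIntegrityError(
                f"VAF {self.vaf} inconsistent with {self.alt_reads}/{self.depth}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key ``(chrom, pos, ref, alt)``."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @classmethod
    def from_evidence(cls, chrom: str, pos: int, ref: str, alt: str,
                      depth: int, alt_reads: int, **kwargs) -> "VariantCall":
        """Build a call with VAF derived from ``alt_reads / depth``."""
        vaf = alt_reads / depth if depth > 0 else 0.0
        return cls(chrom=chrom, pos=pos, ref=ref, alt=alt, depth=depth,
                   alt_reads=alt_reads, vaf=vaf, **kwargs)


@dataclass(frozen=True)
class CNVEvent:
    """A gene-level copy-number event; identity for similarity is (gene, direction)."""

    gene: str
    direction: str  # "gain" | "loss"
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"direction must be gain|loss, got {self.direction!r}")
        if self.direction == "gain" and self.log2_ratio <= 0:
            raise ValueError(
                f"gain with log2_ratio {self.log2_ratio} <= 0 for {self.gene}")
        if self.direction == "loss" and self.log2_ratio >= 0:
            raise ValueError(
                f"loss with log2_ratio {self.log2_ratio} >= 0 for {self.gene}")

    @property
    def key(self) -> tuple[str, str]:
        return (self.gene, self.direction)


@dataclass
class LesionSample:
    """All filtered variants and CNV events for one (patient, stage) specimen."""

    patient_id: str
    stage: str
    variants: list[VariantCall] = field(default_factory=list)
    cnv_events: list[CNVEvent] = field(default_factory=list)
    depth_pre_dedup: float = 0.0
    depth_post_dedup: float = 0.0
    oscore: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(
                f"stage {self.stage!r} not one of {STAGES}")
        keys = [v.key for v in self.variants]
        if len(keys) != len(set(keys)):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise DataIntegrityError(
                f"duplicate variant keys in {self.patient_id}/{self.stage}: "
                f"{sorted(dupes)[:3]}")

    def variant_keys(self) -> frozenset[tuple[str, int, str, str]]:
        return frozenset(v.key for v in self.variants)

    def cnv_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset(e.key for e in self.cnv_events)

    def mutated_genes(self, effects: frozenset[str] | None = None) -> frozenset[str]:
        """Genes carrying >=1 variant, optionally restricted to an effect class."""
        return frozenset(
            v.gene for v in self.variants
            if v.gene and (effects is None or v.effect in effects))


@dataclass
class Patient:
    """One patient's matched lesion samples across the Correa cascade."""

    patient_id: str
    samples: dict[str, LesionSample] = field(default_factory=dict)
    clinical: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for stage, sample in self.samples.items():
            if stage not in STAGES:
                raise ValueError(f"unknown stage {stage!r} for {self.patient_id}")
            if sample.stage != stage:
                raise ValueError(
                    f"sample stage {sample.stage!r} filed under {stage!r}")

    def stage_keys(self, stage: str, *, subtract_normal: bool = False
                   ) -> frozenset[tuple[str, int, str, str]]:
        """Variant keys for a stage, optionally with NM-control keys removed."""
        keys = self.samples[stage].variant_keys()
        if subtract_normal and "NM" in self.samples:
            keys = keys - self.samples["NM"].variant_keys()
        return keys

    def has_stages(self, stages: Iterable[str]) -> bool:
        return all(s in self.samples for s in stages)


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the somatic filter cascade.

    Defaults are the calling thresholds applied after VarScan2 candidate
    generation: a 2% minimum VAF from the caller, then rules (1)-(7) in
    order — minimum depth 20, base quality 15, >=5 supporting reads,
    support on both strands, strand bias <=10% (read as the minor-strand
    share of supporting reads being at least ``min_minor_strand_fraction``),
    <=1% population frequency in 1000 Genomes and ExAC (ALL and EAS), and
    absence from a recurrent-artifact blacklist.
    """

    min_vaf: float = 0.02
    min_depth: int = 20
    min_base_quality: float = 15.0
    min_alt_reads: int = 5
    require_both_strands: bool = True
    min_minor_strand_fraction: float = 0.10
    max_pop_af: float = 0.01

    # reason identifiers, in cascade order
    RULES = ("min_vaf", "min_depth", "min_base_quality", "min_alt_reads",
             "both_strands", "strand_bias", "population_frequency", "blacklist")


def _first_failed_rule(v: VariantCall, cfg: FilterConfig) -> str | None:
    if v.depth == 0:
        if v.alt_reads > 0:
            raise DataIntegrityError(
                f"depth=0 with alt_reads={v.alt_reads} at {v.chrom}:{v.pos}")
        return "min_depth"
    if v.vaf < cfg.min_vaf:
        return "min_vaf"
    if v.depth < cfg.min_depth:
        return "min_depth"
    if v.mean_base_quality < cfg.min_base_quality:
        return "min_base_quality"
    if v.alt_reads < cfg.min_alt_reads:
        return "min_alt_reads"
    if cfg.require_both_strands and (v.alt_fwd == 0 or v.alt_rev == 0):
        return "both_strands"
    if v.alt_reads > 0 and min(v.alt_fwd, v.alt_rev) / v.alt_reads < cfg.min_minor_strand_fraction:
        return "strand_bias"
    for af in (v.pop_af_1kg, v.pop_af_exac_all, v.pop_af_exac_eas):
        if af is not None and af > cfg.max_pop_af:
            return "population_frequency"
    if v.blacklist:
        return "blacklist"
    return None


def apply_filter_cascade(
    variants: Sequence[VariantCall],
    thresholds: FilterConfig | None = None,
) -> tuple[list[VariantCall], list[tuple[VariantCall, str]]]:
    """Apply the somatic filter cascade in rule order.

    Returns ``(kept, rejected)`` where each rejected record carries the
    identifier of the *first* failing rule. ``kept`` plus the rejected
    variants partition the input; order is preserved.
    """
    cfg = thresholds or FilterConfig()
    kept: list[VariantCall] = []
    rejected: list[tuple[VariantCall, str]] = []
    for v in variants:
        reason = _first_failed_rule(v, cfg)
        if reason is None:
            kept.append(v)
        else:
            rejected.append((v, reason))
    return kept, rejected


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QCVerdict:
    passed: bool
    failed_checks: frozenset[str]


#: (pre-dedup, post-dedup) mean-coverage thresholds by sample role.
_DEPTH_THRESHOLDS = {"lesion": (200.0, 60.0), "normal": (100.0, 30.0)}
_MIN_OSCORE = 35.0


def qc_sample(sample: LesionSample, role: str) -> QCVerdict:
    """Depth and DNA-damage QC.

    Lesion samples must exceed 200x pre-deduplication and 60x
    post-deduplication mean coverage; matched normals 100x/30x. Either
    role additionally requires a Picard-style total damage OScore >= 35.
    """
    if role not in _DEPTH_THRESHOLDS:
        raise ValueError(f"role must be lesion|normal, got {role!r}")
    pre_min, post_min = _DEPTH_THRESHOLDS[role]
    failed = set()
    if not sample.depth_pre_dedup > pre_min:
        failed.add("pre_dedup_depth")
    if not sample.depth_post_dedup > post_min:
        failed.add("post_dedup_depth")
    if sample.oscore < _MIN_OSCORE:
        failed.add("oscore")
    return QCVerdict(passed=not failed, failed_checks=frozenset(failed))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfFieldMap:
    """Names of the INFO/FORMAT keys the VCF dialect uses for evidence fields."""

    base_quality: str = "BQ"
    alt_fwd: str = "SAF"
    alt_rev: str = "SAR"
    pop_af_1kg: str = "AF_1KG"
    pop_af_exac_all: str = "AF_EXAC_ALL"
    pop_af_exac_eas: str = "AF_EXAC_EAS"
    blacklist: str = "BLACKLIST"
    gene: str = "GENE"
    effect: str = "EFFECT"


#: Mandatory columns of the MAF-like TSV dialect.
TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "gene", "effect", "depth", "alt_reads",
    "vaf", "mean_base_quality", "alt_fwd", "alt_rev",
    "pop_af_1kg", "pop_af_exac_all", "pop_af_exac_eas", "blacklist",
]


def read_variants(path: str | Path, format: str = "vcf",
                  fields: VcfFieldMap | None = None) -> list[VariantCall]:
    """Read variant calls from VCF 4.x or the MAF-like TSV dialect.

    Multi-allelic VCF records are decomposed into one call per alternate
    allele. 1-based coordinates are preserved.
    """
    path = Path(path)
    if format == "vcf":
        return _read_vcf(path, fields or VcfFieldMap())
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"format must be vcf|tsv, got {format!r}")


def _info_get(rec, key, default=None):
    # pysam raises when the key is not declared in the header at all
    try:
        return rec.info.get(key, default)
    except (KeyError, ValueError):
        return default


def _info_scalar(rec, key, default=None):
    val = _info_get(rec, key, default)
    if isinstance(val, tuple):
        val = val[0] if val else default
    return val


def _read_vcf(path: Path, fm: VcfFieldMap) -> list[VariantCall]:
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_names = list(vf.header.samples)
        for rec in vf:
            try:
                if sample_names:
                    fmt = rec.samples[sample_names[0]]
                    depth = fmt.get("DP")
                    ad = fmt.get("AD")
                else:  # evidence in INFO for sample-less VCFs
                    depth = _info_scalar(rec, "DP")
                    ad = _info_get(rec, "AD")
                if depth is None or ad is None:
                    raise VariantParseError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks DP/AD")
                alts = rec.alts or ()
                adf = _info_get(rec, fm.alt_fwd)
                adr = _info_get(rec, fm.alt_rev)
                bq = _info_scalar(rec, fm.base_quality, 0.0) or 0.0
                for i, alt in enumerate(alts):
                    alt_reads = int(ad[i + 1])
                    fwd = int(adf[i]) if adf is not None else alt_reads
                    rev = int(adr[i]) if adr is not None else 0
                    calls.append(VariantCall.from_evidence(
                        chrom=rec.chrom, pos=rec.pos, ref=rec.ref, alt=alt,
                        depth=int(depth), alt_reads=alt_reads,
                        gene=str(_info_scalar(rec, fm.gene, "") or ""),
                        effect=str(_info_scalar(rec, fm.effect, "") or ""),
                        mean_base_quality=float(bq),
                        alt_fwd=fwd, alt_rev=rev,
                        pop_af_1kg=_maybe_float(_info_scalar(rec, fm.pop_af_1kg)),
                        pop_af_exac_all=_maybe_float(_info_scalar(rec, fm.pop_af_exac_all)),
                        pop_af_exac_eas=_maybe_float(_info_scalar(rec, fm.pop_af_exac_eas)),
                        blacklist=bool(_info_get(rec, fm.blacklist, False)),
                    ))
            except (KeyError, TypeError, IndexError) as exc:
                raise VariantParseError(
                    f"{path}: malformed record at {rec.chrom}:{rec.pos}: {exc}"
                ) from exc
    return calls


def _maybe_float(x) -> float | None:
    return None if x is None else float(x)


def _read_tsv(path: Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    missing = [c for c in TSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    calls = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            calls.append(VariantCall(
                chrom=str(row.chrom), pos=int(row.pos), ref=str(row.ref),
                alt=str(row.alt),
                gene="" if pd.isna(row.gene) else str(row.gene),
                effect="" if pd.isna(row.effect) else str(row.effect),
                depth=int(row.depth), alt_reads=int(row.alt_reads),
                vaf=float(row.vaf),
                mean_base_quality=float(row.mean_base_quality),
                alt_fwd=int(row.alt_fwd), alt_rev=int(row.alt_rev),
                pop_af_1kg=None if pd.isna(row.pop_af_1kg) else float(row.pop_af_1kg),
                pop_af_exac_all=None if pd.isna(row.pop_af_exac_all) else float(row.pop_af_exac_all),
                pop_af_exac_eas=None if pd.isna(row.pop_af_exac_eas) else float(row.pop_af_exac_eas),
                blacklist=bool(row.blacklist),
            ))
        except (ValueError, TypeError) as exc:
            raise VariantParseError(f"{path}: line {lineno}: {exc}") from exc
    return calls


def write_variants_tsv(variants: Sequence[VariantCall], path: str | Path) -> None:
    """Write calls as the MAF-like TSV dialect (stable column order)."""
    rows = [{c: getattr(v, c) for c in TSV_COLUMNS} for v in variants]
    df = pd.DataFrame(rows, columns=TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n",
              float_format="%.17g")


_VCF_CONTIG_LENGTH = 250_000_000  # synthetic header length, ample for hg-style contigs


def write_variants_vcf(variants: Sequence[VariantCall], path: str | Path,
                       sample_name: str = "SAMPLE",
                       fields: VcfFieldMap | None = None) -> None:
    """Write calls as an uncompressed single-sample VCF 4.2 file."""
    fm = fields or VcfFieldMap()
    header = pysam.VariantHeader()
    for contig in sorted({v.chrom for v in variants}, key=_contig_sort_key):
        header.contigs.add(contig, length=_VCF_CONTIG_LENGTH)
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.info.add(fm.base_quality, 1, "Float", "Mean base quality of alt reads")
    header.info.add(fm.alt_fwd, "A", "Integer", "Alt reads, forward strand")
    header.info.add(fm.alt_rev, "A", "Integer", "Alt reads, reverse strand")
    header.info.add(fm.pop_af_1kg, 1, "Float", "1000 Genomes allele frequency")
    header.info.add(fm.pop_af_exac_all, 1, "Float", "ExAC ALL allele frequency")
    header.info.add(fm.pop_af_exac_eas, 1, "Float", "ExAC EAS allele frequency")
    header.info.add(fm.blacklist, 0, "Flag", "Recurrent-artifact blacklist site")
    header.info.add(fm.gene, 1, "String", "HUGO symbol")
    header.info.add(fm.effect, 1, "String", "Functional class")
    header.add_sample(sample_name)
    ordered = sorted(variants, key=lambda v: (_contig_sort_key(v.chrom), v.pos,
                                              v.ref, v.alt))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in ordered:
            rec = out.new_record(contig=v.chrom, start=v.pos - 1,
                                 alleles=(v.ref, v.alt))
            rec.samples[sample_name]["DP"] = v.depth
            rec.samples[sample_name]["AD"] = (v.depth - v.alt_reads, v.alt_reads)
            rec.info[fm.base_quality] = v.mean_base_quality
            rec.info[fm.alt_fwd] = (v.alt_fwd,)
            rec.info[fm.alt_rev] = (v.alt_rev,)
            if v.pop_af_1kg is not None:
                rec.info[fm.pop_af_1kg] = v.pop_af_1kg
            if v.pop_af_exac_all is not None:
                rec.info[fm.pop_af_exac_all] = v.pop_af_exac_all
            if v.pop_af_exac_eas is not None:
                rec.info[fm.pop_af_exac_eas] = v.pop_af_exac_eas
            if v.blacklist:
                rec.info[fm.blacklist] = True
            if v.gene:
                rec.info[fm.gene] = v.gene
            if v.effect:
                rec.info[fm.effect] = v.effect
            out.write(rec)


def _contig_sort_key(chrom: str):
    name = chrom.removeprefix("chr")
    return (0, int(name)) if name.isdigit() else (1, name)


def read_seg(path: str | Path) -> pd.DataFrame:
    """Read a SEG table (chrom, start, end, log2[, minor_cn]); 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "log2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    if (df["end"] < df["start"]).any():
        raise DataIntegrityError(f"{path}: segment with end < start")
    df["length_bp"] = df["end"] - df["start"] + 1
    return df


def read_cnv_events(path: str | Path) -> list[CNVEvent]:
    """Read a gene-level CNV table (gene, direction, log2_ratio)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("gene", "direction", "log2_ratio") if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")
    return [CNVEvent(gene=str(r.gene), direction=str(r.direction),
                     log2_ratio=float(r.log2_ratio))
            for r in df.itertuples(index=False)]


def rejected_report(rejected: Sequence[tuple[VariantCall, str]],
                    path: str | Path) -> None:
    """Write rejected variants with their first-failing-rule reason as TSV."""
    rows = []
    for v, reason in rejected:
        row = {c: getattr(v, c) for c in TSV_COLUMNS}
        row["reason"] = reason
        rows.append(row)
    pd.DataFrame(rows, columns=TSV_COLUMNS + ["reason"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n")
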