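"""Cohort-level mutational landscape across Correa stages.

Gene mutation frequencies per stage (a patient counts as mutated in a gene
when it carries at least one kept non-synonymous small variant at that
stage), Fisher-exact stage contrasts, the abnormal-pathway rule (a pathway
is abnormal in a sample when one or more of its genes is mutated), and
hypergeometric over-representation of gene sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats as sps

from . import stats as stats_kit
from .indices import NON_SYNONYMOUS_EFFECTS
from .variant_model import LesionSample, Patient

__all__ = [
    "StageFrequencyTable",
    "GeneSetCollection",
    "mutation_frequency",
    "stage_contrast",
    "pathway_abnormality",
    "overrepresentation",
    "oncogenic_pathways",
    "ContrastResult",
]

ENRICHMENT_ALPHA = 0.01


@dataclass
class GeneSetCollection:
    """Named gene sets with an optional background universe."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] | None = None

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            if self.universe is not None and not genes <= self.universe:
                raise ValueError(f"gene set {name!r} not within the universe")

    @classmethod
    def from_gmt(cls, path: str | Path,
                 universe: Iterable[str] | None = None) -> "GeneSetCollection":
        sets: dict[str, frozenset[str]] = {}
        for line in Path(path).read_text().splitlines():
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: GMT line needs name, desc, >=1 gene")
            sets[parts[0]] = frozenset(g for g in parts[2:] if g)
        return cls(sets=sets,
                   universe=frozenset(universe) if universe is not None else None)

    def to_gmt(self, path: str | Path) -> None:
        lines = [
            "\t".join([name, "na", *sorted(genes)])
            for name, genes in sorted(self.sets.items())
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    def all_genes(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for genes in self.sets.values():
            out |= genes
        return out


def oncogenic_pathways() -> GeneSetCollection:
    """The bundled ten canonical oncogenic-pathway gene sets (editable GMT)."""
    gmt = resources.files("correaevo.data").joinpath("oncogenic_pathways.gmt")
    with resources.as_file(gmt) as path:
        return GeneSetCollection.from_gmt(path)


@dataclass
class StageFrequencyTable:
    """Gene x stage counts of mutated patients with per-stage cohort sizes."""

    genes: list[str]
    stages: list[str]
    counts: pd.DataFrame  # index genes, columns stages
    n_patients: dict[str, int]

    def __post_init__(self) -> None:
        for stage in self.stages:
            n = self.n_patients[stage]
            col = self.counts[stage]
            if ((col < 0) | (col > n)).any():
                raise ValueError(f"count outside [0, {n}] in stage {stage}")

    def frequency(self, gene: str, stage: str) -> float:
        return self.counts.loc[gene, stage] / self.n_patients[stage]


def build_frequency_table(cohort: Sequence[Patient],
                          stages: Sequence[str] = ("IM", "LGIN", "HGIN", "EGC"),
                          effects: frozenset[str] = NON_SYNONYMOUS_EFFECTS,
                          ) -> StageFrequencyTable:
    """Count, per gene and stage, the patients carrying >=1 qualifying variant."""
    counts: dict[str, dict[str, int]] = {}
    n_patients = {s: 0 for s in stages}
    for patient in cohort:
        for stage in stages:
            if stage not in patient.samples:
                continue
            n_patients[stage] += 1
            for gene in patient.samples[stage].mutated_genes(effects):
                counts.setdefault(gene, {s: 0 for s in stages})[stage] += 1
    genes = sorted(counts)
    df = pd.DataFrame(
        [[counts[g][s] for s in stages] for g in genes],
        index=pd.Index(genes, name="gene"), columns=list(stages), dtype=int)
    return StageFrequencyTable(genes=genes, stages=list(stages), counts=df,
                               n_patients=n_patients)


def mutation_frequency(cohort: Sequence[Patient], stage: str,
                       top_n: int = 25,
                       effects: frozenset[str] = NON_SYNONYMOUS_EFFECTS,
                       ) -> pd.DataFrame:
    """Top-n recurrently mutated genes at one stage.

    Returns a DataFrame (gene, count, n_patients, frequency), sorted by
    descending frequency with alphabetical tie-break; genes mutated in no
    patient are excluded.
    """
    table = build_frequency_table(cohort, stages=(stage,), effects=effects)
    n = table.n_patients[stage]
    if n == 0:
        warnings.warn(f"no patient has a sample at stage {stage}",
                      stacklevel=2)
        return pd.DataFrame(columns=["gene", "count", "n_patients", "frequency"])
    df = table.counts[table.counts[stage] > 0].copy()
    df = df.rename(columns={stage: "count"}).reset_index()
    df["n_patients"] = n
    df["frequency"] = df["count"] / n
    df = df.sort_values(["frequency", "gene"], ascending=[False, True],
                        kind="mergesort").head(top_n).reset_index(drop=True)
    return df[["gene", "count", "n_patients", "frequency"]]


@dataclass
class ContrastResult:
    gene: str
    stage_a: str
    stage_b: str
    table: list[list[int]]
    p: float


def stage_contrast(table: StageFrequencyTable, gene: str,
                   stage_a: str, stage_b: str) -> ContrastResult:
    """Two-sided Fisher contrast of a gene's mutated-patient counts."""
    n_a, n_b = table.n_patients[stage_a], table.n_patients[stage_b]
    if n_a == 0 or n_b == 0:
        raise ValueError("both stages need at least one patient")
    mut_a = int(table.counts.loc[gene, stage_a]) if gene in table.counts.index else 0
    mut_b = int(table.counts.loc[gene, stage_b]) if gene in table.counts.index else 0
    two_by_two = [[mut_a, n_a - mut_a], [mut_b, n_b - mut_b]]
    return ContrastResult(gene=gene, stage_a=stage_a, stage_b=stage_b,
                          table=two_by_two,
                          p=stats_kit.fisher_exact(two_by_two))


def pathway_abnormality(sample: LesionSample,
                        pathways: GeneSetCollection,
                        effects: frozenset[str] = NON_SYNONYMOUS_EFFECTS,
                        ) -> dict[str, bool]:
    """A pathway is abnormal when the sample mutates one or more of its genes."""
    mutated = sample.mutated_genes(effects)
    return {name: bool(genes & mutated)
            for name, genes in pathways.sets.items()}


def overrepresentation(mutated_genes: Iterable[str],
                       pathways: GeneSetCollection,
                       alpha: float = ENRICHMENT_ALPHA,
                       adjust: bool = False) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    With universe size N, set size K, query size n and overlap k, the
    p-value is P(X >= k) for X ~ Hypergeom(N, K, n). Rows with p below
    ``alpha`` are flagged enriched; an optional Benjamini-Hochberg column
    can be added but the flag uses the unadjusted p.
    """
    universe = pathways.universe or pathways.all_genes()
    query = set(mutated_genes)
    dropped = query - universe
    if dropped:
        warnings.warn(
            f"{len(dropped)} query gene(s) outside the universe dropped",
            stacklevel=2)
        query &= universe
    N, n = len(universe), len(query)
    rows = []
    for name, genes in sorted(pathways.sets.items()):
        K = len(genes)
        k = len(genes & query)
        p = 1.0 if k == 0 else float(sps.hypergeom.sf(k - 1, N, K, n))
        rows.append({"pathway": name, "overlap": k, "set_size": K,
                     "query_size": n, "universe_size": N, "p": p,
                     "enriched": p < alpha})
    df = pd.DataFrame(rows)
    if adjust and len(df):
        from statsmodels.stats.multitest import multipletests
        df["p_bh"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    return df
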