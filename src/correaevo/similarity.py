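"""Genomic similarity between Correa stages and evolutionary-trajectory calls.

The central quantities of the analysis:

* the Jaccard similarity coefficient |A ∩ B| / |A ∪ B| between two lesions'
  variant-key sets (identically, the "concordance ratio" when expressed as
  a percentage against the EGC lesion);
* the genetic distance |A Δ B|, the count of variants private to one of
  the two lesions;
* the CT1/CT2/CT3 concordance tiers (how many precursor stages reach >=20%
  concordance with EGC);
* the per-patient trajectory call — linear, punctuated, or independent
  evolution — from the (LGIN, HGIN) x EGC Jaccard triple;
* hierarchical clustering of patients by their concordance profiles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .variant_model import Patient

__all__ = [
    "SimilarityResult",
    "TrajectoryCall",
    "ConcordanceTier",
    "jaccard",
    "genetic_distance",
    "concordance_with_egc",
    "assign_tier",
    "classify_trajectory",
    "patient_similarity",
    "cluster_cases",
    "linkage_to_newick",
]

PRECURSOR_STAGES = ("IM", "LGIN", "HGIN")

#: Default Jaccard floor below which similarity to EGC counts as "limited"
#: when calling independent evolution. Exposed in configuration.
DEFAULT_INDEPENDENT_FLOOR = 0.15

#: Default concordance percentage at or above which a precursor stage
#: counts as "similar" to EGC for tier assignment.
DEFAULT_TIER_THRESHOLD = 20.0


def jaccard(a: frozenset | set, b: frozenset | set) -> float:
    """|a ∩ b| / |a ∪ b|; 0 (with a warning) when both sets are empty."""
    union = len(a | b)
    if union == 0:
        warnings.warn("Jaccard of two empty sets; returning 0", stacklevel=2)
        return 0.0
    return len(a & b) / union


def genetic_distance(a: frozenset | set, b: frozenset | set) -> int:
    """Number of variants present in exactly one of the two sets."""
    return len(a ^ b)


def concordance_with_egc(stage_set: frozenset | set,
                         egc_set: frozenset | set) -> tuple[int, int, float]:
    """Shared count, union count, and percentage shared with EGC (2 dp).

    The percentage is the share of the variant union (shared plus
    discordant) common to the precursor lesion and EGC.
    """
    shared = len(stage_set & egc_set)
    union = len(stage_set | egc_set)
    if union == 0:
        warnings.warn("empty union: concordance undefined", stacklevel=2)
        return 0, 0, float("nan")
    return shared, union, round(100.0 * shared / union, 2)


@dataclass
class ConcordanceTier:
    patient_id: str
    tier: str  # CT1 | CT2 | CT3
    n_similar_stages: int
    threshold: float


def assign_tier(concordances: Mapping[str, float],
                threshold: float = DEFAULT_TIER_THRESHOLD,
                patient_id: str = "") -> ConcordanceTier:
    """CT tier from the three precursor-stage concordance percentages.

    CT1 (highly similar): two or more stages at or above the threshold;
    CT2: exactly one; CT3: none. A concordance exactly at the threshold
    counts as similar (the rule is ">= 20%").
    """
    missing = [s for s in PRECURSOR_STAGES if s not in concordances]
    if missing:
        raise ValueError(f"missing concordance for stage(s): {missing}")
    n_similar = sum(concordances[s] >= threshold for s in PRECURSOR_STAGES)
    tier = "CT1" if n_similar >= 2 else ("CT2" if n_similar == 1 else "CT3")
    return ConcordanceTier(patient_id=patient_id, tier=tier,
                           n_similar_stages=n_similar, threshold=threshold)


@dataclass
class TrajectoryCall:
    patient_id: str
    model: str  # linear | punctuated | independent
    triple: tuple[float, float, float]  # (J_LE, J_HE, J_LH)
    egc_similarity_floor: float


def classify_trajectory(j_le: float, j_he: float, j_lh: float,
                        floor: float = DEFAULT_INDEPENDENT_FLOOR,
                        patient_id: str = "") -> TrajectoryCall:
    """Evolutionary-model call from the LGIN/HGIN/EGC Jaccard triple.

    * independent — LGIN and HGIN resemble each other more than either
      resembles EGC, and both EGC similarities stay below ``floor``
      (EGC arose from a lineage separate from both precursors);
    * linear — otherwise, when HGIN is at least as similar to EGC as LGIN
      (stepwise LGIN -> HGIN -> EGC progression; ties resolve here);
    * punctuated — EGC more similar to LGIN than to HGIN (EGC seeded
      directly from the LGIN clone).
    """
    for name, v in (("J_LE", j_le), ("J_HE", j_he), ("J_LH", j_lh)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name}={v} outside [0,1]")
    egc_max = max(j_le, j_he)
    if j_lh > egc_max and egc_max < floor:
        model = "independent"
    elif j_he >= j_le:
        model = "linear"
    else:
        model = "punctuated"
    return TrajectoryCall(patient_id=patient_id, model=model,
                          triple=(j_le, j_he, j_lh),
                          egc_similarity_floor=floor)


@dataclass
class SimilarityResult:
    """All pairwise similarity statistics for one patient at one level."""

    patient_id: str
    level: str  # mutation | cnv
    pairwise_jaccard: dict[tuple[str, str], float] = field(default_factory=dict)
    concordance_with_egc: dict[str, float] = field(default_factory=dict)
    genetic_distance: dict[tuple[str, str], int] = field(default_factory=dict)
    shared_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def triple(self) -> tuple[float, float, float]:
        """(J_LE, J_HE, J_LH) for trajectory classification."""
        return (self.pairwise_jaccard[("LGIN", "EGC")],
                self.pairwise_jaccard[("HGIN", "EGC")],
                self.pairwise_jaccard[("LGIN", "HGIN")])


def patient_similarity(patient: Patient, level: str = "mutation",
                       subtract_normal: bool = True) -> SimilarityResult:
    """Pairwise Jaccard/distance and EGC concordance for one patient.

    At the mutation level, the NM control sample's variant keys are
    subtracted from every lesion set by default (NM is the germline /
    artifact background). CNV events are compared on (gene, direction).
    """
    if level not in ("mutation", "cnv"):
        raise ValueError(f"level must be mutation|cnv, got {level!r}")
    stages = [s for s in ("IM", "LGIN", "HGIN", "EGC") if s in patient.samples]
    sets: dict[str, frozenset] = {}
    for s in stages:
        if level == "mutation":
            sets[s] = patient.stage_keys(s, subtract_normal=subtract_normal)
        else:
            sets[s] = patient.samples[s].cnv_keys()
    result = SimilarityResult(patient_id=patient.patient_id, level=level)
    for i, a in enumerate(stages):
        for b in stages[i + 1:]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                j = jaccard(sets[a], sets[b])
            result.pairwise_jaccard[(a, b)] = j
            result.pairwise_jaccard[(b, a)] = j
            d = genetic_distance(sets[a], sets[b])
            result.genetic_distance[(a, b)] = d
            result.genetic_distance[(b, a)] = d
    if "EGC" in sets:
        for s in stages:
            if s == "EGC":
                continue
            shared, union, pct = concordance_with_egc(sets[s], sets["EGC"])
            result.shared_counts[s] = (shared, union)
            result.concordance_with_egc[s] = pct
    return result


@dataclass
class ClusterResult:
    linkage: np.ndarray
    leaf_order: list[Hashable]
    flat_clusters: dict[Hashable, int]


def cluster_cases(concordance_matrix: pd.DataFrame,
                  n_clusters: int = 3) -> ClusterResult:
    """Agglomerative clustering of patients by concordance profiles.

    Average linkage on Euclidean distances between each patient's vector
    of per-stage concordance percentages; deterministic leaf order for a
    fixed input row order.
    """
    if concordance_matrix.isna().any().any():
        bad = concordance_matrix.index[
            concordance_matrix.isna().any(axis=1)].tolist()
        raise ValueError(f"NaN concordance cells for patients: {bad}")
    values = concordance_matrix.to_numpy(dtype=float)
    if len(values) < 2:
        raise ValueError("need at least two patients to cluster")
    link = hierarchy.linkage(pdist(values, metric="euclidean"),
                             method="average")
    order = hierarchy.leaves_list(link)
    labels = hierarchy.fcluster(link, t=min(n_clusters, len(values)),
                                criterion="maxclust")
    ids = list(concordance_matrix.index)
    return ClusterResult(
        linkage=link,
        leaf_order=[ids[i] for i in order],
        flat_clusters={pid: int(lab) for pid, lab in zip(ids, labels)},
    )


def linkage_to_newick(link: np.ndarray, leaf_names: Sequence[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return render(tree, tree.dist) + ";"
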