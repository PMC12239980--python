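"""Rule-based IHC marker scoring and progression-risk evaluation.

Implements the immunohistochemistry scoring rubrics for TP53 (wild-type
vs mutant-type staining pattern), PRKDC (percent-positive score plus
intensity score, positive when the sum exceeds 3), and the mismatch-repair
panel (dMMR when any of MLH1/PMS2/MSH2/MSH6 lacks expression), and
evaluates marker rules as predictors of LGIN progression to HGIN/EGC
(sensitivity, specificity, Fisher contrast).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import stats as stats_kit

__all__ = [
    "IHCReading",
    "MarkerRecord",
    "MarkerEvaluation",
    "score_tp53",
    "score_prkdc",
    "score_mmr",
    "evaluate_marker",
    "read_marker_records",
    "InsufficientDataError",
]

MMR_PROTEINS = ("MLH1", "PMS2", "MSH2", "MSH6")
TP53_PATTERNS = ("scattered_weak_moderate", "diffuse_strong", "absent")
PRKDC_INTENSITIES = ("none", "light_yellow", "brown_yellow")


class InsufficientDataError(ValueError):
    """Raised when an evaluation has no records in a required outcome class."""


@dataclass(frozen=True)
class IHCReading:
    """One marker reading; only the fields relevant to the marker are used."""

    marker: str
    percent_positive: float | None = None
    intensity: str | None = None     # PRKDC: none | light_yellow | brown_yellow
    pattern: str | None = None       # TP53: scattered_weak_moderate | diffuse_strong | absent
    expressed: bool | None = None    # MMR proteins

    def __post_init__(self) -> None:
        if self.percent_positive is not None and not (
                0.0 <= self.percent_positive <= 1.0):
            raise ValueError(
                f"percent_positive {self.percent_positive} outside [0,1]")


def score_tp53(reading: IHCReading) -> str:
    """TP53 status: MT for >50% diffuse strong nuclei (missense pattern) or
    complete absence of expression (nonsense pattern); WT otherwise."""
    if reading.pattern is None:
        raise ValueError("TP53 reading lacks a staining pattern")
    if reading.pattern not in TP53_PATTERNS:
        raise ValueError(f"unknown TP53 pattern {reading.pattern!r}")
    if reading.pattern == "absent":
        return "MT"
    if reading.pattern == "diffuse_strong":
        if reading.percent_positive is None:
            raise ValueError("TP53 diffuse-strong reading lacks percent_positive")
        return "MT" if reading.percent_positive > 0.5 else "WT"
    return "WT"


def _prkdc_percent_score(fraction: float) -> int:
    # bins lower-inclusive at 5% and 25%: <5 -> 0, 5-25 -> 1, 25-50 -> 2, >=50 -> 3
    if fraction < 0.05:
        return 0
    if fraction < 0.25:
        return 1
    if fraction < 0.50:
        return 2
    return 3


def score_prkdc(reading: IHCReading) -> tuple[str, tuple[int, int]]:
    """PRKDC status with its (percent_score, intensity_score) pair.

    Percent-positive bins score 0/1/2/3 at <5%, 5-25%, 25-50%, >=50%;
    intensity scores 0/1/2 for no color, light yellow, brown-yellow.
    Negative when the sum is <= 3, positive otherwise.
    """
    if reading.percent_positive is None:
        raise ValueError("PRKDC reading lacks percent_positive")
    if reading.intensity not in PRKDC_INTENSITIES:
        raise ValueError(f"unknown PRKDC intensity {reading.intensity!r}")
    p_score = _prkdc_percent_score(reading.percent_positive)
    i_score = PRKDC_INTENSITIES.index(reading.intensity)
    status = "positive" if p_score + i_score > 3 else "negative"
    return status, (p_score, i_score)


def score_mmr(readings: Sequence[IHCReading]) -> str:
    """dMMR when at least one of MLH1/PMS2/MSH2/MSH6 lacks expression."""
    by_marker = {r.marker: r for r in readings}
    missing = [m for m in MMR_PROTEINS if m not in by_marker]
    if missing:
        raise ValueError(f"incomplete MMR panel; missing {missing}")
    for m in MMR_PROTEINS:
        if by_marker[m].expressed is None:
            raise ValueError(f"{m} reading lacks an expression call")
    return "dMMR" if any(not by_marker[m].expressed for m in MMR_PROTEINS) \
        else "pMMR"


@dataclass(frozen=True)
class MarkerRecord:
    """One validation-cohort patient's marker statuses and outcome."""

    patient_id: str
    tp53_status: str    # WT | MT
    prkdc_status: str   # positive | negative
    pclo_status: str    # positive | negative
    outcome: str        # progressed | stable

    def __post_init__(self) -> None:
        if self.outcome not in ("progressed", "stable"):
            raise ValueError(f"outcome must be progressed|stable, "
                             f"got {self.outcome!r}")

    def marker_positive(self, marker: str) -> bool:
        if marker == "TP53":
            return self.tp53_status == "MT"
        if marker == "PRKDC":
            return self.prkdc_status == "positive"
        if marker == "PCLO":
            return self.pclo_status == "positive"
        raise ValueError(f"unknown marker {marker!r}")


@dataclass
class MarkerEvaluation:
    rule: str
    sensitivity: float
    specificity: float
    table: list[list[int]]  # [[pos|progressed, neg|progressed], [pos|stable, neg|stable]]
    fisher_p: float


def evaluate_marker(records: Sequence[MarkerRecord],
                    rule: str) -> MarkerEvaluation:
    """Evaluate a marker rule (e.g. ``"TP53"`` or ``"TP53 or PRKDC"``) as a
    progression predictor.

    Sensitivity is the marker-positive share of progressed patients;
    specificity the marker-negative share of stable patients. An "or" rule
    is positive when any component marker is positive.
    """
    markers = [m.strip() for m in rule.split(" or ")]
    progressed = [r for r in records if r.outcome == "progressed"]
    stable = [r for r in records if r.outcome == "stable"]
    if not progressed or not stable:
        raise InsufficientDataError(
            "need at least one progressed and one stable record; "
            f"got {len(progressed)} progressed, {len(stable)} stable")

    def positive(r: MarkerRecord) -> bool:
        return any(r.marker_positive(m) for m in markers)

    tp = sum(positive(r) for r in progressed)
    fp = sum(positive(r) for r in stable)
    table = [[tp, len(progressed) - tp], [fp, len(stable) - fp]]
    return MarkerEvaluation(
        rule=rule,
        sensitivity=tp / len(progressed),
        specificity=(len(stable) - fp) / len(stable),
        table=table,
        fisher_p=stats_kit.fisher_exact(table),
    )


def read_marker_records(path: str | Path) -> list[MarkerRecord]:
    """Read the validation-cohort TSV (patient_id, tp53, prkdc, pclo, outcome)."""
    df = pd.read_csv(path, sep="\t")
    required = ["patient_id", "tp53", "prkdc", "pclo", "outcome"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [MarkerRecord(patient_id=str(r.patient_id), tp53_status=str(r.tp53),
                         prkdc_status=str(r.prkdc), pclo_status=str(r.pclo),
                         outcome=str(r.outcome))
            for r in df.itertuples(index=False)]


def write_marker_records(records: Sequence[MarkerRecord],
                         path: str | Path) -> None:
    pd.DataFrame(
        [{"patient_id": r.patient_id, "tp53": r.tp53_status,
          "prkdc": r.prkdc_status, "pclo": r.pclo_status,
          "outcome": r.outcome} for r in records],
        columns=["patient_id", "tp53", "prkdc", "pclo", "outcome"],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")
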