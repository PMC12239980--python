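"""Per-sample genomic instability indices.

Four standard indices summarise genomic instability per lesion, using
explicit textbook definitions (each is configuration-switchable and the
report names the definition used):

* TMB — non-synonymous mutations per megabase of callable territory;
* CIS — fraction of the assessed genome length lying in copy-altered
  segments (|log2 ratio| at or above a cutoff, default 0.2);
* LOH fraction — fraction of assessed genome length with minor copy
  number zero;
* ITH — the MATH score, ``100 * 1.4826 * MAD(VAF) / median(VAF)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .variant_model import LesionSample

__all__ = ["IndexPanel", "NON_SYNONYMOUS_EFFECTS", "tmb", "cis",
           "loh_fraction", "ith_math", "index_panel"]

#: Functional classes counted as non-synonymous (oncoplot convention).
NON_SYNONYMOUS_EFFECTS = frozenset(
    {"missense", "nonsense", "frameshift", "splice_site", "inframe_indel"})


@dataclass(frozen=True)
class IndexPanel:
    tmb: float
    cis: float
    loh_fraction: float
    ith: float | None  # None when fewer than 3 usable VAFs

    def __post_init__(self) -> None:
        for name in ("tmb", "cis", "loh_fraction"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be finite and >= 0")
        if not (self.cis <= 1.0 and self.loh_fraction <= 1.0):
            raise ValueError("cis and loh_fraction must be <= 1")


def tmb(sample: LesionSample, callable_mb: float,
        effects: frozenset[str] = NON_SYNONYMOUS_EFFECTS) -> float:
    """Non-synonymous mutation count per megabase of callable territory."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be > 0")
    count = sum(1 for v in sample.variants if v.effect in effects)
    return count / callable_mb


def cis(segments: Sequence[tuple[float, float]], cutoff: float = 0.2) -> float:
    """Length fraction of segments whose |log2 ratio| >= cutoff."""
    lengths = np.array([s[0] for s in segments], dtype=float)
    log2 = np.array([s[1] for s in segments], dtype=float)
    if (lengths < 0).any():
        raise ValueError("negative segment length")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total segment length must be > 0")
    return float(lengths[np.abs(log2) >= cutoff].sum() / total)


def loh_fraction(segments: Sequence[tuple[float, int]]) -> float:
    """Length fraction of segments with minor copy number zero."""
    lengths = np.array([s[0] for s in segments], dtype=float)
    minor = np.array([s[1] for s in segments])
    if (lengths < 0).any():
        raise ValueError("negative segment length")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("total segment length must be > 0")
    return float(lengths[minor == 0].sum() / total)


def ith_math(vafs: Sequence[float]) -> float | None:
    """MATH score: 100 * 1.4826 * median(|v - median|) / median.

    Returns None (insufficient data) for fewer than three positive VAFs.
    """
    v = np.asarray([x for x in vafs if x > 0], dtype=float)
    if len(v) < 3:
        return None
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    return float(100.0 * 1.4826 * mad / med)


def index_panel(sample: LesionSample, callable_mb: float,
                cnv_segments: Sequence[tuple[float, float]],
                loh_segments: Sequence[tuple[float, int]],
                cis_cutoff: float = 0.2) -> IndexPanel:
    """Assemble all four indices for one lesion sample."""
    return IndexPanel(
        tmb=tmb(sample, callable_mb),
        cis=cis(cnv_segments, cutoff=cis_cutoff),
        loh_fraction=loh_fraction(loh_segments),
        ith=ith_math([v.vaf for v in sample.variants]),
    )
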