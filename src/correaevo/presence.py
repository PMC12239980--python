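"""Bayesian presence posterior for a variant in a lesion.

When comparing lesion genomes from the same patient, a variant that passed
the hard calling filters in one stage may sit just below threshold in
another, which would artificially depress the apparent sharing between
stages. This module scores, from the raw read evidence alone, the
posterior probability that a variant is truly present in a lesion.

The model compares two hypotheses for the ``a`` alt-supporting reads among
``d`` total reads at a site:

* absent:  reads arise from sequencing error, ``a ~ Binomial(d, eps)``;
* present: the true variant fraction ``f`` is unknown with a uniform prior
  on ``[f_lo, f_hi]``, so the marginal likelihood is the average of
  ``Binomial(a; d, f)`` over that prior.

With prior probability ``pi`` of presence, the posterior is
``pi * L1 / (pi * L1 + (1 - pi) * L0)``. The prior average is evaluated by
composite Simpson quadrature on a fixed ``f``-grid, accurate far beyond
the per-cell noise in real data.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .variant_model import DataIntegrityError, Patient

__all__ = ["PresenceModelConfig", "presence_probability", "presence_matrix"]


@dataclass(frozen=True)
class PresenceModelConfig:
    """Parameters of the two-hypothesis binomial presence model.

    Defaults: a symmetric ``pi = 0.5`` presence prior, ``eps = 0.005``
    per-base error (typical for FFPE libraries after deduplication), and a
    Uniform(0.05, 0.5) prior on the true variant fraction — the range a
    clonal heterozygous variant spans under partial tumor purity.
    """

    prior_present: float = 0.5
    error_rate: float = 0.005
    vaf_prior_low: float = 0.05
    vaf_prior_high: float = 0.5
    grid_points: int = 200

    def __post_init__(self) -> None:
        if not (0.0 < self.prior_present < 1.0):
            raise ValueError("prior_present must be in (0,1)")
        if not (0.0 < self.error_rate <= 0.05):
            raise ValueError("error_rate must be in (0, 0.05]")
        if not (0.0 < self.vaf_prior_low < self.vaf_prior_high <= 1.0):
            raise ValueError("require 0 < vaf_prior_low < vaf_prior_high <= 1")
        if self.grid_points < 10:
            raise ValueError("grid_points must be >= 10")


@lru_cache(maxsize=8)
def _leggauss(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.polynomial.legendre.leggauss(n)


def presence_probability(depth: int, alt_reads: int,
                         config: PresenceModelConfig | None = None) -> float:
    """Posterior probability that a variant is present given read evidence."""
    cfg = config or PresenceModelConfig()
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if alt_reads < 0 or alt_reads > depth:
        raise DataIntegrityError(
            f"alt_reads={alt_reads} outside [0, depth={depth}]")
    # log-scale likelihoods keep high-depth cells finite
    log_l0 = sps.binom.logpmf(alt_reads, depth, cfg.error_rate)
    # Gauss-Legendre prior average: the integrand is a degree-``depth``
    # polynomial in f, so grid_points nodes integrate it exactly up to
    # depth = 2*grid_points - 1 and near-exactly beyond
    nodes, weights = _leggauss(cfg.grid_points)
    lo, hi = cfg.vaf_prior_low, cfg.vaf_prior_high
    grid = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
    log_pmf = sps.binom.logpmf(alt_reads, depth, grid)
    shift = log_pmf.max()
    mean_pmf = float((weights * np.exp(log_pmf - shift)).sum()) / 2.0
    if mean_pmf <= 0.0:
        log_l1 = -np.inf
    else:
        log_l1 = shift + np.log(mean_pmf)
    # posterior odds in log space
    log_prior_odds = np.log(cfg.prior_present) - np.log(1.0 - cfg.prior_present)
    log_odds = log_prior_odds + log_l1 - log_l0
    return float(1.0 / (1.0 + np.exp(-log_odds)))


def presence_matrix(
    patient: Patient,
    union_variants: list[tuple[str, int, str, str]],
    config: PresenceModelConfig | None = None,
    pileup: Mapping[tuple[str, tuple[str, int, str, str]], tuple[int, int]] | None = None,
    stages: list[str] | None = None,
) -> pd.DataFrame:
    """Variant x stage table of presence probabilities for one patient.

    Evidence per cell comes from the stage's called variant when present;
    otherwise from ``pileup`` — a lookup ``(stage, variant_key) ->
    (depth, alt_reads)`` giving the site coverage in stages where the
    variant was not called. Cells with no evidence from either source are
    left as NaN (flagged missing, never imputed).
    """
    cfg = config or PresenceModelConfig()
    if stages is None:
        stages = [s for s in ("IM", "LGIN", "HGIN", "EGC")
                  if s in patient.samples]
    index = pd.Index(["{}:{}:{}:{}".format(*k) for k in union_variants],
                     name="variant")
    out = pd.DataFrame(np.nan, index=index, columns=stages)
    for stage in stages:
        sample = patient.samples[stage]
        by_key = {v.key: v for v in sample.variants}
        for key, row in zip(union_variants, out.index):
            if key in by_key:
                v = by_key[key]
                evidence = (v.depth, v.alt_reads)
            elif pileup is not None and (stage, key) in pileup:
                evidence = pileup[(stage, key)]
            else:
                continue  # missing cell stays NaN
            depth, alt = evidence
            if depth >= 1:
                out.loc[row, stage] = presence_probability(depth, alt, cfg)
    return out


def presence_calls(matrix: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Binary presence calls from a posterior matrix; NaN cells stay NaN."""
    return matrix.where(matrix.isna(), (matrix >= threshold).astype(float))
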