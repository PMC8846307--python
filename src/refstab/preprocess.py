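"""Cq transformations: relative quantities, descriptives, efficiencies.

The stability algorithms that operate on expression levels (geNorm,
NormFinder) take *relative quantities* q = E^(minCq - Cq), the
expression of each sample relative to the most-expressed sample of that
gene; q lies in (0, 1] with the per-gene maximum exactly 1.  E is the
per-cycle amplification factor, 2 for perfect doubling.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import CqMatrix

__all__ = [
    "RQMatrix",
    "relative_quantities",
    "efficiency_from_slope",
    "descriptive_stats",
    "expression_tiers",
]

DEFAULT_EFFICIENCY = 2.0

#: mean-Cq boundaries (cycles) separating abundant / moderate / scarce
#: transcripts; chosen inside the empty gaps of the observed clusters.
TIER_HIGH_BELOW = 20.0
TIER_LOW_FROM = 23.5


@dataclasses.dataclass(frozen=True)
class RQMatrix:
    """Relative quantities on the same axes as the source CqMatrix."""

    data: pd.DataFrame
    groups: pd.Series
    efficiency_of: Mapping[str, float]

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    def log(self, base: float = 2.0) -> pd.DataFrame:
        """log-scale expression; equals (minCq - Cq)·log_base(E) exactly."""
        return np.log(self.data) / np.log(base)


def relative_quantities(
    cq: CqMatrix,
    efficiencies: Mapping[str, float] | None = None,
    default_efficiency: float = DEFAULT_EFFICIENCY,
) -> RQMatrix:
    """Transform Cq to relative quantities q_ij = E_j^(min_i Cq_ij - Cq_ij).

    Each gene's column is scaled to its own most-expressed (lowest-Cq)
    sample, so the per-gene maximum is exactly 1.  The default E = 2
    assumes perfect doubling for every assay; per-gene efficiencies may
    be supplied as amplification bases (e.g. 1.93 for 93%).
    """
    eff = {}
    for gene in cq.gene_ids:
        e = float((efficiencies or {}).get(gene, default_efficiency))
        if e <= 1.0:
            raise ValueError(f"amplification base for {gene!r} must exceed 1, got {e}")
        eff[gene] = e
    bases = pd.Series(eff)[cq.data.columns]
    q = bases.to_numpy() ** (cq.data.min(axis=0) - cq.data)
    return RQMatrix(q, cq.groups, eff)


def efficiency_from_slope(slope: float) -> float:
    """Percent amplification efficiency from a standard-curve slope.

    The slope is in cycles per log10 dilution step and must be negative;
    returns (10^(-1/slope) - 1) * 100, i.e. 100% for a slope of
    -1/log10(2) ≈ -3.3219.
    """
    if not slope < 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return (10.0 ** (-1.0 / slope) - 1.0) * 100.0


def descriptive_stats(cq: CqMatrix, samples: Iterable | None = None) -> pd.DataFrame:
    """Per-gene arithmetic descriptives of raw Cq over a sample subset.

    Returns mean, min, q25, median, q75, max, sd (n-1) and cv_pct
    (100*sd/mean) with genes as rows.
    """
    df = cq.data if samples is None else cq.data.loc[list(samples)]
    if df.empty:
        raise ValueError("empty sample subset")
    sd = df.std(axis=0, ddof=1).fillna(0.0)
    out = pd.DataFrame(
        {
            "mean": df.mean(axis=0),
            "min": df.min(axis=0),
            "q25": df.quantile(0.25, axis=0),
            "median": df.median(axis=0),
            "q75": df.quantile(0.75, axis=0),
            "max": df.max(axis=0),
            "sd": sd,
            "cv_pct": 100.0 * sd / df.mean(axis=0),
        }
    )
    out.index.name = "gene"
    return out


def expression_tiers(mean_cq: Mapping[str, float]) -> dict[str, str]:
    """Classify genes by mean Cq into high / intermediate / low expression.

    Lower Cq means higher abundance: high below 20 cycles, intermediate
    in [20, 23.5), low from 23.5 up.
    """
    tiers = {}
    for gene, m in mean_cq.items():
        if m < TIER_HIGH_BELOW:
            tiers[gene] = "high"
        elif m < TIER_LOW_FROM:
            tiers[gene] = "intermediate"
        else:
            tiers[gene] = "low"
    return tiers
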