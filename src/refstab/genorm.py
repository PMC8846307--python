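"""geNorm expression-stability analysis.

A gene's M value is the mean standard deviation of its pairwise log2
expression ratios with every other candidate: two genes that are both
good normalizers keep a constant expression ratio across samples, so
stable genes have low M.  Stepwise exclusion of the highest-M gene
yields a ranking and, at each step, the average M of the remaining set
(the familiar geNorm stability curve).  The pairwise variation
V(n, n+1) between normalization factors built from the n and n+1
best-ranked genes decides how many reference genes are enough; below a
0.15 threshold the extra gene adds nothing.

With E = 2, log2(q_A/q_B) = Cq_B - Cq_A + constant, so every statistic
here is equivalently a statistic of raw Cq differences.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .preprocess import RQMatrix

__all__ = [
    "GeNormResult",
    "PairwiseVariationSeries",
    "pairwise_variability",
    "m_values",
    "genorm_ranking",
    "normalization_factor",
    "pairwise_variation_series",
    "V_THRESHOLD",
]

V_THRESHOLD = 0.15


def _log_expr(rq: RQMatrix, samples: Iterable | None = None) -> pd.DataFrame:
    x = rq.log(2.0)
    if samples is not None:
        x = x.loc[list(samples)]
    return x


def pairwise_variability(
    rq: RQMatrix,
    gene_a: str,
    gene_b: str,
    samples: Iterable | None = None,
) -> float:
    """SD (n-1 denominator) over samples of log2(q_A / q_B)."""
    if gene_a == gene_b:
        raise ValueError("pairwise variability needs two distinct genes")
    x = _log_expr(rq, samples)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    return float((x[gene_a] - x[gene_b]).std(ddof=1))


def m_values(
    rq: RQMatrix,
    genes: Sequence[str] | None = None,
    samples: Iterable | None = None,
) -> pd.Series:
    """Per-gene M: mean pairwise log-ratio SD against all other genes."""
    x = _log_expr(rq, samples)
    genes = list(genes) if genes is not None else list(x.columns)
    if len(genes) < 2:
        raise ValueError("M values need at least 2 genes")
    x = x[genes].to_numpy()
    # SD matrix of all column differences; vectorised over pairs
    k = x.shape[1]
    diffs = x[:, :, None] - x[:, None, :]
    sds = diffs.std(axis=0, ddof=1)
    m = (sds.sum(axis=1)) / (k - 1)
    return pd.Series(m, index=genes, name="M")


@dataclasses.dataclass(frozen=True)
class GeNormResult:
    """Outcome of stepwise geNorm exclusion.

    ``exclusion_order`` lists genes from least stable (first excluded) to
    the terminal pair.  ``m_of`` holds, per gene, the average M of the
    gene set still in play at that gene's exclusion step — the value the
    geNorm stability curve plots, strictly decreasing towards the best
    pair, which shares the terminal value.  ``own_m_of`` keeps each
    excluded gene's own M at that step.  ``ranking`` is best-to-worst
    with the terminal pair (tied) first, in input column order.
    """

    exclusion_order: tuple
    m_of: dict
    own_m_of: dict
    ranking: tuple
    final_pair: tuple

    def ranks(self, tie_policy: str = "min") -> dict:
        """Integer ranks, best = 1; the terminal pair is tied.

        ``min`` gives both pair members rank 1 and the next gene rank 3
        (competition ranking); ``consecutive`` breaks the tie by input
        column order, ranks 1 and 2.
        """
        if tie_policy == "min":
            out = {self.ranking[0]: 1, self.ranking[1]: 1}
            out.update({g: i + 1 for i, g in enumerate(self.ranking) if i >= 2})
        elif tie_policy == "consecutive":
            out = {g: i + 1 for i, g in enumerate(self.ranking)}
        else:
            raise ValueError(f"unknown tie policy {tie_policy!r}")
        return out


def genorm_ranking(
    rq: RQMatrix,
    genes: Sequence[str] | None = None,
    samples: Iterable | None = None,
) -> GeNormResult:
    """Stepwise exclusion: drop the highest-M gene until two remain.

    Ties on the maximal M are broken by removing the gene occurring
    later in input column order.
    """
    x = _log_expr(rq, samples)
    remaining = list(genes) if genes is not None else list(x.columns)
    if len(remaining) < 3:
        raise ValueError("stepwise geNorm needs at least 3 genes")
    exclusion, m_of, own_m_of = [], {}, {}
    while len(remaining) > 2:
        m = m_values(rq, remaining, samples)
        step_avg = float(m.mean())
        # later-in-input-order wins the tie: scan reversed
        worst = max(reversed(list(m.index)), key=lambda g: m[g])
        exclusion.append(worst)
        m_of[worst] = step_avg
        own_m_of[worst] = float(m[worst])
        remaining.remove(worst)
    m = m_values(rq, remaining, samples)
    terminal = float(m.mean())
    for g in remaining:
        m_of[g] = terminal
        own_m_of[g] = float(m[g])
    ranking = tuple(remaining) + tuple(reversed(exclusion))
    return GeNormResult(
        exclusion_order=tuple(exclusion) + tuple(remaining),
        m_of=m_of,
        own_m_of=own_m_of,
        ranking=ranking,
        final_pair=tuple(remaining),
    )


def normalization_factor(
    rq: RQMatrix,
    genes: Sequence[str],
    samples: Iterable | None = None,
) -> pd.Series:
    """Per-sample normalization factor: geometric mean of RQ over genes."""
    genes = list(genes)
    if not genes:
        raise ValueError("normalization factor needs at least 1 gene")
    x = _log_expr(rq, samples)
    return pd.Series(2.0 ** x[genes].mean(axis=1), index=x.index, name="NF")


@dataclasses.dataclass(frozen=True)
class PairwiseVariationSeries:
    """V(n, n+1) over nested normalization-factor gene sets."""

    v_of: dict
    threshold: float
    optimal_n: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.v_of, name="V").rename_axis("n")


def pairwise_variation_series(
    rq: RQMatrix,
    result: GeNormResult,
    samples: Iterable | None = None,
    threshold: float = V_THRESHOLD,
) -> PairwiseVariationSeries:
    """V(n, n+1) = SD over samples of log2(NF_n / NF_{n+1}), n = 2..k-1.

    ``optimal_n`` is the smallest n whose V falls below the threshold;
    if none does, all k genes are reported with a warning (the criterion
    is a guideline, not a hard rule).
    """
    ranking = list(result.ranking)
    k = len(ranking)
    if k < 3:
        raise ValueError("pairwise variation needs at least 3 ranked genes")
    x = _log_expr(rq, samples)
    log_nf = {n: x[ranking[:n]].mean(axis=1) for n in range(2, k + 1)}
    v_of = {
        n: float((log_nf[n] - log_nf[n + 1]).std(ddof=1)) for n in range(2, k)
    }
    below = [n for n, v in v_of.items() if v < threshold]
    if below:
        optimal_n = min(below)
    else:
        warnings.warn(
            f"no pairwise variation fell below {threshold}; "
            "reporting all genes as the optimal set",
            stacklevel=2,
        )
        optimal_n = k
    return PairwiseVariationSeries(v_of=v_of, threshold=threshold, optimal_n=optimal_n)
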