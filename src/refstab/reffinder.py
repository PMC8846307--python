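"""Consensus (comprehensive) ranking across stability methods.

Each method's scores are converted to integer ranks (1 = most stable)
and a gene's comprehensive score is the geometric mean of its ranks —
the aggregation behind the familiar "comprehensive ranking" column of
reference-gene surveys.  Four votes enter by default: comparative
delta-Ct, stepwise geNorm, ungrouped model-based (NormFinder-style)
stability, and the BestKeeper mean-absolute-deviation SD.  geNorm's
tied terminal pair contributes rank 1 for both genes by default
(competition ranking: 1, 1, 3, ...), the policy that reproduces
published composite scores; consecutive tie-breaking is available.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .bestkeeper import bestkeeper_descriptives
from .deltact import delta_ct_scores
from .genorm import genorm_ranking
from .io import CqMatrix
from .normfinder import normfinder_ungrouped
from .preprocess import relative_quantities

__all__ = [
    "StabilityResult",
    "AggregateRanking",
    "rank_from_scores",
    "comprehensive_ranking",
    "reffinder_pipeline",
]


@dataclasses.dataclass(frozen=True)
class StabilityResult:
    """One method's per-gene scores and ascending-stability ranks."""

    method: str
    score_of: dict
    rank_of: dict

    def as_series(self) -> pd.Series:
        order = sorted(self.score_of, key=lambda g: self.rank_of[g])
        return pd.Series({g: self.score_of[g] for g in order}, name=self.method)


def rank_from_scores(
    scores: Mapping[str, float],
    tie_policy: str = "consecutive",
) -> dict:
    """Ascending integer ranks from scores (lower score = better rank).

    ``consecutive`` (default) breaks ties by input order, yielding a
    permutation of 1..k; ``min`` assigns tied genes their minimal
    (competition) rank, so a tied pair gets 1, 1, 3, ...
    """
    items = list(scores.items())
    for gene, s in items:
        if s is None or (isinstance(s, float) and math.isnan(s)):
            raise ValueError(f"cannot rank {gene!r}: score is NaN")
    order = sorted(range(len(items)), key=lambda i: items[i][1])
    ranks: dict = {}
    if tie_policy == "consecutive":
        for pos, i in enumerate(order, start=1):
            ranks[items[i][0]] = pos
    elif tie_policy == "min":
        pos = 0
        prev_score = None
        prev_rank = 0
        for i in order:
            pos += 1
            gene, s = items[i]
            if prev_score is not None and s == prev_score:
                ranks[gene] = prev_rank
            else:
                ranks[gene] = pos
                prev_rank, prev_score = pos, s
    else:
        raise ValueError(f"unknown tie policy {tie_policy!r}")
    return ranks


@dataclasses.dataclass(frozen=True)
class AggregateRanking:
    """Geometric-mean-of-ranks consensus over several methods."""

    geo_rank_of: dict
    order: tuple
    per_method_ranks: pd.DataFrame

    def as_series(self) -> pd.Series:
        return pd.Series(
            {g: self.geo_rank_of[g] for g in self.order}, name="geo_rank"
        )


def comprehensive_ranking(results: Sequence[StabilityResult]) -> AggregateRanking:
    """Aggregate >= 2 methods over an identical gene set.

    geo_rank(g) = (prod of the per-method ranks)^(1/M); the output order
    is ascending geo_rank with ties broken by the first method's input
    gene order.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("consensus needs at least 2 methods")
    gene_sets = [set(r.rank_of) for r in results]
    if any(s != gene_sets[0] for s in gene_sets[1:]):
        raise ValueError("methods rank different gene sets")
    genes = list(results[0].rank_of)
    M = len(results)
    geo = {
        g: math.prod(r.rank_of[g] for r in results) ** (1.0 / M) for g in genes
    }
    order = tuple(sorted(genes, key=lambda g: (geo[g], genes.index(g))))
    table = pd.DataFrame(
        {r.method: pd.Series(r.rank_of) for r in results}
    ).loc[list(order)]
    table["geo_rank"] = pd.Series(geo)
    return AggregateRanking(geo_rank_of=geo, order=order, per_method_ranks=table)


def reffinder_pipeline(
    cq: CqMatrix,
    samples: Iterable | None = None,
    genorm_tie_policy: str = "min",
    bestkeeper_statistic: str = "sd_cp",
) -> AggregateRanking:
    """Run the four default methods and aggregate their ranks.

    BestKeeper votes by ``sd_cp`` (default) or by descending index
    correlation (``index_r``); the model-based method runs ungrouped,
    matching how consensus web tools treat unlabelled uploads.
    """
    sub = cq if samples is None else cq.select(samples=samples)
    rq = relative_quantities(sub)

    dct = delta_ct_scores(sub)
    gn = genorm_ranking(rq)
    nf = normfinder_ungrouped(rq)
    if bestkeeper_statistic == "sd_cp":
        bk_scores = bestkeeper_descriptives(sub)["sd_cp"]
    elif bestkeeper_statistic == "index_r":
        from .bestkeeper import bestkeeper_index, index_correlations

        idx = bestkeeper_index(sub)
        bk_scores = -index_correlations(sub, idx)["r"]  # higher r = better
    else:
        raise ValueError(f"unknown BestKeeper statistic {bestkeeper_statistic!r}")

    results = [
        StabilityResult("deltact", dct.to_dict(), rank_from_scores(dct.to_dict())),
        StabilityResult("genorm", dict(gn.m_of), gn.ranks(genorm_tie_policy)),
        StabilityResult("normfinder", nf.to_dict(), rank_from_scores(nf.to_dict())),
        StabilityResult(
            "bestkeeper", bk_scores.to_dict(), rank_from_scores(bk_scores.to_dict())
        ),
    ]
    return comprehensive_ranking(results)
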