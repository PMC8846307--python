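"""BestKeeper descriptive stability on raw Cq.

BestKeeper never transforms Cq to relative quantities: it ranks genes
by the spread of their raw crossing points.  Its "std dev [+/- CP]" is
the *mean absolute deviation* about the arithmetic mean Cq (not the
classical SD), with genes above 1 cycle deemed unacceptable; CV is
that deviation as a percent of the mean.  x-fold values express the
extreme Cq excursions as fold changes around the geometric mean, and
the BestKeeper index — the per-sample geometric mean Cq over the
candidates — gives each gene a Pearson correlation that measures how
well it follows the common trend.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CqMatrix

__all__ = [
    "BestKeeperReport",
    "bestkeeper_descriptives",
    "pairwise_correlations",
    "bestkeeper_index",
    "index_correlations",
    "bestkeeper_report",
    "SD_ACCEPTABLE",
    "P_FLOOR",
]

SD_ACCEPTABLE = 1.0  # cycles; genes at or above are deemed unstable
P_FLOOR = 0.001  # reporting floor for p-values, full precision kept internally


def _subset(cq: CqMatrix, samples: Iterable | None) -> pd.DataFrame:
    return cq.data if samples is None else cq.data.loc[list(samples)]


def bestkeeper_descriptives(
    cq: CqMatrix,
    samples: Iterable | None = None,
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """Per-gene descriptive block (rows = genes).

    Columns: n, geo_mean_cq, ar_mean_cq, min_cq, max_cq, sd_cp (mean
    absolute deviation, cycles), cv_pct, min_xfold, max_xfold, sd_xfold,
    acceptable (sd_cp < 1).  x-fold values anchor on the geometric mean:
    min_xfold = -E^(geo_mean - min), max_xfold = +E^(max - geo_mean).
    """
    df = _subset(cq, samples)
    if len(df) < 2:
        raise ValueError("descriptives need at least 2 samples")
    if (df.to_numpy() <= 0).any():
        raise ValueError("geometric mean undefined for non-positive Cq")
    geo = np.exp(np.log(df).mean(axis=0))
    ar = df.mean(axis=0)
    sd_cp = (df - ar).abs().mean(axis=0)
    out = pd.DataFrame(
        {
            "n": len(df),
            "geo_mean_cq": geo,
            "ar_mean_cq": ar,
            "min_cq": df.min(axis=0),
            "max_cq": df.max(axis=0),
            "sd_cp": sd_cp,
            "cv_pct": 100.0 * sd_cp / ar,
            "min_xfold": -(efficiency ** (geo - df.min(axis=0))),
            "max_xfold": efficiency ** (df.max(axis=0) - geo),
            "sd_xfold": efficiency**sd_cp,
        }
    )
    out["acceptable"] = out["sd_cp"] < SD_ACCEPTABLE
    out.index.name = "gene"
    return out


def _pearson(a: pd.Series, b: pd.Series) -> tuple[float, float]:
    if a.std(ddof=1) == 0 or b.std(ddof=1) == 0:
        warnings.warn("zero-variance gene; correlation undefined", stacklevel=3)
        return np.nan, np.nan
    r, p = stats.pearsonr(a, b)
    return float(r), float(p)


def pairwise_correlations(
    cq: CqMatrix,
    samples: Iterable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson r and two-sided p for every unordered gene pair on raw Cq."""
    df = _subset(cq, samples)
    if len(df) < 3:
        raise ValueError("correlations need at least 3 samples")
    genes = list(df.columns)
    r = pd.DataFrame(np.eye(len(genes)), index=genes, columns=genes)
    p = pd.DataFrame(np.zeros((len(genes), len(genes))), index=genes, columns=genes)
    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            rv, pv = _pearson(df[a], df[b])
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
    return r, p


def bestkeeper_index(
    cq: CqMatrix,
    genes: Sequence[str] | None = None,
    samples: Iterable | None = None,
    acceptable_only: bool = False,
) -> pd.Series:
    """Per-sample BestKeeper index: geometric mean Cq over the chosen genes.

    Defaults to all candidates; ``acceptable_only`` restricts to genes
    with sd_cp < 1 cycle, as the original tool optionally does.
    """
    df = _subset(cq, samples)
    genes = list(genes) if genes is not None else list(df.columns)
    if acceptable_only:
        desc = bestkeeper_descriptives(cq, samples)
        genes = [g for g in genes if desc.loc[g, "acceptable"]]
    if not genes:
        raise ValueError("BestKeeper index needs at least 1 gene")
    return pd.Series(
        np.exp(np.log(df[genes]).mean(axis=1)), index=df.index, name="bestkeeper_index"
    )


def index_correlations(
    cq: CqMatrix,
    index: pd.Series,
    samples: Iterable | None = None,
) -> pd.DataFrame:
    """Pearson r and p of each gene's raw Cq against the index."""
    df = _subset(cq, samples)
    rows = {}
    for gene in df.columns:
        rows[gene] = _pearson(df[gene], index.loc[df.index])
    out = pd.DataFrame(rows, index=["r", "p"]).T
    out.index.name = "gene"
    return out


@dataclasses.dataclass(frozen=True)
class BestKeeperReport:
    """Full BestKeeper output bundle for one sample subset."""

    descriptives: pd.DataFrame
    pair_r: pd.DataFrame
    pair_p: pd.DataFrame
    index: pd.Series
    index_correlations: pd.DataFrame

    @property
    def sd_cp(self) -> pd.Series:
        return self.descriptives["sd_cp"]

    def formatted_p(self, p: float) -> float:
        """p-values are reported no smaller than the 0.001 floor."""
        return max(float(p), P_FLOOR)


def bestkeeper_report(
    cq: CqMatrix,
    samples: Iterable | None = None,
    efficiency: float = 2.0,
    acceptable_only_index: bool = False,
) -> BestKeeperReport:
    """Run the complete BestKeeper analysis on a sample subset."""
    desc = bestkeeper_descriptives(cq, samples, efficiency)
    pair_r, pair_p = pairwise_correlations(cq, samples)
    index = bestkeeper_index(cq, samples=samples, acceptable_only=acceptable_only_index)
    idx_corr = index_correlations(cq, index, samples)
    return BestKeeperReport(desc, pair_r, pair_p, index, idx_corr)
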