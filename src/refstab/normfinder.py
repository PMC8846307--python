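"""Model-based (NormFinder-style) stability via variance decomposition.

Log-scale expression of gene i in sample j of group g is modelled
additively: gene level + sample loading + group-specific gene shift +
noise.  Per-sample loading is removed by centering each sample on its
across-gene mean; what remains is decomposed into an intragroup
variance sigma^2_ig (how noisy the gene is within a group) and an
intergroup deviation d_ig (how much the gene's level departs between
groups).  Because each gene is measured against the average of all k
candidates, naive moment estimates are biased; the k/(k-2)-type
corrections below remove that bias, and negative variance estimates
are truncated at zero.  The intergroup deviations are shrunk towards
zero in proportion to their sampling noise, and a gene's stability
value combines the shrunken deviation magnitude with its uncertainty —
low values mark genes that are both steady within groups and level
across groups.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GroupDesign
from .preprocess import RQMatrix

__all__ = [
    "VarianceComponents",
    "normfinder_grouped",
    "normfinder_ungrouped",
    "normfinder_stability",
    "intergroup_variation_table",
]


@dataclasses.dataclass(frozen=True)
class VarianceComponents:
    """Variance decomposition underlying the stability values.

    All on the chosen log scale: ``sigma2`` intragroup variances
    (gene x group), ``d`` raw and ``d_shrunk`` shrunken intergroup
    deviations (each gene's deviations sum to zero over groups),
    ``gamma2`` the common intergroup variance, ``stability_of`` the
    per-gene stability (lower = more stable).
    """

    sigma2: pd.DataFrame
    d: pd.DataFrame
    d_shrunk: pd.DataFrame
    gamma2: float
    stability_of: pd.Series
    log_base: float


def _log_expr(rq: RQMatrix, samples: Iterable | None, base: float) -> pd.DataFrame:
    x = rq.log(base)
    if samples is not None:
        x = x.loc[list(samples)]
    return x


def _intragroup_sigma2(z: pd.DataFrame) -> pd.Series:
    """Bias-corrected per-gene variance from sample-centered residuals.

    Centering each sample on its across-gene mean mixes 1/k of every
    gene's noise into every residual; solving the resulting moment
    equations gives the correction below (undefined for k < 3).
    """
    k = z.shape[1]
    if k < 3:
        raise ValueError("variance decomposition needs at least 3 genes")
    v = z.var(axis=0, ddof=1)
    return np.maximum(0.0, (v - v.sum() / (k * (k - 1))) * k / (k - 2))


def normfinder_grouped(
    rq: RQMatrix,
    design: GroupDesign | Mapping[str, str] | None = None,
    samples: Iterable | None = None,
    log_base: float = 2.0,
) -> VarianceComponents:
    """Grouped stability: intragroup noise plus shrunken intergroup shift.

    ``design`` defaults to the group labels carried by the matrix; any
    sample -> group mapping (e.g. breed instead of environment) may be
    supplied instead.  Needs >= 2 groups with >= 2 samples each and
    >= 3 genes.
    """
    x = _log_expr(rq, samples, log_base)
    if design is None:
        labels = rq.groups.loc[x.index]
        design = GroupDesign.from_labels(labels)
    elif not isinstance(design, GroupDesign):
        design = GroupDesign.from_labels(pd.Series(dict(design)).loc[x.index])
    design.require_grouped(min_per_group=2)

    k = x.shape[1]
    groups = list(design.groups)
    G = len(groups)
    z = x.sub(x.mean(axis=1), axis=0)  # remove per-sample loading

    sigma2, zbar, n_g = {}, {}, design.n_g
    for g in groups:
        zg = z.loc[list(design.members[g])]
        sigma2[g] = _intragroup_sigma2(zg)
        zbar[g] = zg.mean(axis=0)
    sigma2 = pd.DataFrame(sigma2)  # genes x groups
    zbar = pd.DataFrame(zbar)
    d = zbar.sub(zbar.mean(axis=1), axis=0)  # unweighted group centering

    n_series = pd.Series(n_g)
    s2n = sigma2.div(n_series, axis=1)  # sampling variance of each group mean
    gamma2 = max(
        0.0,
        float((d**2).to_numpy().sum()) / ((k - 1) * (G - 1))
        - float(s2n.to_numpy().sum()) / (k * G),
    )
    if gamma2 > 0:
        shrink = gamma2 / (gamma2 + s2n)
    else:
        shrink = s2n * 0.0
    d_shrunk = d * shrink
    rho = d_shrunk.abs() + np.sqrt(s2n * shrink)
    stability = rho.mean(axis=1).rename("stability")
    return VarianceComponents(
        sigma2=sigma2,
        d=d,
        d_shrunk=d_shrunk,
        gamma2=gamma2,
        stability_of=stability,
        log_base=log_base,
    )


def normfinder_ungrouped(
    rq: RQMatrix,
    samples: Iterable | None = None,
    genes: Sequence[str] | None = None,
    log_base: float = 2.0,
) -> pd.Series:
    """Single-group stability: the bias-corrected intragroup SD per gene."""
    x = _log_expr(rq, samples, log_base)
    if genes is not None:
        x = x[list(genes)]
    z = x.sub(x.mean(axis=1), axis=0)
    return np.sqrt(_intragroup_sigma2(z)).rename("stability")


def normfinder_stability(
    rq: RQMatrix,
    design: GroupDesign | None = None,
    samples: Iterable | None = None,
    log_base: float = 2.0,
) -> pd.Series:
    """Stability values; dispatches to the grouped or ungrouped variant.

    With fewer than two groups (or no design) the ungrouped reduction is
    used, so a degenerate single-group design and the ungrouped call
    agree by construction.
    """
    if design is None or len(design.groups) < 2:
        return normfinder_ungrouped(rq, samples=samples, log_base=log_base)
    return normfinder_grouped(rq, design, samples=samples, log_base=log_base).stability_of


def intergroup_variation_table(vc: VarianceComponents) -> pd.DataFrame:
    """Raw (unshrunken) gene x group intergroup deviations, for plotting."""
    return vc.d.copy()
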