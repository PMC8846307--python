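"""Target-gene normalization with a chosen reference panel.

Relative expression of a target is its relative quantity divided by the
per-sample normalization factor (geometric mean RQ of the panel).  The
module also contrasts two panels side by side — the practical question
being whether a badly chosen panel (e.g. one containing a gene whose
own expression shifts between groups) distorts or even reverses the
apparent group difference of a target.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .genorm import normalization_factor
from .io import CqMatrix, GroupDesign
from .preprocess import RQMatrix, relative_quantities

__all__ = ["NormalizedExpression", "normalize_targets", "panel_contrast", "PanelContrast"]


@dataclasses.dataclass(frozen=True)
class NormalizedExpression:
    """Per-sample relative expression of one target and group summaries."""

    target: str
    panel: tuple
    expression: pd.Series  # per sample, > 0
    summary: pd.DataFrame  # per group: n, mean, sd, se
    fold_difference: float  # ratio of group mean expressions (first/second)


def _group_summary(expr: pd.Series, design: GroupDesign) -> pd.DataFrame:
    rows = {}
    for g in design.groups:
        vals = expr.loc[list(design.members[g])]
        n = len(vals)
        sd = float(vals.std(ddof=1)) if n > 1 else 0.0
        rows[g] = {
            "n": n,
            "mean": float(vals.mean()),
            "sd": sd,
            "se": sd / np.sqrt(n),
        }
    return pd.DataFrame(rows).T.rename_axis("group")


def normalize_targets(
    target_cq: CqMatrix,
    ref_panel: Sequence[str],
    rq: RQMatrix,
    design: GroupDesign | None = None,
) -> dict[str, NormalizedExpression]:
    """Normalize each target gene by the panel's normalization factor.

    ``target_cq`` holds the target genes' Cq columns (same samples as
    the reference matrix); ``rq`` the reference genes' relative
    quantities.  Targets must not appear in the panel.
    """
    panel = list(ref_panel)
    overlap = set(panel) & set(target_cq.gene_ids)
    if overlap:
        raise ValueError(f"targets overlap the reference panel: {sorted(overlap)}")
    missing = set(panel) - set(rq.gene_ids)
    if missing:
        raise ValueError(f"panel genes absent from reference matrix: {sorted(missing)}")
    if design is None:
        design = target_cq.design()
    nf = normalization_factor(rq, panel, samples=target_cq.sample_ids)
    target_rq = relative_quantities(target_cq, rq.efficiency_of)
    out = {}
    for gene in target_cq.gene_ids:
        expr = (target_rq.data[gene] / nf).rename(gene)
        summ = _group_summary(expr, design)
        means = summ["mean"]
        fold = float(means.iloc[0] / means.iloc[1]) if len(means) > 1 else 1.0
        out[gene] = NormalizedExpression(
            target=gene,
            panel=tuple(panel),
            expression=expr,
            summary=summ,
            fold_difference=fold,
        )
    return out


@dataclasses.dataclass(frozen=True)
class PanelContrast:
    """Side-by-side group summaries of one target under two panels."""

    target: str
    best: NormalizedExpression
    worst: NormalizedExpression
    reversal: bool  # substantial group difference flips direction between panels


def panel_contrast(
    target_cq: CqMatrix,
    best_panel: Sequence[str],
    worst_panel: Sequence[str],
    rq: RQMatrix,
    design: GroupDesign | None = None,
    reversal_margin: float = 0.25,
) -> dict[str, PanelContrast]:
    """Contrast normalization under two reference panels per target.

    A *reversal* is flagged when the fold difference between the first
    two groups points in opposite directions under the two panels AND
    exceeds ``reversal_margin`` (log2 units, default 0.25 ~ 1.19-fold)
    under both — the signature of a panel gene whose own group shift
    confounds the target's, as opposed to sign jitter around a null
    difference.
    """
    if design is None:
        design = target_cq.design()
    best = normalize_targets(target_cq, best_panel, rq, design)
    worst = normalize_targets(target_cq, worst_panel, rq, design)
    out = {}
    for gene in target_cq.gene_ids:
        lfb = np.log2(best[gene].fold_difference)
        lfw = np.log2(worst[gene].fold_difference)
        flipped = bool(np.sign(lfb) * np.sign(lfw) < 0)
        substantial = min(abs(lfb), abs(lfw)) > reversal_margin
        out[gene] = PanelContrast(
            target=gene,
            best=best[gene],
            worst=worst[gene],
            reversal=flipped and substantial,
        )
    return out
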