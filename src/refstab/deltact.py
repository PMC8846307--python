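"""Comparative delta-Ct stability.

Score a gene by the mean, over every other candidate, of the standard
deviation across samples of the pairwise Cq difference.  With perfect
doubling (E = 2) this is algebraically identical to the first-iteration
geNorm M value, since log2 expression ratios are Cq differences up to a
per-gene constant that the SD removes.  It is kept as its own method
because consensus rankings treat it as a fourth, independent vote.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .io import CqMatrix

__all__ = ["delta_ct_scores"]


def delta_ct_scores(
    cq: CqMatrix,
    genes: Sequence[str] | None = None,
    samples: Iterable | None = None,
) -> pd.Series:
    """Mean pairwise-difference SD per gene on raw Cq; lower = more stable."""
    df = cq.data if samples is None else cq.data.loc[list(samples)]
    genes = list(genes) if genes is not None else list(df.columns)
    if len(genes) < 2:
        raise ValueError("comparative delta-Ct needs at least 2 genes")
    if len(df) < 2:
        raise ValueError("comparative delta-Ct needs at least 2 samples")
    x = df[genes].to_numpy()
    diffs = x[:, :, None] - x[:, None, :]
    sds = diffs.std(axis=0, ddof=1)
    scores = sds.sum(axis=1) / (len(genes) - 1)
    return pd.Series(scores, index=genes, name="delta_ct")
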