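"""Synthetic Cq generator with known variance structure.

Cq values are generated from the additive model that the stability
methods implicitly assume on the log-expression scale:

    Cq[i, g, j] = baseline_i + s_gj + shift_ig + eps_igj

with per-sample loading offsets s ~ N(0, sample_factor_sd^2) shared by
all genes of a sample (mimicking input-amount differences, which
ratio-based methods must ignore), fixed group x gene shifts, and
independent per-gene noise eps ~ N(0, noise_sd_i^2).  Because the truth
is known, every stability method becomes testable by parameter
recovery.  ``paperlike_spec`` re-fits all parameters by moments from
the packaged bovine PBMC dataset, so simulated matrices mirror its
two-environment, 10-gene structure.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .io import CQ_MAX, CQ_MIN, CqMatrix

__all__ = ["SimulationSpec", "generate_cq", "paperlike_spec"]


@dataclasses.dataclass(frozen=True)
class SimulationSpec:
    """Ground truth for one synthetic Cq matrix.

    ``groups`` maps group label -> sample count (>= 2 each);
    ``baseline_cq`` the per-gene level in cycles; ``noise_sd`` per-gene
    noise SD (cycles, >= 0); ``group_shift`` per-gene map
    group -> additive shift (cycles, defaults to 0);
    ``sample_factor_sd`` the SD of the shared per-sample loading offset.
    """

    groups: Mapping[str, int]
    baseline_cq: Mapping[str, float]
    noise_sd: Mapping[str, float]
    group_shift: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )
    sample_factor_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("need at least one group")
        for g, n in self.groups.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs >= 2 samples, got {n}")
        if set(self.noise_sd) != set(self.baseline_cq):
            raise ValueError("noise_sd must cover exactly the baseline genes")
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SDs must be >= 0")
        if self.sample_factor_sd < 0:
            raise ValueError("sample_factor_sd must be >= 0")

    @property
    def gene_ids(self) -> list:
        return list(self.baseline_cq)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def generate_cq(spec: SimulationSpec) -> tuple[CqMatrix, SimulationSpec]:
    """Draw one Cq matrix from the spec; reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids
    rows, labels, ids = [], [], []
    for group, n in spec.groups.items():
        shifts = np.array(
            [spec.group_shift.get(g, {}).get(group, 0.0) for g in genes]
        )
        base = np.array([spec.baseline_cq[g] for g in genes])
        sds = np.array([spec.noise_sd[g] for g in genes])
        loading = rng.normal(0.0, spec.sample_factor_sd, size=n)
        noise = rng.normal(0.0, 1.0, size=(n, len(genes))) * sds
        rows.append(base + shifts + loading[:, None] + noise)
        labels += [group] * n
        ids += [f"{group}_{j + 1}" for j in range(n)]
    values = np.clip(np.vstack(rows), CQ_MIN, CQ_MAX)
    df = pd.DataFrame(values, index=ids, columns=genes)
    return CqMatrix(df, pd.Series(labels, index=ids)), spec


def paperlike_spec(seed: int = 0) -> SimulationSpec:
    """Moment-fit a spec to the packaged bovine PBMC dataset.

    Baselines are the per-gene overall mean Cq; group shifts the
    per-gene group-mean deviations; the loading SD is estimated from
    per-sample mean residuals across genes; per-gene noise SDs are the
    pooled within-group SDs with the loading component removed.
    """
    from .datasets import load_pbmc_cq

    cq = load_pbmc_cq()
    df, labels = cq.data, cq.groups
    group_means = df.groupby(labels).mean()
    baseline = df.mean(axis=0)
    shifts = group_means.sub(baseline, axis=1)

    # residuals about each sample's group x gene mean
    resid = df - group_means.loc[labels].to_numpy()
    sample_offset = resid.mean(axis=1)
    sample_factor_sd = float(sample_offset.std(ddof=1))
    within_var = resid.var(axis=0, ddof=1)
    noise_var = np.maximum(within_var - sample_factor_sd**2, 0.01**2)

    return SimulationSpec(
        groups={g: int((labels == g).sum()) for g in dict.fromkeys(labels)},
        baseline_cq=baseline.round(4).to_dict(),
        noise_sd=np.sqrt(noise_var).round(4).to_dict(),
        group_shift={
            g: shifts[g].round(4).to_dict() for g in df.columns
        },
        sample_factor_sd=round(sample_factor_sd, 4),
        seed=seed,
    )
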