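"""Packaged example data: bovine PBMC reference-gene Cq matrix.

The packaged dataset is a published RT-qPCR survey of 10 candidate
reference genes (GAPDH, RPL4, EEF1A1, RPS9, HPRT1, UXT, HMBS, B2M,
RPS15, ACTB) in peripheral blood mononuclear cells of 30 cattle: 15
animals from a cold arid high-altitude hypoxia environment (Ladakhi,
Holstein-Friesian-cross and Jersey cows) and 15 from a hot arid
normoxia environment (Sahiwal, Karan Fries and Holstein Friesian cows).
One averaged Cq value per animal and gene.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import CqMatrix, read_cq_table

__all__ = [
    "load_pbmc_cq",
    "primer_standard_curves",
    "COLD_GROUP",
    "HOT_GROUP",
]

COLD_GROUP = "cold_arid"
HOT_GROUP = "hot_arid"

#: standard-curve slope, published percent efficiency and R^2 per assay
#: (six-point, five-fold dilution series of pooled PBMC cDNA).  The last
#: four entries are the hypoxia/heat-stress target-gene assays.
_STANDARD_CURVES = {
    # gene: (slope, efficiency_pct, r2)
    "ACTB": (-3.14, 108.20, 0.996),
    "GAPDH": (-3.58, 90.20, 0.827),
    "EEF1A1": (-3.30, 100.92, 0.986),
    "B2M": (-3.27, 102.20, 0.998),
    "HMBS": (-3.20, 105.21, 0.996),
    "RPL4": (-3.32, 101.2, 0.922),
    "RPS15": (-3.54, 91.6, 0.989),
    "RPS9": (-3.34, 99.25, 0.941),
    "UXT": (-3.22, 104.4, 0.997),
    "HPRT1": (-3.64, 88.06, 0.987),
    "HIF1A": (-3.16, 103.0, 0.991),
    "EPAS1": (-3.10, 114.0, 0.995),
    "HSP70": (-2.90, 120.0, 0.990),
    "HSP27": (-3.20, 104.0, 0.998),
}


def load_pbmc_cq() -> CqMatrix:
    """Load the packaged 30-sample x 10-gene bovine PBMC Cq matrix.

    Sample order: LAC1-6, HFX1-5, JYC1-4 (group ``cold_arid``), then
    SAC1-5, KFC1-5, HFC1-5 (group ``hot_arid``).
    """
    ref = resources.files("refstab.data") / "bovine_pbmc_cq.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return read_cq_table(fh, sep=",")


def primer_standard_curves() -> pd.DataFrame:
    """Published standard-curve slope, percent efficiency and R^2 per assay."""
    return pd.DataFrame.from_dict(
        _STANDARD_CURVES, orient="index", columns=["slope", "efficiency_pct", "r2"]
    ).rename_axis("gene")
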