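"""Model/Results front end over the stability methods.

`ReferenceGeneStability` wraps a validated Cq matrix the way a
statsmodels model wraps its endog/exog: construct it from a DataFrame,
a CSV path, or the packaged dataset, then call :meth:`fit` to run the
selected stability methods.  The returned :class:`StabilityResults`
carries each method's scores, the consensus ranking, the geNorm
optimal-gene-count analysis, and a text ``summary()``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import bestkeeper as bk
from . import deltact as dc
from . import genorm as gn
from . import normfinder as nf
from .io import CqMatrix, GroupDesign, read_cq_table, write_stability_report
from .preprocess import descriptive_stats, expression_tiers, relative_quantities
from .reffinder import StabilityResult, comprehensive_ranking, rank_from_scores

__all__ = ["ReferenceGeneStability", "StabilityResults"]

ALL_METHODS = ("genorm", "normfinder", "bestkeeper", "deltact")


class ReferenceGeneStability:
    """Expression-stability model for a panel of candidate reference genes.

    Parameters
    ----------
    cq : CqMatrix
        Complete samples x genes Cq matrix with group labels.
    efficiencies : mapping, optional
        Per-gene amplification bases; default 2.0 (perfect doubling).

    Examples
    --------
    >>> from refstab.datasets import load_pbmc_cq
    >>> model = ReferenceGeneStability(load_pbmc_cq())
    >>> res = model.fit()
    >>> res.consensus.order[0]
    'RPS9'
    """

    def __init__(
        self,
        cq: CqMatrix,
        efficiencies: Mapping[str, float] | None = None,
    ) -> None:
        self.cq = cq
        self.efficiencies = dict(efficiencies or {})
        self.rq = relative_quantities(cq, self.efficiencies)

    # -- constructors ----------------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        groups: pd.Series | Mapping[str, str] | None = None,
        **kwargs,
    ) -> "ReferenceGeneStability":
        if groups is None:
            groups = pd.Series("all", index=data.index)
        elif not isinstance(groups, pd.Series):
            groups = pd.Series(dict(groups)).loc[data.index]
        return cls(CqMatrix(data.astype(float), groups), **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "ReferenceGeneStability":
        return cls(read_cq_table(path), **kwargs)

    # -- fitting ---------------------------------------------------------------

    def fit(
        self,
        methods: Sequence[str] = ALL_METHODS,
        subset_group: str | None = None,
        normfinder_design: GroupDesign | Mapping[str, str] | str | None = "labels",
        genorm_threshold: float = gn.V_THRESHOLD,
    ) -> "StabilityResults":
        """Run the selected methods, optionally on a single group.

        ``normfinder_design`` selects the grouping for the model-based
        method: ``"labels"`` uses the matrix's group column (falling
        back to ungrouped when only one group remains), ``None`` forces
        the ungrouped variant, and any sample -> group mapping supplies
        a custom design (e.g. breeds).
        """
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}; choose from {ALL_METHODS}")
        if not methods:
            raise ValueError("select at least one method")
        cq = self.cq if subset_group is None else self.cq.select(group=subset_group)
        rq = relative_quantities(cq, self.efficiencies)

        results: dict[str, StabilityResult] = {}
        genorm_res = variation = nf_components = None

        if "genorm" in methods:
            genorm_res = gn.genorm_ranking(rq)
            variation = gn.pairwise_variation_series(
                rq, genorm_res, threshold=genorm_threshold
            )
            results["genorm"] = StabilityResult(
                "genorm", dict(genorm_res.m_of), genorm_res.ranks("min")
            )
        if "normfinder" in methods:
            design: GroupDesign | None
            if normfinder_design == "labels":
                design = cq.design()
                if len(design.groups) < 2:
                    design = None
            elif normfinder_design is None:
                design = None
            elif isinstance(normfinder_design, GroupDesign):
                design = normfinder_design
            else:
                design = GroupDesign.from_labels(
                    pd.Series(dict(normfinder_design)).loc[cq.data.index]
                )
            if design is not None:
                nf_components = nf.normfinder_grouped(rq, design)
                scores = nf_components.stability_of
            else:
                scores = nf.normfinder_ungrouped(rq)
            results["normfinder"] = StabilityResult(
                "normfinder", scores.to_dict(), rank_from_scores(scores.to_dict())
            )
        bk_report = None
        if "bestkeeper" in methods:
            bk_report = bk.bestkeeper_report(cq)
            scores = bk_report.sd_cp
            results["bestkeeper"] = StabilityResult(
                "bestkeeper", scores.to_dict(), rank_from_scores(scores.to_dict())
            )
        if "deltact" in methods:
            scores = dc.delta_ct_scores(cq)
            results["deltact"] = StabilityResult(
                "deltact", scores.to_dict(), rank_from_scores(scores.to_dict())
            )

        consensus = None
        if len(results) >= 2:
            order = ["deltact", "genorm", "normfinder", "bestkeeper"]
            consensus = comprehensive_ranking(
                [results[m] for m in order if m in results]
            )
        return StabilityResults(
            model=self,
            cq=cq,
            method_results=results,
            genorm=genorm_res,
            pairwise_variation=variation,
            normfinder_components=nf_components,
            bestkeeper=bk_report,
            consensus=consensus,
        )


class StabilityResults:
    """Fitted stability analysis: per-method scores plus the consensus."""

    def __init__(
        self,
        model,
        cq,
        method_results,
        genorm,
        pairwise_variation,
        normfinder_components,
        bestkeeper,
        consensus,
    ) -> None:
        self.model = model
        self.cq = cq
        self.method_results = method_results
        self.genorm = genorm
        self.pairwise_variation = pairwise_variation
        self.normfinder_components = normfinder_components
        self.bestkeeper = bestkeeper
        self.consensus = consensus

    # -- views -----------------------------------------------------------------

    def scores(self) -> pd.DataFrame:
        """Gene x method score table, genes ordered by consensus when present."""
        table = pd.DataFrame(
            {m: pd.Series(r.score_of) for m, r in self.method_results.items()}
        )
        if self.consensus is not None:
            table = table.loc[list(self.consensus.order)]
            table["geo_rank"] = pd.Series(self.consensus.geo_rank_of)
        return table.rename_axis("gene")

    def recommended_panel(self) -> tuple:
        """The optimal-count best genes: geNorm V analysis sizes the panel,
        the consensus (when fitted) orders it."""
        if self.genorm is None:
            raise ValueError("panel recommendation needs the genorm method")
        n = self.pairwise_variation.optimal_n
        ranking = (
            self.consensus.order if self.consensus is not None else self.genorm.ranking
        )
        return tuple(ranking[:n])

    def summary(self) -> str:
        """Human-readable report in the spirit of a statsmodels summary."""
        design = self.cq.design()
        lines = [
            "Reference-gene expression stability",
            "=" * 68,
            f"samples: {len(self.cq.sample_ids)}   genes: {len(self.cq.gene_ids)}   "
            f"groups: {dict(design.n_g)}",
            "",
            self.scores().round(3).to_string(),
        ]
        if self.pairwise_variation is not None:
            v = self.pairwise_variation
            vtxt = "  ".join(f"V{n}/{n + 1}={val:.3f}" for n, val in v.v_of.items())
            lines += [
                "",
                f"pairwise variation: {vtxt}",
                f"optimal number of reference genes: {v.optimal_n} "
                f"(threshold {v.threshold})",
            ]
        if self.genorm is not None:
            pair = "/".join(self.genorm.final_pair)
            lines.append(f"most stable pair (geNorm): {pair} "
                         f"(M = {self.genorm.m_of[self.genorm.final_pair[0]]:.3f})")
        if self.consensus is not None:
            lines.append(
                "consensus ranking: " + " > ".join(self.consensus.order)
            )
        return "\n".join(lines)

    def descriptives(self) -> pd.DataFrame:
        stats = descriptive_stats(self.cq)
        stats["tier"] = pd.Series(expression_tiers(stats["mean"].to_dict()))
        return stats

    def write_reports(self, directory: str | Path) -> list[Path]:
        """One CSV per fitted method plus the consensus table."""
        paths = write_stability_report(self.method_results.values(), directory)
        if self.consensus is not None:
            path = Path(directory) / "stability_consensus.csv"
            self.consensus.per_method_ranks.round(3).rename_axis("gene").to_csv(path)
            paths.append(path)
        return paths

    def plot_genorm(self, ax=None):
        """geNorm stability curve and V-value bars (needs matplotlib)."""
        import matplotlib.pyplot as plt

        if self.genorm is None or self.pairwise_variation is None:
            raise ValueError("plot needs the genorm method")
        if ax is None:
            _, ax = plt.subplots(1, 2, figsize=(10, 4))
        order = list(self.genorm.exclusion_order)
        ax[0].plot(range(len(order)), [self.genorm.m_of[g] for g in order], "o-")
        ax[0].set_xticks(range(len(order)))
        ax[0].set_xticklabels(order, rotation=90)
        ax[0].set_ylabel("average expression stability M")
        v = self.pairwise_variation
        ax[1].bar([f"V{n}/{n + 1}" for n in v.v_of], list(v.v_of.values()))
        ax[1].axhline(v.threshold, color="red", ls="--")
        ax[1].set_ylabel("pairwise variation")
        return ax
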