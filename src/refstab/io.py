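"""Reading, validating and writing Cq tables and stability reports.

A Cq (quantification-cycle) table is a complete rectangular matrix of
samples x genes, with one experimental-group label per sample.  All
downstream stability algorithms assume the matrix is complete: missing
values are rejected rather than imputed, because every score in this
package is an SD-type statistic that imputation would silently bias.
Technical replicates are assumed to be collapsed upstream (one Cq per
sample and gene).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqMatrix",
    "GroupDesign",
    "CqValidationError",
    "read_cq_table",
    "write_stability_report",
]

#: admissible Cq range in PCR cycles; values outside indicate the table is
#: not a Cq table at all (e.g. already-transformed relative quantities).
CQ_MIN, CQ_MAX = 5.0, 45.0

GROUP_COLUMN = "group"


class CqValidationError(ValueError):
    """Raised when a Cq table violates the structural contract."""


@dataclasses.dataclass(frozen=True)
class CqMatrix:
    """A validated, complete samples x genes Cq matrix with group labels.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples as rows (index = sample ids), genes as columns, Cq values
        in PCR cycles.
    groups : pandas.Series
        Group label per sample, aligned with ``data.index``.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise CqValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise CqValidationError(f"duplicate gene ids: {dups}")
        if df.shape[0] < 3:
            raise CqValidationError("need at least 3 samples")
        if df.shape[1] < 1:
            raise CqValidationError("need at least 1 gene")
        try:
            values = df.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise CqValidationError(f"non-numeric Cq value: {exc}") from exc
        if not np.isfinite(values).all():
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise CqValidationError(
                f"missing or non-finite Cq at sample {df.index[i]!r}, "
                f"gene {df.columns[j]!r}; complete matrices are required"
            )
        if (values < CQ_MIN).any() or (values > CQ_MAX).any():
            i, j = np.argwhere((values < CQ_MIN) | (values > CQ_MAX))[0]
            raise CqValidationError(
                f"Cq {values[i, j]} at sample {df.index[i]!r}, gene "
                f"{df.columns[j]!r} outside the admissible range "
                f"[{CQ_MIN}, {CQ_MAX}] cycles"
            )
        groups = self.groups
        if not groups.index.equals(df.index):
            raise CqValidationError("group labels do not align with sample ids")
        if groups.isna().any():
            raise CqValidationError("every sample needs exactly one group label")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def gene_ids(self) -> list:
        return list(self.data.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self.data

    def design(self) -> "GroupDesign":
        return GroupDesign.from_labels(self.groups)

    def select(
        self,
        samples: Iterable | None = None,
        group: str | None = None,
        genes: Iterable | None = None,
    ) -> "CqMatrix":
        """Restrict to a sample subset, a single group, and/or a gene subset."""
        df, labels = self.data, self.groups
        if group is not None:
            if group not in set(labels):
                raise KeyError(f"unknown group {group!r}; have {sorted(set(labels))}")
            mask = labels == group
            df, labels = df.loc[mask], labels.loc[mask]
        if samples is not None:
            samples = list(samples)
            df, labels = df.loc[samples], labels.loc[samples]
        if genes is not None:
            df = df.loc[:, list(genes)]
        return CqMatrix(df, labels)


@dataclasses.dataclass(frozen=True)
class GroupDesign:
    """An ordered partition of the samples into experimental groups."""

    groups: tuple
    members: Mapping[str, tuple]

    @classmethod
    def from_labels(cls, labels: pd.Series) -> "GroupDesign":
        order = list(dict.fromkeys(labels))
        members = {g: tuple(labels.index[labels == g]) for g in order}
        return cls(tuple(order), members)

    @property
    def n_g(self) -> dict:
        return {g: len(m) for g, m in self.members.items()}

    def require_grouped(self, min_per_group: int = 2) -> None:
        if len(self.groups) < 2:
            raise ValueError(
                "grouped analysis needs >=2 groups; use the ungrouped variant"
            )
        for g, n in self.n_g.items():
            if n < min_per_group:
                raise ValueError(f"group {g!r} has {n} samples; need >= {min_per_group}")


def read_cq_table(
    source: str | Path | IO[str],
    orientation: str = "samples-as-rows",
    sep: str | None = None,
    default_group: str = "all",
) -> CqMatrix:
    """Read a delimited Cq table into a validated :class:`CqMatrix`.

    The first column holds sample ids (or gene ids when
    ``orientation="genes-as-rows"``); a column literally named ``group`` is
    taken as the per-sample group label.  Comma and tab delimiters are
    auto-detected when ``sep`` is not given.  Samples without a group
    column all receive ``default_group``.
    """
    if orientation not in ("samples-as-rows", "genes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    import io as _io

    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text(encoding="utf-8")
    header = text.lstrip().splitlines()[0] if text.strip() else ""
    delim = sep or ("\t" if "\t" in header else ",")
    labels = [h.strip() for h in header.split(delim)][1:]
    # pandas silently renames duplicate columns, so check the raw header
    if len(labels) != len(set(labels)):
        dups = sorted({h for h in labels if labels.count(h) > 1})
        raise CqValidationError(f"duplicate gene or sample ids in header: {dups}")
    try:
        df = pd.read_csv(_io.StringIO(text), sep=delim, index_col=0, engine="python")
    except pd.errors.ParserError as exc:
        raise CqValidationError(f"ragged or malformed table: {exc}") from exc
    if orientation == "genes-as-rows":
        df = df.T
    if GROUP_COLUMN in df.columns:
        groups = df[GROUP_COLUMN].astype(str)
        df = df.drop(columns=[GROUP_COLUMN])
    else:
        groups = pd.Series(default_group, index=df.index)
    # locate non-numeric cells before the bulk cast so the error names them
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            sample = df.index[bad.to_numpy().nonzero()[0][0]]
            raise CqValidationError(
                f"non-numeric Cq {df.loc[sample, col]!r} at sample "
                f"{sample!r}, gene {col!r}"
            )
        df[col] = coerced
    if df.shape[1] < 2:
        # a candidate-gene table needs comparisons; single-gene views are
        # only produced programmatically (e.g. target matrices)
        raise CqValidationError("need at least 2 genes")
    return CqMatrix(df, groups)


def write_cq_table(cq: CqMatrix, path: str | Path, decimals: int = 2) -> None:
    """Write a CqMatrix back to CSV (sample id, group, then gene columns)."""
    out = cq.data.round(decimals).copy()
    out.insert(0, GROUP_COLUMN, cq.groups)
    out.index.name = "sample"
    out.to_csv(path)


def write_stability_report(
    results: Sequence,
    directory: str | Path,
    decimals: int = 3,
) -> list[Path]:
    """Write one CSV per stability result (columns: rank, gene, score).

    ``results`` are :class:`refstab.reffinder.StabilityResult`-like objects
    with ``method``, ``score_of`` and ``rank_of`` attributes.  Returns the
    written paths; overwrites idempotently.
    """
    results = list(results)
    if not results:
        raise ValueError("need at least one stability result to report")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for res in results:
        if not res.score_of:
            raise ValueError(f"{res.method}: empty gene list")
        rows = sorted(res.score_of, key=lambda g: res.rank_of[g])
        frame = pd.DataFrame(
            {
                "rank": [res.rank_of[g] for g in rows],
                "gene": rows,
                "score": [round(float(res.score_of[g]), decimals) for g in rows],
            }
        )
        path = directory / f"stability_{res.method}.csv"
        frame.to_csv(path, index=False, float_format=f"%.{decimals}f")
        paths.append(path)
    return paths
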