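"""Two-group labeled feature-by-sample matrices.

The same container serves gene expression (log2-scale intensities),
DNA-methylation beta values in [0, 1], and lncRNA expression: a numeric
``features x samples`` grid plus a case/control label per sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"


@dataclass
class LabeledMatrix:
    """Features x samples numeric matrix with a two-group sample partition.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by feature ID, columns by sample ID. Cells may be NaN
        (missing measurements); downstream statistics use available samples.
    groups : pandas.Series
        Per-sample label, ``"case"`` or ``"control"``, indexed by sample ID
        in the same order as the columns of ``values``.
    """

    values: pd.DataFrame
    groups: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if list(self.groups.index) != list(self.values.columns):
            # allow same set, different order: realign
            if set(self.groups.index) == set(self.values.columns):
                self.groups = self.groups.reindex(self.values.columns)
            else:
                missing = set(self.values.columns) - set(self.groups.index)
                raise ValueError(f"samples without a group label: {sorted(missing)}")
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValueError(f"group labels must be case/control, got {sorted(bad)}")
        for g in (CASE, CONTROL):
            if int((self.groups == g).sum()) < 3:
                raise ValueError(f"group {g!r} has fewer than 3 samples")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate feature IDs; collapse_duplicates() first")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def case_columns(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == CASE].index]

    def control_columns(self) -> pd.DataFrame:
        return self.values.loc[:, self.groups[self.groups == CONTROL].index]


def collapse_duplicates(values: pd.DataFrame, pvalues: pd.Series | None = None) -> pd.DataFrame:
    """Collapse duplicate feature IDs (e.g. multiple probes per gene symbol).

    When per-feature p-values are supplied, the row with the smallest p wins;
    otherwise the first occurrence is kept.
    """
    if not values.index.has_duplicates:
        return values
    if pvalues is None:
        return values[~values.index.duplicated(keep="first")]
    order = pvalues.reindex(values.index).to_numpy()
    df = values.copy()
    df["__p"] = order
    df = df.sort_values("__p", kind="stable")
    df = df[~df.index.duplicated(keep="first")].drop(columns="__p")
    return df.loc[[i for i in dict.fromkeys(values.index)]]


def read_matrix_tsv(matrix_path: str | Path, groups_path: str | Path) -> LabeledMatrix:
    """Read a matrix TSV (first column = feature ID, header = sample IDs)
    together with a two-column sample-to-group TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    gdf = pd.read_csv(groups_path, sep="\t", index_col=0)
    groups = gdf.iloc[:, 0].astype(str)
    groups.index = groups.index.astype(str)
    return LabeledMatrix(values=values, groups=groups)


def write_matrix_tsv(matrix: LabeledMatrix, matrix_path: str | Path,
                     groups_path: str | Path | None = None) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(matrix_path, sep="\t", float_format="%.6g")
    if groups_path is not None:
        g = matrix.groups.rename("group").to_frame()
        g.index.name = "sample_id"
        g.to_csv(groups_path, sep="\t")
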