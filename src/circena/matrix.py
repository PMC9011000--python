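"""Features-by-samples expression container shared across modules."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class ExpressionMatrix:
    """A features × samples abundance table with per-sample group labels.

    ``data`` holds counts or RPM values (``units`` says which); ``groups``
    maps every sample (column) to its experimental group.
    """

    data: pd.DataFrame
    groups: pd.Series
    units: str = "counts"

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate feature ids in expression matrix")
        if (self.data.to_numpy() < 0).any():
            raise ValueError("negative values in expression matrix")
        self.groups = pd.Series(self.groups)
        missing = [s for s in self.data.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[list(self.data.columns)]

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == group]

    def subset(self, features) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[list(features)], self.groups, self.units)

    # ---------------------------------------------------------------- I/O

    def to_tsv(self, path: str | Path, float_format: str = "%.6g") -> None:
        self.data.to_csv(path, sep="\t", index_label="feature_id",
                         float_format=float_format)

    @classmethod
    def from_tsv(cls, path: str | Path, groups: pd.Series | dict,
                 units: str = "counts") -> "ExpressionMatrix":
        data = pd.read_csv(path, sep="\t", index_col=0)
        return cls(data=data, groups=pd.Series(groups), units=units)


def read_design(path: str | Path) -> pd.Series:
    """Read a two-column sample→group design TSV (header: sample, group)."""
    df = pd.read_csv(path, sep="\t")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="group")


def write_design(groups: pd.Series, path: str | Path) -> None:
    pd.DataFrame({"sample": groups.index, "group": groups.values}).to_csv(
        path, sep="\t", index=False
    )
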