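"""Core in-memory containers: the expression matrix and the five-group sample design.

The experiment layout mirrors a two-factor (exposure timing x dose) design with
a shared unirradiated control:

========  ============  ========
group     time class    dose /Gy
========  ============  ========
A         control       0
B         long_term     0.1
C         long_term     1.0
D         acute         0.1
E         acute         1.0
========  ============  ========

``long_term`` samples were irradiated as embryos and profiled 16 weeks later;
``acute`` samples were irradiated as adults 4 h before profiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DesignError, FormatError

GROUPS = ("A", "B", "C", "D", "E")

GROUP_TIME_CLASS = {
    "A": "control",
    "B": "long_term",
    "C": "long_term",
    "D": "acute",
    "E": "acute",
}

GROUP_DOSE_GY = {"A": 0.0, "B": 0.1, "C": 1.0, "D": 0.1, "E": 1.0}


@dataclass
class ExpressionMatrix:
    """A probe-set (or probe) x sample expression matrix.

    Parameters
    ----------
    data
        DataFrame with unique row identifiers (probe sets or probes) and
        unique column identifiers (samples).
    scale
        ``"log2"`` for log2 expression values (must be finite) or ``"raw"``
        for linear-scale intensities (must be strictly positive for
        background correction).
    """

    data: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise FormatError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique()[:5]
            raise FormatError(f"duplicate row identifiers: {list(dups)}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique()[:5]
            raise FormatError(f"duplicate column identifiers: {list(dups)}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric cells")
        if values.size and np.isnan(values).any():
            raise FormatError("expression matrix contains missing values")
        if self.scale == "log2" and values.size and not np.isfinite(values).all():
            raise FormatError("log2 expression matrix contains non-finite values")

    @property
    def row_ids(self) -> pd.Index:
        return self.data.index

    @property
    def col_ids(self) -> pd.Index:
        return self.data.columns

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_rows(self, ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[ids], scale=self.scale)

    def log2(self) -> "ExpressionMatrix":
        """Return a log2-scale copy (no-op if already log2)."""
        if self.scale == "log2":
            return self
        vals = self.data.to_numpy(dtype=float)
        if (vals <= 0).any():
            raise FormatError("cannot log2-transform non-positive intensities")
        return ExpressionMatrix(
            pd.DataFrame(np.log2(vals), index=self.data.index, columns=self.data.columns),
            scale="log2",
        )


@dataclass
class SampleDesign:
    """Maps each sample to one of the five treatment groups A-E.

    The derived factors (``time_class``, ``dose_gy``) are functions of the
    group label; they are materialized so design tables written to disk are
    self-describing.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if "group" not in self.table.columns:
            raise DesignError("design table must have a 'group' column")
        bad = set(self.table["group"]) - set(GROUPS)
        if bad:
            raise DesignError(f"unknown group labels: {sorted(bad)}")
        if self.table.index.has_duplicates:
            raise DesignError("duplicate sample identifiers in design")
        self.table = self.table.copy()
        self.table["time_class"] = self.table["group"].map(GROUP_TIME_CLASS)
        self.table["dose_gy"] = self.table["group"].map(GROUP_DOSE_GY)

    @classmethod
    def from_groups(cls, sample_to_group: dict[str, str]) -> "SampleDesign":
        tbl = pd.DataFrame({"group": pd.Series(sample_to_group)})
        tbl.index.name = "sample"
        return cls(tbl)

    @property
    def samples(self) -> pd.Index:
        return self.table.index

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    def groups_present(self) -> list[str]:
        present = set(self.table["group"])
        return [g for g in GROUPS if g in present]

    def samples_in(self, *groups: str) -> list[str]:
        mask = self.table["group"].isin(groups)
        return list(self.table.index[mask])

    def require_groups(self, *groups: str) -> None:
        for g in groups:
            if not (self.table["group"] == g).any():
                raise DesignError(f"group {g!r} has no samples")

    def align_to(self, matrix: ExpressionMatrix) -> "SampleDesign":
        """Restrict and order the design to the matrix columns."""
        missing = [c for c in matrix.col_ids if c not in self.table.index]
        if missing:
            raise DesignError(f"samples missing from design: {missing[:5]}")
        return SampleDesign(self.table.loc[matrix.col_ids, ["group"]])
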