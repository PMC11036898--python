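"""Core data containers shared across the pipeline.

The central object is :class:`CountTable`, a sample x ASV matrix of
non-negative integer read counts backed by a :class:`pandas.DataFrame`.
Sample metadata travels as a plain DataFrame indexed by sample id and is
validated by :func:`validate_metadata`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CountTable", "validate_metadata", "GROUP_CASE", "GROUP_CONTROL"]

GROUP_CASE = "EIM"
GROUP_CONTROL = "C"

#: metadata columns every table must carry
_REQUIRED_META = ("is_negative_control",)


@dataclass
class CountTable:
    """Sample x ASV matrix of non-negative integer counts.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows are samples, columns are ASVs.  Entries must be
        non-negative and integer-valued (any integer or float dtype that
        holds whole numbers is accepted and cast to int64).
    """

    data: pd.DataFrame = field()

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        if df.columns.has_duplicates:
            dupes = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate ASV ids: {dupes}")
        values = df.to_numpy()
        if values.size:
            if np.any(values < 0):
                i, j = np.argwhere(values < 0)[0]
                raise ValueError(
                    f"negative count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
                )
            if not np.allclose(values, np.round(values)):
                i, j = np.argwhere(~np.isclose(values, np.round(values)))[0]
                raise ValueError(
                    f"non-integer count at sample {df.index[i]!r}, ASV {df.columns[j]!r}"
                )
        self.data = df.astype(np.int64)

    # -- identifiers ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    # -- derived quantities --------------------------------------------
    def depths(self) -> pd.Series:
        """Total reads per sample (library size)."""
        return self.data.sum(axis=1)

    def relative_abundance(self) -> pd.DataFrame:
        """Row-normalised fractions; raises on zero-depth samples."""
        totals = self.depths()
        zero = totals[totals == 0]
        if len(zero):
            raise ValueError(f"zero-depth sample(s): {list(zero.index)}")
        return self.data.div(totals, axis=0)

    def select_samples(self, ids) -> "CountTable":
        return CountTable(self.data.loc[list(ids)])

    def select_asvs(self, ids) -> "CountTable":
        return CountTable(self.data.loc[:, list(ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.data.equals(other.data)


def validate_metadata(meta: pd.DataFrame, counts: CountTable | None = None) -> pd.DataFrame:
    """Validate a sample-metadata frame.

    Biological samples must carry ``group`` (EIM / C) and ``subtype``
    (CD / UC); negative controls carry neither.  When ``counts`` is
    given the metadata index must cover all of its samples.
    """
    if "is_negative_control" not in meta.columns:
        meta = meta.copy()
        meta["is_negative_control"] = False
    if meta.index.has_duplicates:
        raise ValueError("duplicate sample ids in metadata")
    meta = meta.copy()
    meta["is_negative_control"] = meta["is_negative_control"].astype(bool)
    bio = meta.loc[~meta["is_negative_control"]]
    if len(bio):
        for col in ("group", "subtype"):
            if col not in meta.columns:
                raise ValueError(f"metadata missing required column {col!r}")
            if bio[col].isna().any():
                bad = bio.index[bio[col].isna()].tolist()
                raise ValueError(f"biological sample(s) missing {col!r}: {bad}")
        bad_groups = set(bio["group"].unique()) - {GROUP_CASE, GROUP_CONTROL}
        if bad_groups:
            raise ValueError(f"unknown group label(s): {sorted(bad_groups)}")
    if counts is not None:
        missing = set(counts.sample_ids) - set(meta.index)
        if missing:
            raise ValueError(f"samples absent from metadata: {sorted(missing)}")
    return meta
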