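"""Core in-memory containers shared across the package.

All three are thin, validated wrappers around pandas objects: an
``ExpressionMatrix`` (genes x samples, log-scale), a ``ClinicalTable``
(per-sample covariates) and an ``OrderedLabeling`` (assignment of samples
to K ordered levels such as pathologic stage or risk-of-death quartile).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import (
    DomainError,
    DuplicateIdentifierError,
    EmptyInputError,
    NonNumericValueError,
)

#: AJCC early-stage codes in their clinical order.
STAGE_ORDER: tuple[str, ...] = ("IA", "IB", "IIA", "IIB")

#: Mandatory clinical columns.
CLINICAL_COLUMNS: tuple[str, ...] = (
    "sample_id",
    "subtype",
    "stage",
    "os_time",
    "event",
    "age",
)


@dataclass
class ExpressionMatrix:
    """A gene-by-sample grid of log-scale expression values.

    Parameters
    ----------
    data
        DataFrame with gene identifiers as the index and sample identifiers
        as the columns. Values must all be finite floats; there is no
        missing-data rule downstream, so missing values are rejected here.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        # a gene-less matrix is a legal (empty) scan input; a sample-less one is not
        if self.data.shape[1] == 0:
            raise EmptyInputError("expression matrix has no samples")
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate gene identifiers: {dups}")
        if self.data.columns.duplicated().any():
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIdentifierError(f"duplicate sample identifiers: {dups}")
        values = self.data.to_numpy()
        if values.size:
            if not np.issubdtype(values.dtype, np.number):
                raise NonNumericValueError("expression matrix contains non-numeric cells")
            if not np.isfinite(values.astype(float)).all():
                raise NonNumericValueError(
                    "expression matrix contains NaN/inf cells (no imputation is performed)"
                )
        self.data = self.data.astype(float)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)])


@dataclass
class ClinicalTable:
    """Per-sample clinical covariates.

    Columns: ``sample_id`` (unique), ``subtype`` (AC/SCC), ``stage`` (one of
    IA/IB/IIA/IIB or missing), ``os_time`` (overall-survival time, > 0, any
    consistent unit -- only the ordering is used downstream), ``event``
    (1 = death observed, 0 = censored), ``age`` (years, > 0).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CLINICAL_COLUMNS if c not in self.data.columns]
        if missing:
            raise DomainError(f"clinical table missing mandatory columns: {missing}")
        if len(self.data) == 0:
            raise EmptyInputError("clinical table has no rows")
        df = self.data.copy()
        if df["sample_id"].duplicated().any():
            dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DuplicateIdentifierError(f"duplicate sample identifiers: {dups}")
        stages = df["stage"].dropna()
        bad = set(stages) - set(STAGE_ORDER)
        if bad:
            raise DomainError(
                f"unknown stage codes {sorted(bad)}; expected one of {STAGE_ORDER}"
            )
        times = pd.to_numeric(df["os_time"], errors="coerce")
        if ((times <= 0) & df["os_time"].notna()).any() or (
            times.isna() & df["os_time"].notna()
        ).any():
            raise DomainError("os_time must be a positive number where present")
        events = df["event"].dropna()
        if not set(pd.to_numeric(events, errors="coerce").dropna()) <= {0, 1} or (
            pd.to_numeric(events, errors="coerce").isna() & df["event"].notna()
        ).any():
            raise DomainError("event must be 0 (censored) or 1 (died)")
        ages = pd.to_numeric(df["age"], errors="coerce")
        if ((ages <= 0) & df["age"].notna()).any():
            raise DomainError("age must be positive where present")
        df["os_time"] = times
        df["event"] = pd.to_numeric(df["event"], errors="coerce").astype("Int64")
        df["age"] = ages
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, sample_ids: list[str]) -> "ClinicalTable":
        order = {s: i for i, s in enumerate(sample_ids)}
        sel = self.data[self.data["sample_id"].isin(order)].copy()
        sel = sel.sort_values("sample_id", key=lambda s: s.map(order))
        return ClinicalTable(sel.reset_index(drop=True))


@dataclass
class OrderedLabeling:
    """Assignment of samples to K ordered levels.

    ``assignment`` maps sample_id -> level index in 1..K; ``level_names``
    gives the K level labels in their fixed order (index 1 first).
    """

    level_names: tuple[str, ...]
    assignment: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        self.level_names = tuple(self.level_names)
        k = len(self.level_names)
        if k < 2:
            raise DomainError(f"an ordered labeling needs K >= 2 levels, got K={k}")
        vals = np.asarray(self.assignment, dtype=int)
        if len(vals) == 0:
            raise EmptyInputError("labeling assigns no samples")
        if vals.min() < 1 or vals.max() > k:
            raise DomainError("level indices must lie in 1..K")
        counts = np.bincount(vals, minlength=k + 1)[1:]
        if (counts == 0).any():
            empty = [self.level_names[i] for i in np.nonzero(counts == 0)[0]]
            raise DomainError(f"empty levels are not allowed: {empty}")
        if self.assignment.index.duplicated().any():
            raise DuplicateIdentifierError("labeling contains duplicate sample ids")
        self.assignment = pd.Series(vals, index=self.assignment.index)

    @property
    def K(self) -> int:
        return len(self.level_names)

    @property
    def n_k(self) -> tuple[int, ...]:
        vals = self.assignment.to_numpy()
        return tuple(int((vals == i).sum()) for i in range(1, self.K + 1))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.assignment.index)

    def levels_for(self, sample_ids: list[str]) -> np.ndarray:
        """Level indices (1..K) for the given samples, in the given order."""
        missing = [s for s in sample_ids if s not in self.assignment.index]
        if missing:
            raise DomainError(f"samples without a level assignment: {missing[:5]}")
        return self.assignment.loc[list(sample_ids)].to_numpy(dtype=int)

    def reversed(self) -> "OrderedLabeling":
        """The same grouping with the level order flipped."""
        k = self.K
        return OrderedLabeling(
            level_names=tuple(reversed(self.level_names)),
            assignment=(k + 1) - self.assignment,
        )
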