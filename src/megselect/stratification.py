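"""Ordered patient groupings: pathologic stage, risk-of-death, age quartiles.

Risk levels of death follow the quartile construction used for early-stage
NSCLC cohorts: among uncensored patients, the first quartile, the median and
the third quartile of overall-survival time cut the cohort into four ordered
strata -- extremely high risk (shortest-surviving quarter), high, moderate
and low risk. Age groups use the same quartile machinery. Stage groups use
the AJCC early-stage order IA < IB < IIA < IIB, dropping empty stages (a
cohort can legitimately contain zero patients of one stage).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import STAGE_ORDER, ClinicalTable, OrderedLabeling
from .exceptions import DomainError, EmptyInputError

logger = logging.getLogger(__name__)

RISK_LEVEL_NAMES: tuple[str, ...] = (
    "extremely-high-risk",
    "high-risk",
    "moderate-risk",
    "low-risk",
)


def filter_patients(
    clin: ClinicalTable,
    require_uncensored: bool = False,
    subtypes: set[str] | None = None,
    stages: set[str] | None = None,
) -> ClinicalTable:
    """Apply the cohort inclusion rules and log how many rows each removes.

    ``require_uncensored`` keeps only patients whose death was observed
    (event == 1), so that survival-quartile membership is unambiguous.
    ``subtypes``/``stages`` restrict to the given categories when provided.
    """
    df = clin.data
    removed: dict[str, int] = {}
    if require_uncensored:
        keep = df["event"] == 1
        removed["censored"] = int((~keep).sum())
        df = df[keep]
    if subtypes is not None:
        keep = df["subtype"].isin(set(subtypes))
        removed["subtype"] = int((~keep).sum())
        df = df[keep]
    if stages is not None:
        bad = set(stages) - set(STAGE_ORDER)
        if bad:
            raise DomainError(f"unknown stage codes in filter: {sorted(bad)}")
        keep = df["stage"].isin(set(stages))
        removed["stage"] = int((~keep).sum())
        df = df[keep]
    for criterion, n in removed.items():
        if n:
            logger.info("filter_patients: removed %d patients by %s", n, criterion)
    if len(df) == 0:
        raise EmptyInputError("no patients survive the active filters")
    return ClinicalTable(df.reset_index(drop=True))


def assign_stage_groups(clin: ClinicalTable) -> OrderedLabeling:
    """Label samples by pathologic stage, ordered IA < IB < IIA < IIB.

    Stages with zero patients are dropped (with a warning) and K shrinks
    accordingly; fewer than two non-empty stages is an error.
    """
    df = clin.data
    if df["stage"].isna().any():
        missing = df.loc[df["stage"].isna(), "sample_id"].tolist()
        raise DomainError(f"samples without a stage: {missing[:5]}")
    present = [s for s in STAGE_ORDER if (df["stage"] == s).any()]
    dropped = [s for s in STAGE_ORDER if s not in present]
    if dropped:
        logger.warning("assign_stage_groups: dropping empty stage levels %s", dropped)
    if len(present) < 2:
        raise DomainError(
            f"need at least 2 non-empty stage levels, got {len(present)} ({present})"
        )
    index = {s: i + 1 for i, s in enumerate(present)}
    assignment = pd.Series(
        df["stage"].map(index).to_numpy(dtype=int),
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    return OrderedLabeling(level_names=tuple(present), assignment=assignment)


def assign_quartile_groups(
    values: pd.Series,
    reverse: bool = False,
    level_names: tuple[str, ...] | None = None,
) -> OrderedLabeling:
    """Four ordered groups cut at the first quartile, median and third quartile.

    Cutoffs are the empirical (type-7, linearly interpolated) quartiles of
    ``values``. With ``reverse=False`` level 1 is the lowest-value quartile
    (value <= Q1 -> 1, <= median -> 2, <= Q3 -> 3, else 4); samples tied at
    a cutoff always land in the same group, so the split is deterministic,
    and with n distinct values the group sizes differ by at most 1 (the
    remainder going to the lower groups). ``reverse=True`` flips the level
    order (level 1 = highest values). Only the ranks of ``values`` matter.
    """
    if not isinstance(values, pd.Series):
        values = pd.Series(np.asarray(values, dtype=float))
    if values.isna().any():
        missing = values.index[values.isna()].tolist()
        raise DomainError(f"samples with a missing value: {missing[:5]}")
    x = values.to_numpy(dtype=float)
    if np.unique(x).size < 4:
        raise DomainError(
            f"need at least 4 distinct values for quartile groups, got {np.unique(x).size}"
        )
    # "value <= interpolated quartile" in exact arithmetic reduces to a
    # comparison against the order statistic at floor(1 + (n-1)p): the
    # interpolated cutoff lies strictly between adjacent distinct values, so
    # comparing against the lower one is equivalent and immune to the
    # floating-point rounding of the interpolation itself.
    n = x.size
    xs = np.sort(x)
    c1, med, c3 = xs[[(n - 1) // 4, (n - 1) // 2, (3 * (n - 1)) // 4]]
    level = 1 + (x > c1).astype(int) + (x > med) + (x > c3)
    if reverse:
        level = 5 - level
    names = level_names if level_names is not None else ("Q1", "Q2", "Q3", "Q4")
    if len(names) != 4:
        raise DomainError("quartile groups need exactly 4 level names")
    # heavy ties can leave an inter-quartile band empty; drop it and renumber
    present = np.unique(level)
    if len(present) < 4:
        dropped = [names[i - 1] for i in range(1, 5) if i not in present]
        logger.warning("assign_quartile_groups: dropping empty levels %s", dropped)
        if len(present) < 2:
            raise DomainError("fewer than 2 non-empty quartile levels")
        remap = {old: new + 1 for new, old in enumerate(present)}
        level = np.vectorize(remap.get)(level)
        names = tuple(names[i - 1] for i in present)
    assignment = pd.Series(level, index=values.index)
    return OrderedLabeling(level_names=tuple(names), assignment=assignment)


def assign_risk_groups(clin: ClinicalTable) -> OrderedLabeling:
    """Risk-of-death levels from overall-survival quartiles.

    Level 1 = extremely high risk (shortest-surviving quarter) ... level 4 =
    low risk (longest). Requires every patient to have a survival time; the
    caller is expected to have excluded censored patients first, otherwise
    quartile membership would be ambiguous.
    """
    df = clin.data
    times = pd.Series(
        df["os_time"].to_numpy(dtype=float),
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    return assign_quartile_groups(times, reverse=False, level_names=RISK_LEVEL_NAMES)


def assign_age_groups(clin: ClinicalTable) -> OrderedLabeling:
    """Age quartile levels, youngest quarter first."""
    df = clin.data
    if df["age"].isna().any():
        missing = df.loc[df["age"].isna(), "sample_id"].tolist()
        raise DomainError(f"samples without an age: {missing[:5]}")
    ages = pd.Series(
        df["age"].to_numpy(dtype=float),
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    return assign_quartile_groups(
        ages, reverse=False, level_names=("age-Q1", "age-Q2", "age-Q3", "age-Q4")
    )
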