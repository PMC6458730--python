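"""Downstream association checks.

Three questions follow a scan: how much do the significant gene sets of
different categories overlap; does a sample's risk-of-death level track its
pathologic stage (Spearman rank correlation on the two ordinal labelings);
and do the survival curves of the stages actually differ (Kaplan-Meier
estimates with a multi-group log-rank test). Kaplan-Meier fitting and the
log-rank statistic are delegated to lifelines.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .exceptions import DomainError

__all__ = [
    "OverlapSummary",
    "SurvivalComparison",
    "overlap_summary",
    "spearman_ordinal",
    "logrank_km",
]


@dataclass
class OverlapSummary:
    """Exact membership counts for every intersection region of 2-4 gene sets.

    ``region_counts`` maps a tuple of set names (the sets a region belongs to,
    and no others) to the number of genes in that region; all 2^m - 1 regions
    are present, empty ones with count 0. Each gene of the union appears in
    exactly one region (``membership``).
    """

    set_names: tuple[str, ...]
    region_counts: dict[tuple[str, ...], int]
    membership: dict[str, tuple[str, ...]] = field(repr=False)

    @property
    def union_size(self) -> int:
        return len(self.membership)

    def count(self, *names: str) -> int:
        """Count of the exclusive region belonging to exactly ``names``."""
        key = tuple(n for n in self.set_names if n in names)
        if len(key) != len(names):
            raise DomainError(f"unknown set names in {names}")
        return self.region_counts[key]

    def to_json_dict(self) -> dict:
        return {
            "set_names": list(self.set_names),
            "union_size": self.union_size,
            "regions": {"&".join(k): v for k, v in self.region_counts.items()},
        }


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group plus the multi-group log-rank test."""

    group_names: tuple[str, ...]
    km_curves: dict[str, pd.DataFrame] = field(repr=False)  # time, survival, at_risk
    chi_square: float = float("nan")
    p_value: float = float("nan")
    degrees_of_freedom: int = 0
    spearman_rho: float | None = None
    spearman_p: float | None = None

    def to_json_dict(self) -> dict:
        out = {
            "groups": list(self.group_names),
            "logrank_chi_square": self.chi_square,
            "logrank_p_value": self.p_value,
            "degrees_of_freedom": self.degrees_of_freedom,
        }
        if self.spearman_rho is not None:
            out["spearman_rho"] = self.spearman_rho
            out["spearman_p"] = self.spearman_p
        return out


def overlap_summary(sets: dict[str, set]) -> OverlapSummary:
    """Venn-style region counts and per-gene region assignment for 2-4 sets."""
    names = tuple(sets)
    if not 2 <= len(names) <= 4:
        raise DomainError(f"overlap summary needs 2-4 sets, got {len(names)}")
    as_sets = {n: set(sets[n]) for n in names}
    membership: dict[str, tuple[str, ...]] = {}
    union = set().union(*as_sets.values())
    for gene in union:
        membership[gene] = tuple(n for n in names if gene in as_sets[n])
    region_counts: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            region_counts[combo] = 0
    for region in membership.values():
        region_counts[region] += 1
    return OverlapSummary(set_names=names, region_counts=region_counts,
                          membership=membership)


def spearman_ordinal(x, y, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation between two ordinal labelings.

    Ties are handled by midranks. The two-sided p-value uses the
    t-approximation (adequate for the cohort sizes this package targets);
    ``exact=True`` instead estimates it by 10,000 seeded label permutations.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise DomainError("x and y must be equal-length 1-D label vectors")
    if xa.size < 3:
        raise DomainError("need at least 3 paired labels")
    if np.unique(xa).size < 2 or np.unique(ya).size < 2:
        raise DomainError("correlation is undefined for a constant labeling")
    res = stats.spearmanr(xa, ya)
    rho = float(res.statistic)
    if not exact:
        return rho, float(res.pvalue)
    rng = np.random.default_rng(0)
    n_perm = 10_000
    count = 0
    for _ in range(n_perm):
        perm_rho = stats.spearmanr(xa, rng.permutation(ya)).statistic
        if abs(perm_rho) >= abs(rho) - 1e-12:
            count += 1
    return rho, (1 + count) / (n_perm + 1)


def logrank_km(times, events, groups) -> SurvivalComparison:
    """Kaplan-Meier curves per group and the unweighted multi-group log-rank test.

    ``times`` are positive survival times, ``events`` binary flags (1 = death
    observed), ``groups`` the group label of each sample. Censored samples
    contribute to the risk sets only. Requires at least two groups and at
    least one observed event.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    if not (t.shape == e.shape == g.shape) or t.ndim != 1:
        raise DomainError("times, events and groups must be equal-length vectors")
    if (t <= 0).any():
        raise DomainError("survival times must be positive")
    if not set(np.unique(e)) <= {0, 1}:
        raise DomainError("event flags must be 0 or 1")
    names = tuple(pd.unique(g))
    if len(names) < 2:
        raise DomainError("log-rank comparison needs at least 2 groups")
    if e.sum() == 0:
        raise DomainError("log-rank comparison needs at least one observed event")
    curves: dict[str, pd.DataFrame] = {}
    for name in names:
        mask = g == name
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], e[mask], label=str(name))
        at_risk = kmf.event_table["at_risk"]
        surv = kmf.survival_function_.iloc[:, 0]
        curves[str(name)] = pd.DataFrame(
            {
                "time": surv.index.to_numpy(dtype=float),
                "survival": surv.to_numpy(dtype=float),
                "at_risk": at_risk.reindex(surv.index).to_numpy(dtype=float),
            }
        ).reset_index(drop=True)
    test = multivariate_logrank_test(t, g, e)
    return SurvivalComparison(
        group_names=tuple(str(n) for n in names),
        km_curves=curves,
        chi_square=float(test.test_statistic),
        p_value=float(test.p_value),
        degrees_of_freedom=len(names) - 1,
    )
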