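"""Monotone feature selection via the total discriminating error (DE_total).

For a gene measured on samples falling into K ordered levels, the statistic
asks how well a single expression threshold ("discriminating line") separates
the samples at levels 1..k from those at levels k+1..K, for each of the K-1
splits. Candidate thresholds are the expression values of the lower-block
samples; the error of a threshold t is

    #(lower-block values > t) + #(upper-block values <= t)

and each split contributes its minimal achievable error e_k. DE_total is the
sum of the K-1 split errors: 0 for a perfectly monotonically increasing gene,
large for a gene with no trend. A descending scan is the same computation on
the negated values. Because only the ordering of values enters, the score is
invariant under any strictly increasing transformation and makes no
distributional assumption.

Significance is assessed by permutation: level labels are shuffled across
samples B times (the same B permutations for every gene), and the p-value is
the add-one estimator (1 + #{permuted DE_total <= observed}) / (B + 1). The
smallest attainable p is therefore 1/(B+1); B must be chosen with the
multiple-testing burden in mind (see docs). q-values are Benjamini-Hochberg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, OrderedLabeling
from .exceptions import DomainError

DIRECTIONS = ("ascending", "descending")


def _check_direction(direction: str) -> None:
    if direction not in DIRECTIONS:
        raise DomainError(f"direction must be one of {DIRECTIONS}, got {direction!r}")


@dataclass(frozen=True)
class SplitResult:
    """Best discriminating line for one of the K-1 level splits."""

    split_index: int  # k in 1..K-1: lower block = levels <= k
    threshold: float  # chosen line (an expression value of a lower-block sample)
    errors_lower: int  # lower-block samples on the wrong side (> t for ascending)
    errors_upper: int  # upper-block samples on the wrong side (<= t for ascending)

    @property
    def e_k(self) -> int:
        return self.errors_lower + self.errors_upper


@dataclass
class DEScore:
    """Per-split discriminating errors and their sum for one gene/direction."""

    gene_id: str
    direction: str
    splits: list[SplitResult]

    @property
    def de_total(self) -> int:
        return int(sum(s.e_k for s in self.splits))


@dataclass
class MEGResults:
    """Ranked per-gene scan results for one direction.

    ``table`` has one row per gene with columns gene, direction, de_total,
    p_value, q_value, significant; ``metadata`` records K, n_k, B, seed and
    alpha so a run can be reproduced exactly.
    """

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> list[str]:
        return self.table.loc[self.table["significant"], "gene"].tolist()

    def n_significant(self, alpha: float) -> int:
        return int((self.table["q_value"] < alpha).sum())


# ---------------------------------------------------------------------------
# single-split / single-gene reference path
# ---------------------------------------------------------------------------


def discriminating_error(
    values_lower: np.ndarray,
    values_upper: np.ndarray,
    direction: str = "ascending",
    split_index: int = 1,
) -> SplitResult:
    """Best single-threshold separation of a lower block from an upper block.

    Ascending: candidate thresholds are the distinct lower-block values; a
    lower-block sample is misclassified iff its value exceeds the line, an
    upper-block sample iff its value is at or below it. Ties among minimal-
    error candidates resolve to the smallest threshold. Descending is the
    ascending rule on negated values, with the line mapped back to the
    original scale.
    """
    _check_direction(direction)
    lower = np.asarray(values_lower, dtype=float)
    upper = np.asarray(values_upper, dtype=float)
    if lower.size == 0 or upper.size == 0:
        raise DomainError("both the lower and the upper block must be non-empty")
    if direction == "descending":
        res = discriminating_error(-lower, -upper, "ascending", split_index)
        return SplitResult(
            split_index=split_index,
            threshold=-res.threshold,
            errors_lower=res.errors_lower,
            errors_upper=res.errors_upper,
        )
    cands = np.unique(lower)  # sorted ascending
    lower_sorted = np.sort(lower)
    upper_sorted = np.sort(upper)
    e_low = lower.size - np.searchsorted(lower_sorted, cands, side="right")
    e_up = np.searchsorted(upper_sorted, cands, side="right")
    best = int(np.argmin(e_low + e_up))  # argmin takes the smallest threshold on ties
    return SplitResult(
        split_index=split_index,
        threshold=float(cands[best]),
        errors_lower=int(e_low[best]),
        errors_upper=int(e_up[best]),
    )


def de_total(
    gene_values,
    labeling: OrderedLabeling,
    direction: str = "ascending",
    gene_id: str = "",
) -> DEScore:
    """DE_total for one gene: sum of the K-1 split errors.

    ``gene_values`` is a pandas Series indexed by sample_id (every labeled
    sample must have a value) or an array aligned with the labeling's
    sample order.
    """
    _check_direction(direction)
    if isinstance(gene_values, pd.Series):
        missing = [s for s in labeling.sample_ids if s not in gene_values.index]
        if missing:
            raise DomainError(f"labeled samples without an expression value: {missing[:5]}")
        values = gene_values.loc[labeling.sample_ids].to_numpy(dtype=float)
    else:
        values = np.asarray(gene_values, dtype=float)
        if values.shape[0] != len(labeling.sample_ids):
            raise DomainError(
                f"got {values.shape[0]} values for {len(labeling.sample_ids)} labeled samples"
            )
    if not np.isfinite(values).all():
        raise DomainError("gene values must be finite for every labeled sample")
    levels = labeling.levels_for(labeling.sample_ids)
    splits = [
        discriminating_error(
            values[levels <= k], values[levels > k], direction, split_index=k
        )
        for k in range(1, labeling.K)
    ]
    return DEScore(gene_id=gene_id, direction=direction, splits=splits)


# ---------------------------------------------------------------------------
# vectorised whole-matrix path
# ---------------------------------------------------------------------------


class _PresortedMatrix:
    """Per-gene sort structure allowing O(N) split scoring per permutation.

    Sorting each gene's values once makes the per-permutation work a few
    cumulative sums: with values in sorted order and z_j = 1 when the j-th
    smallest sample lies in the lower block, the error of the line at sorted
    position j (evaluated at the right edge of its tie run, so that equal
    values share one candidate) is

        n_lower - #lower(<= j') + #upper(<= j'),   j' = last index of j's tie run,

    and the split error is the minimum over positions with z_j = 1.
    """

    def __init__(self, values: np.ndarray):
        x = np.asarray(values, dtype=float)
        if x.ndim != 2:
            raise DomainError("expected a genes x samples matrix")
        self.n_genes, self.n_samples = x.shape
        self.order = np.argsort(x, axis=1, kind="stable")
        xs = np.take_along_axis(x, self.order, axis=1)
        n = self.n_samples
        is_last = np.empty((self.n_genes, n), dtype=bool)
        is_last[:, -1] = True
        if n > 1:
            is_last[:, :-1] = xs[:, :-1] != xs[:, 1:]
        pos = np.where(is_last, np.arange(n), n)
        # last index of each tie run, per position
        self.tie_end = np.minimum.accumulate(pos[:, ::-1], axis=1)[:, ::-1]

    def de_totals(self, levels: np.ndarray, out: np.ndarray | None = None) -> np.ndarray:
        """DE_total of every gene for one level assignment (ascending scan)."""
        k_max = int(levels.max())
        lv = levels[self.order]  # (G, N) levels in per-gene sorted-value order
        total = np.zeros(self.n_genes, dtype=np.int64) if out is None else out
        total[:] = 0
        big = self.n_samples + 1
        for k in range(1, k_max):
            z = lv <= k
            n_lower = int((levels <= k).sum())
            csum = np.cumsum(z, axis=1)
            c_end = np.take_along_axis(csum, self.tie_end, axis=1)
            # errors = n_lower - #lower<=t + #upper<=t, at each tie-run end
            err = n_lower - 2 * c_end + (self.tie_end + 1)
            err[~z] = big  # only lower-block values are candidate lines
            total += err.min(axis=1)
        return total


def _scan_matrix(
    values: np.ndarray,
    levels: np.ndarray,
    direction: str,
    B: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Observed DE_total and permutation p-values for every gene (one direction)."""
    x = values if direction == "ascending" else -values
    pre = _PresortedMatrix(x)
    observed = pre.de_totals(levels).copy()
    rng = np.random.default_rng(seed)
    counts = np.zeros(pre.n_genes, dtype=np.int64)
    scratch = np.empty(pre.n_genes, dtype=np.int64)
    for _ in range(B):
        perm = rng.permutation(levels)
        counts += pre.de_totals(perm, out=scratch) <= observed
    pvals = (1.0 + counts) / (B + 1.0)
    return observed, pvals


def permutation_pvalues(
    expr: ExpressionMatrix,
    labeling: OrderedLabeling,
    direction: str = "ascending",
    B: int = 1000,
    seed: int | None = None,
) -> pd.Series:
    """Permutation p-values of DE_total for every gene.

    The same B random relabelings (level labels shuffled across samples,
    level sizes preserved) are applied to all genes, and the add-one
    estimator p = (1 + #{permuted <= observed}) / (B + 1) is returned, so
    p in (0, 1] and min p = 1/(B+1). ``seed`` is mandatory: runs must be
    reproducible.
    """
    _check_direction(direction)
    if B < 1:
        raise DomainError(f"permutation count B must be >= 1, got {B}")
    if seed is None:
        raise DomainError("an explicit permutation seed is required")
    levels = labeling.levels_for(expr.sample_ids)
    _, pvals = _scan_matrix(expr.values, levels, direction, B, seed)
    return pd.Series(pvals, index=expr.gene_ids, name="p_value")


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, returned in input order.

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any() or np.isnan(p).any():
        raise DomainError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_megs(
    expr: ExpressionMatrix,
    labeling: OrderedLabeling,
    direction: str = "ascending",
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> MEGResults:
    """Full scan for one direction: DE_total, permutation p, BH q, calls.

    A gene is called significant when its q-value is below ``alpha``
    (0.05 by default; 0.1 is the conventional relaxed threshold).
    """
    _check_direction(direction)
    if not 0 < alpha < 1:
        raise DomainError(f"alpha must lie in (0, 1), got {alpha}")
    if B < 1:
        raise DomainError(f"permutation count B must be >= 1, got {B}")
    if seed is None:
        raise DomainError("an explicit permutation seed is required")
    levels = labeling.levels_for(expr.sample_ids)
    observed, pvals = _scan_matrix(expr.values, levels, direction, B, seed)
    qvals = bh_qvalues(pvals)
    table = pd.DataFrame(
        {
            "gene": expr.gene_ids,
            "direction": direction,
            "de_total": observed.astype(int),
            "p_value": pvals,
            "q_value": qvals,
            "significant": qvals < alpha,
        }
    )
    metadata = {
        "K": labeling.K,
        "n_k": list(labeling.n_k),
        "level_names": list(labeling.level_names),
        "B": B,
        "seed": seed,
        "alpha": alpha,
        "direction": direction,
        "n_genes": len(expr.gene_ids),
    }
    return MEGResults(table=table, metadata=metadata)
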