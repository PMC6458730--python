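"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from megselect.containers import OrderedLabeling
from megselect.synthetic import FIXTURE_CONFIGS, generate_dataset


def brute_force_de_total(values: np.ndarray, levels: np.ndarray) -> int:
    """Independent oracle: enumerate every candidate line at every split.

    Candidate thresholds for split k are the distinct values of the samples
    at levels <= k; the error of a line t is #(lower > t) + #(upper <= t).
    Plain python loops throughout -- shares no code with the scan path.
    """
    total = 0
    for k in range(1, int(max(levels))):
        lower = [v for v, g in zip(values, levels) if g <= k]
        upper = [v for v, g in zip(values, levels) if g > k]
        best = None
        for t in set(lower):
            err = sum(1 for v in lower if v > t) + sum(1 for v in upper if v <= t)
            if best is None or err < best:
                best = err
        total += best
    return total


def two_group_logrank_oracle(times, events, groups):
    """Independent oracle: O-E-V tabulation of the two-group log-rank test.

    Walks the distinct event times, accumulating observed minus expected
    deaths in group 0 with the hypergeometric variance at each time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups))
    assert len(labels) == 2
    in0 = groups == labels[0]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & in0).sum()
        d = ((times == t) & (events == 1)).sum()
        d0 = ((times == t) & (events == 1) & in0).sum()
        o_minus_e += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e**2 / var
    return chi2


def make_labeling(levels, sample_ids=None) -> OrderedLabeling:
    """An OrderedLabeling from a plain level-index vector (1..K)."""
    levels = np.asarray(levels, dtype=int)
    if sample_ids is None:
        sample_ids = [f"s{i + 1}" for i in range(len(levels))]
    k = int(levels.max())
    return OrderedLabeling(
        tuple(f"L{i}" for i in range(1, k + 1)),
        pd.Series(levels, index=pd.Index(sample_ids, name="sample_id")),
    )


def random_instance(rng, with_ties=True):
    """A small random (values, levels) pair: K in 2..5, 2-6 samples/level."""
    k = int(rng.integers(2, 6))
    sizes = rng.integers(2, 7, size=k)
    levels = np.repeat(np.arange(1, k + 1), sizes)
    n = len(levels)
    if with_ties and rng.random() < 0.7:
        values = rng.integers(0, 6, size=n).astype(float)  # heavy ties
    else:
        values = rng.normal(size=n)
    return values, levels


@pytest.fixture(scope="session")
def ac_like_dataset():
    """73-sample AC-like synthetic cohort with 24+12 planted monotone genes."""
    return generate_dataset(FIXTURE_CONFIGS["ac_like"])


@pytest.fixture(scope="session")
def scc_like_dataset():
    """31-sample SCC-like synthetic cohort (shares one planted gene id with ac_like)."""
    return generate_dataset(FIXTURE_CONFIGS["scc_like"])


@pytest.fixture(scope="session")
def null_dataset():
    """Cohort with no planted signal."""
    return generate_dataset(FIXTURE_CONFIGS["null"])


@pytest.fixture()
def tiny_clinical_df():
    """A hand-written 10-patient clinical table (4 censored, mixed subtype)."""
    return pd.DataFrame(
        {
            "sample_id": [f"p{i}" for i in range(1, 11)],
            "subtype": ["AC"] * 6 + ["SCC"] * 4,
            "stage": ["IA", "IB", "IB", "IIA", "IIB", "IB", "IA", "IB", "IIB", "IB"],
            "os_time": [5.0, 12.0, 33.0, 48.0, 7.5, 60.0, 21.0, 14.0, 9.0, 40.0],
            "event": [1, 1, 0, 1, 1, 0, 1, 0, 1, 0],
            "age": [61.0, 70.2, 55.0, 66.1, 72.9, 58.4, 64.0, 69.5, 75.1, 62.2],
        }
    )
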