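"""Synthetic cohorts with known ground truth.

The generator emulates the data structure of an early-stage NSCLC expression
study: a log-scale gene-by-sample matrix over a cohort of a few dozen
patients, four ordered risk-of-death levels with roughly equal sizes, a
minority of genes whose per-level means shift monotonically (the planted
MEGs), survival times strictly ordered in distribution across risk levels,
pathologic stages with a configurable ordinal association to risk, and
configurable censoring.

Model
-----
* Null genes: iid Normal(baseline, noise_sd^2) across samples.
* Planted ascending gene, sample at risk level k (1..K):
  Normal(baseline + effect_step * noise_sd * (k - 1), noise_sd^2);
  descending genes are mirrored (mean falls with k).
* Survival: Exponential with mean survival_scale_base *
  survival_scale_factor^(k-1) for risk level k, so level 1 (extremely high
  risk) has the shortest times and quartile stratification of the realized
  times recovers the generating levels with high probability once adjacent
  scales are well separated.
* Stage: a Gaussian copula ties a latent stage score to the latent risk
  score with correlation ``stage_risk_rho`` (0 = independent), then the
  score is discretized to IA/IB/IIA/IIB by the configured marginal
  frequencies.
* Censoring: iid Bernoulli(censoring_fraction) on the event flag.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import STAGE_ORDER, ClinicalTable, ExpressionMatrix
from .exceptions import DomainError

#: Stage frequencies of the two cohorts the generator emulates by default:
#: 73 AC patients split 11/39/5/18 and 31 SCC patients split 6/18/0/7
#: over IA/IB/IIA/IIB.
AC_STAGE_COUNTS: tuple[int, ...] = (11, 39, 5, 18)
SCC_STAGE_COUNTS: tuple[int, ...] = (6, 18, 0, 7)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic cohort.

    Defaults mirror the AC-like study arm: 73 uncensored patients in four
    risk levels of sizes (19, 18, 18, 18), 2,000 genes of which 48 ascend
    and 26 descend with a per-level mean step of 1.0 noise SD.
    """

    n_genes: int = 2000
    group_sizes: tuple[int, ...] = (19, 18, 18, 18)
    n_ascending: int = 48
    n_descending: int = 26
    effect_step: float = 1.0  # per-level mean shift, in units of noise_sd
    noise_sd: float = 1.0
    baseline: float = 7.0  # log2-intensity-like location
    survival_scale_base: float = 6.0  # months; mean OS of the highest-risk level
    survival_scale_factor: float = 4.0  # ratio between adjacent level means
    censoring_fraction: float = 0.0
    stage_risk_rho: float = 0.0
    stage_probs: tuple[float, ...] | None = None  # None -> AC-like frequencies
    subtype: str = "AC"
    planted_offset: int = 0  # planted genes occupy a contiguous id block
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes < 0:
            raise DomainError("n_genes must be >= 0")
        if len(self.group_sizes) < 2 or any(n < 1 for n in self.group_sizes):
            raise DomainError("group_sizes needs >= 2 entries, all >= 1")
        if self.n_ascending < 0 or self.n_descending < 0:
            raise DomainError("planted gene counts must be >= 0")
        if self.planted_offset < 0:
            raise DomainError("planted_offset must be >= 0")
        if self.planted_offset + self.n_ascending + self.n_descending > self.n_genes:
            raise DomainError("planted genes exceed n_genes")
        if self.noise_sd <= 0:
            raise DomainError("noise_sd must be > 0")
        if not 0 <= self.censoring_fraction < 1:
            raise DomainError("censoring_fraction must lie in [0, 1)")
        if not -1 <= self.stage_risk_rho <= 1:
            raise DomainError("stage_risk_rho must lie in [-1, 1]")
        if self.survival_scale_base <= 0 or self.survival_scale_factor <= 1:
            raise DomainError("survival scales must be positive and strictly ordered")
        if self.stage_probs is not None:
            p = np.asarray(self.stage_probs, dtype=float)
            if len(p) != len(STAGE_ORDER) or (p < 0).any() or not np.isclose(p.sum(), 1):
                raise DomainError("stage_probs must be 4 non-negative values summing to 1")


@dataclass
class SyntheticTruth:
    """Ground truth of one generated cohort."""

    ascending_genes: tuple[str, ...]
    descending_genes: tuple[str, ...]
    effect_sizes: dict[str, float] = field(repr=False)  # per planted gene, in noise SDs
    risk_level: pd.Series = field(repr=False)  # sample_id -> generating level 1..K
    stage: pd.Series = field(repr=False)  # sample_id -> stage code

    @property
    def planted_genes(self) -> tuple[str, ...]:
        return self.ascending_genes + self.descending_genes

    def to_json_dict(self) -> dict:
        return {
            "ascending_genes": list(self.ascending_genes),
            "descending_genes": list(self.descending_genes),
            "effect_sizes": self.effect_sizes,
            "risk_level": {k: int(v) for k, v in self.risk_level.items()},
            "stage": dict(self.stage),
        }


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Draw one cohort: expression matrix, clinical table and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    sizes = np.asarray(config.group_sizes, dtype=int)
    k_levels = len(sizes)
    n = int(sizes.sum())
    width = max(3, len(str(n)))
    sample_ids = [f"{config.subtype}_s{i + 1:0{width}d}" for i in range(n)]

    # latent risk score -> fixed level sizes by rank blocks
    z_risk = rng.normal(size=n)
    order = np.argsort(z_risk, kind="stable")
    levels = np.empty(n, dtype=int)
    levels[order] = np.repeat(np.arange(1, k_levels + 1), sizes)

    # survival: exponential, mean strictly increasing with level
    scales = config.survival_scale_base * config.survival_scale_factor ** (
        np.arange(k_levels, dtype=float)
    )
    os_time = rng.exponential(scales[levels - 1])
    os_time = np.maximum(os_time, 1e-3)  # keep times strictly positive

    # stage via Gaussian copula against the latent risk score
    probs = (
        np.asarray(config.stage_probs, dtype=float)
        if config.stage_probs is not None
        else np.asarray(AC_STAGE_COUNTS, dtype=float) / sum(AC_STAGE_COUNTS)
    )
    rho = config.stage_risk_rho
    z_stage = rho * z_risk + np.sqrt(max(0.0, 1 - rho**2)) * rng.normal(size=n)
    cuts = stats.norm.ppf(np.cumsum(probs)[:-1])
    stage_idx = np.searchsorted(cuts, z_stage, side="left")
    stage = np.asarray(STAGE_ORDER)[stage_idx]

    event = (rng.random(n) >= config.censoring_fraction).astype(int)
    age = np.clip(rng.normal(65.0, 8.0, size=n), 35.0, 90.0)

    gene_width = max(4, len(str(config.n_genes)))
    gene_ids = [f"g{i + 1:0{gene_width}d}" for i in range(config.n_genes)]
    x = rng.normal(config.baseline, config.noise_sd, size=(config.n_genes, n))
    a0 = config.planted_offset
    a1 = a0 + config.n_ascending
    d1 = a1 + config.n_descending
    shift = config.effect_step * config.noise_sd * (levels - 1)  # (n,)
    x[a0:a1, :] += shift[None, :]
    x[a1:d1, :] += config.effect_step * config.noise_sd * (k_levels - levels)[None, :]

    expr = ExpressionMatrix(pd.DataFrame(x, index=gene_ids, columns=sample_ids))
    clin = ClinicalTable(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "subtype": config.subtype,
                "stage": stage,
                "os_time": os_time,
                "event": event,
                "age": age,
            }
        )
    )
    idx = pd.Index(sample_ids, name="sample_id")
    asc = tuple(gene_ids[a0:a1])
    desc = tuple(gene_ids[a1:d1])
    truth = SyntheticTruth(
        ascending_genes=asc,
        descending_genes=desc,
        effect_sizes={g: float(config.effect_step) for g in asc + desc},
        risk_level=pd.Series(levels, index=idx),
        stage=pd.Series(stage, index=idx),
    )
    return expr, clin, truth


#: Named fixture configurations used by the test suite. ``ac_like`` mirrors a
#: 73-patient adenocarcinoma arm, ``scc_like`` a 31-patient squamous arm
#: (whose planted block shares exactly one gene id with ``ac_like``), and
#: ``null`` contains no planted signal.
FIXTURE_CONFIGS: dict[str, SyntheticConfig] = {
    "ac_like": SyntheticConfig(
        n_genes=400, group_sizes=(19, 18, 18, 18),
        n_ascending=24, n_descending=12, planted_offset=0, seed=11,
    ),
    "scc_like": SyntheticConfig(
        n_genes=400, group_sizes=(8, 8, 7, 8),
        n_ascending=10, n_descending=6, planted_offset=35,
        stage_probs=tuple(np.asarray(SCC_STAGE_COUNTS) / sum(SCC_STAGE_COUNTS)),
        subtype="SCC", seed=12,
    ),
    "null": SyntheticConfig(
        n_genes=400, group_sizes=(19, 18, 18, 18),
        n_ascending=0, n_descending=0, seed=13,
    ),
}


def regenerate_fixture(name: str, outdir: str | Path) -> dict[str, Path]:
    """Write the named fixture (expression + clinical TSV, truth JSON).

    Output bytes are identical across runs: the configuration carries a
    fixed seed and floats are formatted with a fixed precision.
    """
    from .io_clinical import write_clinical_table, write_expression_matrix

    if name not in FIXTURE_CONFIGS:
        raise DomainError(f"unknown fixture {name!r}; known: {sorted(FIXTURE_CONFIGS)}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    expr, clin, truth = generate_dataset(FIXTURE_CONFIGS[name])
    paths = {
        "expression": outdir / f"{name}_expression.tsv",
        "clinical": outdir / f"{name}_clinical.tsv",
        "truth": outdir / f"{name}_truth.json",
    }
    write_expression_matrix(expr, paths["expression"])
    write_clinical_table(clin, paths["clinical"])
    paths["truth"].write_text(
        json.dumps(truth.to_json_dict(), indent=1, sort_keys=True) + "\n"
    )
    return paths


def config_with(base: SyntheticConfig, **overrides) -> SyntheticConfig:
    """A copy of ``base`` with fields replaced (convenience for sweeps)."""
    return replace(base, **overrides)
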