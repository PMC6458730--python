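# Methods

## The monotone scan

A gene is scored against an ordered labeling of the samples (K levels,
sizes n_1..n_K). For each split k = 1..K−1 the samples at levels ≤ k form
the lower block and the rest the upper block. Candidate discriminating
lines are the *distinct expression values of the lower block*; for a line t
the error is `#(lower > t) + #(upper ≤ t)`, and the split contributes the
minimal error, with ties among minimizers resolved to the smallest t.
DE_total is the sum of the K−1 split errors. The K−1 splits are optimized
independently; no constraint forces the chosen lines into increasing order
(for a clean monotone gene they come out ordered anyway).

Two conventions deserve making explicit, since "above/below the line" leaves
them open:

* A lower-block sample **at** the line is correctly classified; an
  upper-block sample at the line is an error. Consequently a constant gene
  scores the size of the upper blocks (6 for one sample per level at K = 4),
  not 0 — a flat gene is not monotone.
* The descending scan is defined as the ascending scan on negated values,
  with the chosen line mapped back to the original scale. The smallest-
  threshold tie-break therefore acts on the negated scale (i.e. picks the
  largest original-scale line). For tie-free values the descending score of
  a gene equals the ascending score of its negation exactly.

The score depends only on the within-gene ranking of values, so it is
invariant under any strictly increasing transformation and makes no
distributional assumption.

### Complexity

The naive cost per gene and split is O(n_lower · n). The scan path instead
sorts each gene once (O(N log N)) and evaluates all candidate lines of a
split with cumulative sums over the sorted order, handling ties by
evaluating each tie run at its right edge: O(N) per gene, split and
permutation. A 2,000-gene × 73-sample scan with B = 500 permutations takes
a few seconds on one CPU.

## Permutation inference

Level labels are shuffled across samples (level sizes preserved); the same
B permutations are applied to every gene, which keeps the cost at
O(B · G · N) and makes the joint null exchangeable across genes (p-values of
different genes are positively correlated through the shared draws — see
the calibration note below). The p-value is the add-one estimator
`p = (1 + #{permuted DE_total ≤ observed}) / (B + 1)`, which is valid
(never anti-conservative) and never returns 0. The seed is a mandatory
argument; there is no hidden global state.

**Resolution vs multiplicity.** The smallest attainable p is 1/(B+1).
Benjamini–Hochberg rejects the i-th smallest p only if p ≤ α·i/m, so with
m genes scanned and d true monotone genes, calls at FDR α are possible only
when `1/(B+1) ≤ α·d/m`, i.e. `B ≥ m/(α·d) − 1`. For m = 2,000 and d = 26
descending genes at α = 0.05 this means B ≳ 1,540: a scan run with too few
permutations reports *zero* discoveries however strong the signal, a floor
effect and not a power failure. The default is B = 1,000; choose B from the
bound above, not from runtime convenience. The package deliberately keeps
the honest add-one estimator rather than the `c/B` variant that can return
p = 0 and hide the floor.

q-values are plain Benjamini–Hochberg (step-up, capped at 1, returned in
input order); Storey-type null-proportion estimation is not implemented.
Ascending and descending scans are corrected separately, each against all m
genes, mirroring the convention of reporting the two directions as separate
gene lists.

## Stratifications

* **Stage**: fixed clinical order IA < IB < IIA < IIB. Empty stages are
  dropped with a warning (a real cohort can contain no stage-IIA patients)
  and K shrinks; fewer than two non-empty stages is an error.
* **Quartile groups** (risk of death, age): cutoffs are the empirical
  type-7 (linearly interpolated) first quartile, median and third quartile.
  Assignment: value ≤ Q1 → group 1, ≤ median → 2, ≤ Q3 → 3, else 4. With n
  distinct values the sizes differ by at most one, the remainder going to
  the lower groups (73 values → 19/18/18/18). Internally the comparison is
  made against the order statistic at floor(1 + (n−1)p) — the exact-
  arithmetic equivalent of comparing to the interpolated cutoff — so the
  grouping is immune to floating-point rounding of the interpolation and
  exactly rank-invariant. Samples tied at a cutoff all
  land in the same group, so the split is deterministic; heavy ties can
  empty an inter-quartile band, in which case that level is dropped and K
  shrinks, like empty stages. `reverse=True` flips the level order.
* **Risk of death** uses the survival-time quartiles among *uncensored*
  patients in ascending order: level 1 = extremely high risk (shortest
  quarter), level 4 = low risk. Censored patients are excluded before
  stratification (`filter_patients(require_uncensored=True)`), because a
  censored time gives only a lower bound and its quartile membership would
  be ambiguous. Survival times keep their input unit; only ranks matter.

## Association checks

* **Spearman** between two ordinal labelings uses midranks for ties and the
  two-sided t-approximation for the p-value, adequate at the cohort sizes
  targeted here (tens to ~100); an exact permutation p-value is available
  behind a flag. Note that with two 4-level labelings the p-value
  distribution is slightly conservative under independence because of the
  heavy ties.
* **Log-rank / Kaplan–Meier** delegate to lifelines: product-limit
  estimates per group and the unweighted multi-group log-rank statistic
  with the hypergeometric variance at tied event times, df = #groups − 1.
  Censored samples contribute to risk sets only.
* **Overlap summaries** report exact membership counts for every
  intersection region of 2–4 gene sets (the numbers a Venn diagram would
  display); plotting is out of scope.

## The synthetic generator

The generator produces cohorts with the structure the analysis assumes, with
known ground truth:

| parameter | default | meaning |
|---|---|---|
| `group_sizes` | (19, 18, 18, 18) | risk-level sizes; 73 patients total |
| `n_genes` | 2,000 | matrix rows |
| `n_ascending` / `n_descending` | 48 / 26 | planted monotone genes |
| `effect_step` | 1.0 | per-level mean shift, in noise SDs |
| `noise_sd`, `baseline` | 1.0, 7.0 | log-scale Gaussian noise around a log2-intensity-like location |
| `survival_scale_base` | 6.0 months | mean OS of the extremely-high-risk level |
| `survival_scale_factor` | 4.0 | ratio of adjacent level means |
| `censoring_fraction` | 0.0 | Bernoulli censoring of the event flag |
| `stage_risk_rho` | 0.0 | Gaussian-copula association between stage and risk |

Null genes are iid Normal(baseline, noise_sd²); a planted ascending gene
adds `effect_step·noise_sd·(level−1)` to the mean (descending mirrored).
The default cohort shape — 73 patients in quartile groups of 19/18/18/18,
a ~4% minority of planted genes, one-SD steps — emulates a small
adenocarcinoma cohort in which a risk-level scan has real but not trivial
signal. Survival is exponential per level with strictly ordered means, the
simplest ordered family; stages are drawn by discretizing a latent normal
tied to the latent risk score with correlation `stage_risk_rho` (default 0:
stage carries no survival information, so stage scans are null and
stage-vs-risk tests are calibrated). Everything is deterministic given
`seed`.

What the generator does **not** emulate: probe-level microarray artifacts,
batch effects, heavy-tailed or count noise, dependence between genes, and
informative censoring. Passing tests therefore demonstrate the correctness
and calibration of the machinery on clean ordered-group data, not
robustness to those real-data complications (the score's rank invariance
makes the Gaussian choice less restrictive than it looks).

One behaviour worth knowing: because the exponential's spread scales with
its mean, adjacent risk levels overlap substantially at any scale ratio.
Quartile stratification of the *realized* times therefore recovers the
*generating* level for only ~59% of samples at ratio 4 and ~95% on average
at ratio 64 (73 patients). This is a property of exponential survival, not
a bug in the stratification; planted expression effects are tied to the
generating level, so scans against realized quartiles see a slightly
diluted effective step.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` run the brute-force oracle
comparison on 500 random instances (K ∈ 2..5, 2–6 samples per level,
injected ties), null calibration on 1,000 genes × 72 samples at B = 200,
and planted-signal recovery at the full default cohort (2,000 × 73) at
B = 500 and B = 2,000 — sizes chosen so the whole battery completes in a
few minutes on one CPU while still exercising the cohort scale the
defaults describe. The B = 500 recovery run documents the permutation-floor
effect quantitatively (zero calls); the B = 2,000 run shows the same data
yield ≈0.9 sensitivity at ≈3–5% empirical FDR once the floor clears the BH
bound.

## Known limitations

* The permutation floor couples B to the scan size; there is no analytic
  fallback for very large m.
* BH is applied per direction; a gene can in principle be called in both
  directions at K ≥ 3 (never for clean monotone data).
* Quartile stratification requires ≥ 4 distinct values and drops empty
  tie-created bands rather than splitting tied samples.
* `spearman_ordinal` refuses constant labelings instead of returning NaN.
* No missing-data handling: expression matrices must be complete, by design.
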