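# Methods

## Dose-response model and categorization

The pipeline operates on a drugs × cell-lines matrix of natural-log IC50
values (ln µM). Raw-IC50 input can be converted at read time
(`raw_ic50=True`); internally one canonical unit is enforced. Missing
entries carry an explicit mask; imputation defaults to the per-drug median
over observed lines (deterministic and order-independent), with a
K-nearest-drugs alternative (`method="knn"`, K = 5 by default, Euclidean
distance on shared observed lines) behind config. Whether lineage filtering
precedes imputation is itself a config choice; the default is filter first,
so imputed values are computed within the disease subset being analyzed.
Cell-line filtering matches metadata fields case-insensitively with
whitespace stripped (public panel annotations capitalize inconsistently);
values within a field are OR-ed, fields AND-ed.

Per drug, tertile categories are assigned by rank: with n lines and
q = ⌊n/3⌋, the q lowest-ln(IC50) lines are S, the q highest are R, the
middle n − 2q are N. Ties break by ascending value then lexicographic
cell-line id, so the partition is a deterministic function of the value
multiset and the id set — invariant under input permutation and under any
strictly monotone transform of the values. Thresholds recorded with the
calls are the largest S value and the smallest R value. Because the rule is
rank-based, |S| = |R| = ⌊n/3⌋ always; for n = 94 the S fraction prints as
33.0%.

## Greedy maximum coverage and its regularization

The universe is either N ∪ R or R-only for the chosen primary drug; a
candidate secondary drug's kill set is the universe lines in its own S
tertile. Greedy selection maximizes marginal coverage per step, stopping at
`k_max` drugs, full coverage, or when the best marginal gain drops to
≤ λ·|universe|. The threshold form is the standard sparsity-inducing
regularization of greedy cover; λ defaults to 0 (pure greedy) and is
surfaced in every report header. All numeric ties break lexicographically
on drug id, so runs are reproducible byte for byte. Note one consequence,
measured in the test suite: under an exchangeable null the deterministic
tie-break slightly favors lexicographically early drugs whenever integer
coverage counts tie; the null-uniformity test therefore randomizes labels
per replicate.

Coverage fractions use the full filtered panel as denominator, with step 0
the primary drug's own S set — so a report's "primary only" column is the S
fraction and subsequent columns are cumulative kill fractions of the
combination regimens.

An exhaustive enumerator over all size-k candidate subsets (capped at 10⁶
subsets) serves as the optimality oracle in tests; on 200 random instances
the greedy covered count satisfies the classical (1 − 1/e) guarantee and is
exact on separable planted instances.

Multiple report rows are produced by greedy restarts that ban previously
selected secondary drugs. This is an explicit interpretation choice — a
way to enumerate distinct high-coverage regimens — not a claim that any
particular ranked list was produced this way elsewhere.

## Bootstrap confidence

Confidence is bootstrap selection frequency: resample cell lines with
replacement B times (default B = 1000, seed 42; repeated draws of a line
get a `~i` id suffix), rerun categorization → universe → greedy on each
replicate, and report the fraction of replicates whose selection, truncated
to the combination's size and compared as an unordered set, equals the
combination. Replicates with fewer than 3 distinct lines are redrawn and
counted. The score is conditional on the observed panel: it measures
stability of the selection under line resampling, not a posterior
probability over datasets.

## Single-cell screening

Counts are raw UMIs in a sparse cell × gene matrix (Matrix Market triplet
with barcode/feature sidecars, either orientation). Clustering is accepted
as an input label table — it is upstream-tool output, not recomputed here.
A drug covers a cell when ≥ `min_genes_expressed` (default 1) of its target
genes have count ≥ `min_count` (default 1). Presence/absence on raw counts
is the minimal reproducible operationalization of "enriched target-gene
expression"; a CPM-normalized threshold mode exists for deeper-sequenced
data. Per-cluster coverage fractions are exact partitions of the overall
fraction (they aggregate to it weighted by cluster size). Combination
ranking reuses the greedy engine with all cells as the universe.

## Synergy arithmetic

The median-effect fit is OLS of logit₁₀(fa) on log₁₀(dose); fa values at
exactly 0 or 1 are rejected (undefined logit) unless the opt-in clip at
10⁻⁶ is enabled. The combination index uses the mutually exclusive two-term
form by default — the standard choice for CalcuSyn-style reports — with the
mutually nonexclusive cross-term available by flag, since published CI
values rarely state the variant. `call` is "additive" within 10⁻⁹ of
CI = 1. DRIᵢ = Dxᵢ/dᵢ is defined only for dᵢ > 0. Both constant-ratio and
non-constant-ratio dose designs are accepted: each combination row is
evaluated at its own observed fa.

## Synthetic data generator

`simulate_response_matrix` draws per-drug profiles ln(IC50) ~
Normal(µ_d, σ_d) with µ_d ~ Normal(2, 1.5) ln µM and σ_d ~ Uniform(0.4,
0.7) — the narrower within-lineage spread of a single disease-filtered
panel, chosen so the default +3 ln-unit refractory shift dominates the
noise and the planted refractory set coincides with the primary drug's R
tertile. A refractory subset of ⌊n/3⌋ lines (drawn if not supplied) is
shifted +effect_size for the primary drug; each planted secondary drug is
shifted −effect_size on an assigned slice of a partition of the refractory
lines, so the planted combination's kill sets jointly cover the refractory
set. Missingness is masked uniformly at `missing_rate` without ever
emptying a drug row. Because the planted effects live on the refractory
(R) lines, parameter-recovery experiments use `universe_mode:
resistant_only`; under N ∪ R a random drug's expected overlap with the
63-line universe exceeds a planted drug's by construction, so recovery
there is not an informative check.

What the generator does **not** emulate: correlated drug mechanisms,
panel-wide batch structure, heavy-tailed IC50 error, or real drug
identities. Passing recovery tests therefore demonstrates the engine's
correctness under the planted model, not predictive validity on real
panels.

`simulate_sc_counts` emulates droplet UMI data: negative-binomial counts
(dispersion r = 2) with background per-gene means ~ Uniform(0.05, 0.5),
mild lognormal cluster wobble (σ = 0.2), and planted per-cluster programs
whose gene means are multiplied by `program_fold` (default 10) in their
home cluster. It does not model library-size variation, doublets, or
ambient RNA.

## Problem sizes and numerical choices

Test and acceptance workloads are desk-scale by design: 94-line × 30-drug
simulated panels (the size of a disease-filtered pharmacogenomics subset),
≤ 15-line instances for exhaustive-oracle comparisons, 100-seed recovery
sweeps, B = 200 bootstraps, and 150–300-cell single-cell simulations —
enough for every guarantee tested while keeping the whole suite in the
minutes range. Percentages in reports are rounded half-up to one decimal.
All randomness flows through `numpy.random.default_rng` with explicit
seeds; identical config + seed reproduces reports byte for byte.

## Known limitations

- The λ-threshold regularizer is this package's construction; other
  regularized set-cover variants (weighted penalties, cardinality priors)
  are out of scope.
- Bootstrap confidence is selection stability, which can be low for all
  combinations when many near-ties exist even if each is individually
  reasonable.
- The tertile rule ignores effect magnitude beyond rank; no AUC/Emax
  modeling is offered.
- No network access: public panel downloads, target-database clients, and
  pathway visualization are explicitly out of scope.
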