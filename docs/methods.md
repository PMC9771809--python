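# Methods

This note documents the models and procedures implemented in `rnadeg`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic benchmark does and does not show.

## Secondary-structure primitives

Dot-bracket strings are parsed with per-bracket-type stacks; errors name the
offending index. Coordinates are 0-based and intervals half-open throughout,
including in serialized files. Pseudoknot bracket alphabets (`[]`, `{}`,
`<>`) parse only when explicitly enabled; their pairs enter the structure
graph but loop-type annotation requires a nested (pseudoknot-free) table.

Loop types are assigned directly from the pair table using the bpRNA class
definitions rather than by shelling out to bpRNA: paired positions are stems
(S); a loop closed by a pair with no inner helix is a hairpin (H); with one
inner helix it is a bulge (B, unpaired run on one side) or internal loop (I,
runs on both sides); with two or more inner helices its unpaired positions
are multiloop (M). Exterior unpaired runs touching a sequence terminus are
ends (E); exterior runs flanked by helices on both sides are external loops
(X). The goal is agreement with these class definitions, not byte-identity
with bpRNA's output on exotic corner cases (multiplets, pseudoknotted
segments), which are out of scope.

The structure graph has backbone edges (i, i+1) plus pair edges; all-pairs
hop distances are computed by unweighted BFS (scipy csgraph) and stored
dense — constructs of interest are ≲ 1,600 nt, so the O(N²) matrix is
cheap. Unpaired probabilities from a base-pair probability matrix are
`1 − row sum`, clipped to [0, 1], with symmetry/row-sum validation
(tolerance 1e-6 by default).

## Windowed degradation model

Per-position features are one-hot indicators of sequence (A,C,G,U) and loop
type (H,E,I,M,B,S) at every offset k ∈ [−w, w]; w defaults to 12, giving
(2·12+1)·10 = 250 indicator columns plus an intercept (251 parameters).
Offsets outside the sequence contribute all-zero blocks (zero-padding), which
keeps the design linear and is standard practice. The external-loop class X
is encoded as E by default, reflecting the biophysical similarity of the two
unpaired exterior contexts; this is configurable.

The one-hot parametrization is exactly collinear: for every offset the four
sequence indicators and the six structure indicators both sum to the same
in-bounds mask, and the intercept column equals the offset-0 sequence-block
sum. Coefficients are therefore identified only modulo a known null space,
exposed as `WindowFeaturizer.null_space()`. The unpenalized fit returns the
minimum-norm least-squares solution (with a rank warning); the default ridge
penalty λ = 0.1 — small, scale-free shrinkage on the slopes with the
intercept unpenalized — makes the solution unique. Each measurement channel
gets an independent coefficient set; multi-task weight sharing is a
deep-network concern outside this package's scope. Published external
coefficient tables can be imported through the JSON model format (keys
`"offset:indicator"`), but models here are otherwise retrained.

The boosted variant trains an XGBoost regressor on the same indicator
columns (`tree_method="hist"`, single thread, seeded), trading the linear
model's interpretability for the ability to express interactions and
thresholds.

## Whole-molecule stability

The total degradation rate is the sum of per-linkage rates and the half-life
is ln 2 divided by it. Per-nucleotide model outputs are used directly as
linkage-rate proxies (the rate index i is read as the linkage 3′ of
nucleotide i). Predictions are computed over the full sequence first and then
summed over the probed window, so base pairing between untranslated and
coding regions influences the summed rate. Rates are unit-agnostic; the
half-life is reported in the reciprocal unit of the input rates.

## Evaluation

RMSE pools scored positions across constructs within a channel (one global
RMSE per channel); MCRMSE is the arithmetic mean over channels. The
within-error fraction uses a strict inequality |ŷ − y| < σ. The
signal-to-noise ratio averages μ/σ over positions, then over channels;
positions with σ = 0 either raise or are excluded, per flag. Motif
aggregation pools per-position signal by loop class plus derived bins: a
triloop is a hairpin loop of exactly 3 unpaired nt, and internal loops are
split into symmetric/asymmetric by equality of their two side lengths (bins
configurable). Spearman correlations use scipy's two-sided p-value
(t-approximation).

## Curation

The quality filter passes a record when every value across its degradation
channels lies strictly in (min 0.5, max 20) and the SHAPE-reactivity
signal-to-noise strictly exceeds 1. The min/max channels default to the
degradation channels present (the SHAPE channel enters only through the SN
term), and all thresholds are strict and configurable. Failing records are
flagged, never dropped.

Sequence distance for clustering is normalized Levenshtein (edlib), which
handles mixed 107/130-nt datasets; Hamming is available for equal lengths.
The dendrogram uses Ward linkage cut at cophenetic height 0.5. Ward on a
precomputed non-Euclidean distance is formally improper, but it is the
conventional choice as implemented in common libraries and is retained here,
with average linkage available as an alternative. The split rule: all
members of clusters of size ≤ 3 go to the private test set; the private set
is topped up with one random member from each of a random selection of
larger clusters; the rest is randomly partitioned into train and public test
by target counts. All randomness is driven by one seed, and infeasible
targets raise with the achievable maximum. A diagnostic
(`rescaling_diagnostic`) compares per-nucleotide-type medians between two
measurement rounds without applying any rescaling.

## Ensembling

Simple weighted averaging requires aligned prediction sets. The genetic
algorithm searches (subset mask, continuous weights) chromosomes, at most 10
members by default, minimizing MCRMSE on the optimization split. Defaults:
population 64, 200 generations, mutation rate 0.05, tournament selection of
size 3, elitism 2; weights renormalize over the active subset after
mutation, and a uniform-weights mode is available. The initial population
seeds every single-candidate ensemble, so with elitism the returned spec
never scores worse than the best single candidate on the optimization
split — asserted every generation. Held-out evaluation is a separate call
(`evaluate_ensemble`), keeping optimization-split overfitting observable.
Ties break toward fewer members, then lexical ids.

## Synthetic data

The generator emulates the regime of the real crowdsourced datasets:
107-nt constructs scored over their first 68 nt (optionally mixed with
130/102-nt constructs), five channels (SHAPE reactivity and four
accelerated-degradation conditions; the three-channel second-round regime is
a flag away), and an optional constant `GGAAA` 5′ prefix. Ground truth is a
planted windowed linear model per channel (coefficients ~ N(0, 0.05),
intercept 3.0 — values sit in the 2–4 range typical after normalization and
clear of the 0.5 filter floor) plus additive motif offsets (+0.8 on
triloops, +0.3 on asymmetric and +0.1 on symmetric internal loops, encoding
the observed reactivity ordering). Noise is heteroscedastic,
σ = a + b·√max(value, 0) with floor a = 0.05 (avoiding zero division in the
SN ratio) and slope b = 0.15 (yielding realistic SN ≈ 5–10), plus a shared
per-position latent (scale 0.1) that correlates channels; reported error
bars are the total sd of both components, so the within-error fraction of
the generating model is the Gaussian 68.3% by construction.

Structures come from a seeded stochastic nested sampler: helices are placed
recursively with complementary pairs only (AU, GC, GU) and hairpin loops of
at least 3 nt. It produces valid, diverse structures exhibiting all seven
loop classes but is sparser in base pairs than thermodynamic folds and has
no energy model; a folder hook accepts externally computed MFE structures
where realism matters. Consequently, passing tests demonstrate correctness
of the machinery on data with the assumed statistical structure — they do
not certify predictive accuracy on real chemical-mapping data, whose noise
is non-Gaussian in the tails and whose structure features carry folding
errors.

Planted coefficients are projected onto the identifiable subspace (the
orthogonal complement of the featurization's null space) so that parameter
recovery is well-posed; the recovery benchmark scores full-length constructs
so both window boundaries appear in the design, and the unpenalized fit then
reproduces the planted coefficients to ≈ 1e-14. A `fail_fraction` of
constructs is corrupted (drowned SHAPE signal-to-noise or one out-of-range
degradation value) to exercise the filter, and a `duplicate_fraction`
(default 0.1, mirroring the design families present in player-submitted
data) injects near-copies to exercise clustering.

## Problem sizes and determinism

Test and benchmark datasets use 6–400 constructs — large enough that the
recovery fit has ≥ 5× more rows than parameters and Monte-Carlo estimates
(10⁵ draws) sit within tight binomial bounds, and small enough to run
comfortably on one core. Every stochastic component (generator, GA, boosted
trees, split assignment) takes an explicit seed; identical seeds give
bytewise-identical outputs.

## Known limitations

- Loop annotation targets nested structures; pseudoknots and base multiplets
  are not annotated.
- The linear model's coefficients are reported as the minimum-norm or ridge
  representative of an equivalence class; individual coefficient values are
  not directly interpretable without fixing a gauge.
- The clustering metric and the Ward-on-precomputed-distance convention are
  pragmatic choices; reconstructing any particular historical split requires
  the original data and the exact metric used there.
- The GA is a heuristic: it is guaranteed not to underperform the best
  single candidate on the optimization split, but not to find the global
  optimum.
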