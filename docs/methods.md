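# Methods

This note documents the models implemented in `oxynet`, the choices made
where the methodology was genuinely open, and what the synthetic-data
generator does and does not emulate.

## Data model

The central object is the weighted bipartite adjacency matrix *A*
(rows = oxyurid species, columns = individual tortoises,
*a<sub>ij</sub>* = adult worm count).  Matrices are read from CSV with a
header row of host ids and a first column of species names; a
`transposed` option accepts the flipped layout.  All-zero rows and
columns are preserved on input — presence in the file is authoritative,
and each metric decides internally what to ignore rather than mutating
the data.  Uninfected hosts are removed by an explicit, idempotent step
(`drop_uninfected_hosts`) before network analysis only; trait summaries
and ANCOVAs keep them (their richness and abundance are genuine zeros).

Host records validate habitat (`low`/`intermediate`/`high`), life stage
against ring-estimated age (adult > 8 y, subadult 5–8 y, juvenile
1–4 y) and positivity of age, weight and carapace length.

## Von Bertalanffy growth scores

Carapace length follows
L(t) = L<sub>∞</sub> − (L<sub>∞</sub> − L₀)·e<sup>−kt</sup>,
anchored at the hatchling length L₀ rather than a nominal age t₀, so a
single capture (one length/age pair) inverts to a per-individual
growth-rate score k = −(1/t)·ln[(L<sub>∞</sub> − L)/(L<sub>∞</sub> − L₀)].
Defaults — L₀ = 35 mm; L<sub>∞</sub> = 160 mm (females), 140 mm
(males), 150 mm (unknown sex) — are tunable configuration, set to
plausible values for western Mediterranean *T. graeca*; they are not
calibrated estimates.  Ring-count ages are taken as given (no ageing
error model), and no population-level fitting of L<sub>∞</sub>/L₀ from
recaptures is attempted.  Numerics: the round trip estimate∘predict is
exact to 1e−10 except within a few µm of the asymptote, where the
subtraction L<sub>∞</sub> − L necessarily loses a few ulps of
L<sub>∞</sub> (relative error ≲ 1e−8 at k·t ≈ 20).

## Network metrics

All entropies use natural logarithms (a `base` switch exists).
Multiplying all counts by a positive constant leaves every index below
unchanged.

**Connectance** is links/(n_species × n_hosts) over the matrix as given,
so mean host degree = connectance × n_species holds exactly.

**WNODF.**  Rows and columns are sorted internally by decreasing
marginal totals (ties broken by original index, so the metric is
invariant to input permutations).  For an ordered within-axis pair
(upper *u*, lower *l*): the pair scores 0 unless the lower total is
strictly smaller (the decreasing-fill condition — tied totals score 0);
otherwise 100 × (number of positions where 0 < a<sub>l</sub> <
a<sub>u</sub>) / (number of positive cells of *l*).  WNODF is the sum
over both axes divided by R(R−1)/2 + S(S−1)/2.  Empty rows/columns are
dropped first; an axis with a single non-empty member contributes no
pairs, and a matrix degenerate on both axes is an error.

**H₂′.**  With observed interaction entropy H₂,
H₂′ = (H₂max − H₂)/(H₂max − H₂min), clamped to [0, 1].  H₂max is the
entropy of the continuous independence expectation (outer product of
marginal shares, i.e. H(rows) + H(cols)) — cheap, deterministic, and
anchored at exactly 0 for an outer-product matrix — rather than an
integer-constrained search.  H₂min is a deterministic greedy packing
(repeatedly allocate min(row, col) to the largest remaining row and
column totals).  Exhaustive enumeration of all integer matrices with
fixed marginals (2×2 and 2×3, totals ≤ 6) confirms the greedy minimum
equals the true minimum there; for larger matrices it is an upper bound
on the attainable minimum, which is why cross-implementation agreement
is only expected to ~±0.03.

**d′.**  For host *j*, d<sub>j</sub> = Σ<sub>i</sub> p′<sub>ij</sub>
ln(p′<sub>ij</sub>/q<sub>i</sub>) — the KL divergence of the host's
conditional partner shares from species availability — standardized as
d′ = d/ln(A/A<sub>j</sub>).  The denominator is the feasible maximum:
a host concentrating its whole burden A<sub>j</sub> on one partner
faces an availability of at least A<sub>j</sub>/A, since that partner's
total includes the host's own interactions.  This yields exactly 1 on
an equal-margin diagonal matrix and 0 at proportional use (d_min = 0).
Hosts with zero burden get NaN with a warning.  Reported "individual
level" means are over hosts only, matching the per-tortoise definition
of degree.

## Null model and nestedness significance

Cell occurrence probabilities are P<sub>ij</sub> = (k<sub>i</sub>/S +
k<sub>j</sub>/R)/2 (row fill + column fill, averaged); the expected
fill equals the observed connectance identically.  The published
procedure ran weighted nestedness against a binary-probability null;
bridging weights into the null is this package's explicit choice:
filled cells receive the observed positive counts, randomly permuted
(subsampled without replacement when the null draw has fewer links,
padded by resampling with replacement when it has more).  The scheme is
stamped into every result (`weight_scheme`).  Degenerate null draws
(empty rows/columns) are kept and scored 0 — resampling them away would
bias the null upward.  Significance: p = (1 + #{null ≥ observed})/(n +
1), never exactly 0; z = (observed − null mean)/null sd, reported as
NaN when the null sd is 0.  Calibration: matrices drawn from their own
null ensemble have |z| ≤ 2 in ≈ 95% of seeds (checked in the test
suite).  Only this one null model (plus the permuted-weights bridge) is
provided; fixed-marginal swap algorithms are out of scope.

## Rank/abundance evenness

Species are ranked by descending row totals (ties broken by label);
relative abundances are plotted/fitted on log₁₀.  Per-habitat slopes
come from OLS of log₁₀ relative abundance on rank; zero-abundance
species are excluded (no log).  The cross-habitat comparison pools the
curves into one OLS with terms rank, habitat, rank × habitat entered
sequentially (Type I); entering the interaction last makes its F
invariant to SS type.  The F statistics are provably invariant to the
log base and to absolute-vs-relative abundances (both are linear
shifts absorbed by intercepts), which the tests assert numerically.

## Linear-model engine

A deliberately small, self-contained engine (the published analyses
used closed-source software, and an explicit implementation keeps every
modelling choice visible): treatment-coded design matrices with
habitat ordered low < intermediate < high (reference = low), OLS by
least squares with rank checking that names aliased columns,
sequential F tables F = (ΔRSS/Δdf)/(RSS_full/df_full), one-way ANOVA,
and Poisson log-linear models by IRLS (converged when the relative
deviance change < 1e−10, max 100 iterations, non-convergence is an
error with the deviance trace).  Nested Poisson models are compared by
the deviance χ²; when the estimated dispersion φ̂ = deviance/df exceeds
1 and rescaling is on (the default), the statistic becomes
F = (Δdeviance/Δdf)/φ̂ on (Δdf, df_full), which is strictly more
conservative — the quasi-likelihood correction for overdispersed
counts.  The threshold φ̂ > 1 is the natural reading of "rescale when
overdispersion is found" and is logged in the output.  statsmodels is
used only as an independent oracle in the tests, never in the
implementation path.  Body weight and carapace length enter tests
log(x+1)-transformed; growth scores are untransformed.  No
multiple-testing correction is applied across the twelve ANCOVAs by
default (matching the original analysis); mixed models and robust
errors are out of scope.

## Association analyses

Habitat summaries report mean ± SE (SE of a single observation is NA,
not 0) for weight, carapace length, growth score, per-host species
richness and total adult worm burden, over all life stages and over
adults only, with uninfected hosts contributing zeros.  The
growth–infestation ANCOVA fits k ~ covariate + habitat +
covariate × habitat (sequential, interaction last); habitats with fewer
than 3 usable hosts are dropped with a warning.  Per-habitat simple
regressions classify each habitat's association as positive / neutral /
negative from a 99% confidence interval — a deliberately strict call
(effects are only declared at P < 0.01) so that a truly neutral habitat
is rarely mislabelled.  Individual-level models per habitat: Poisson
GLM of species-degree on each trait with the deviance χ² (rescaled
when overdispersed), and Gaussian OLS of d′ on the same traits;
printed degrees of freedom are always the engine's own.

## Synthetic-data generator

Defaults emulate the study design: three habitats with 26/20/20
tortoises in the recorded stage/sex composition (21/9/13 adults), a
14-species pool of which 13 occur per habitat (one species absent from
the high-loss landscape, one exclusive to it), ~28% of hosts free of
adult worms, and cell counts spanning 1 to the low thousands under a
geometric-decay × lognormal law (`count_scale` 1500, `abundance_decay`
0.9, `count_sigma` 0.8).

*Networks* (`simulate_network`): the binary skeleton interpolates, with
mixing weight ν, between a uniform random graph and a perfectly nested
threshold template on the gradient i/R + j/S, then flips each cell with
probability ε; the base fill is pre-compensated so the expected
connectance equals the target exactly (realized fill is unbiased,
checked over 200 seeds).  Positive cells receive strictly decreasing
heavy-tailed weights along the gradient, with a (1 − ν) fraction of the
assignment reshuffled — so ν = 1, ε = 0 gives WNODF = 100 exactly,
while ν = 0 carries no weighted structure beyond its skeleton and sits
within ±2 null standard deviations of its own ensemble.

*Hosts* (`simulate_hosts`): ages uniform within stage bands, growth
scores k ~ truncated Normal(0.12, 0.03) per year, lengths from the
growth curve at the drawn age and rate, weights cubic in length with
lognormal noise.

*Study* (`simulate_study`): infestation couples to k through both
prevalence (logit-linear) and intensity (log-linear Poisson richness,
capped by the pool size), with habitat-specific slopes b (defaults
+1.5 / 0 / −1.5 per SD of k) — positive at low habitat loss, absent at
intermediate, negative at high.  The effect magnitude was chosen for
statistical power: with 20–26 hosts per habitat, a weaker association
would not be reliably detectable, whereas the emulated design should
recover the (+, 0, −) pattern in ≥ 18 of 20 seeds; under b ≡ 0 the
interaction test rejects at the nominal 5% (measured 4–5% over 1000
simulated studies).  Infected hosts receive the top-ranked species of
their habitat pool with occasional random swaps (probability `noise`),
which produces the nested infection structure.  Ground-truth parameters
travel in `StudyDataset.metadata`.

What the generator does **not** emulate: spatial transmission dynamics,
tortoise density, seasonal variation, ageing error in growth rings,
correlations between body size and infestation beyond those induced via
k, and the exact marginal distributions of the field matrices.  Tests
passing on synthetic data therefore demonstrate the correctness and
calibration of the *procedures*, not the field values; reproducing the
published per-habitat network table requires the deposited data CSVs
(see `data/deposited/README.md`), without which those specific checks
fail by design.

## Problem sizes and determinism

Monte-Carlo defaults: 1000 null matrices per nestedness test; the
calibration analyses use 20 seeds (sign recovery), 1000 null studies
(type-I error) and 100–150-replicate ensembles (z calibration) — sizes
at which the Monte-Carlo error is comfortably below the decision
thresholds.  All randomness flows through `numpy.random.default_rng`
seeded from configuration; every stochastic report carries its seed and
replicate count, and identical (config, seed) runs are byte-identical.
Reports are serialized unrounded.
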