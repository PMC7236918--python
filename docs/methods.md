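# Methods

## Data model

An *association record* is one observation of a single Symbiodiniaceae
ITS2 phylotype in one coral colony. Distinct phylotypes co-occurring in a
colony are distinct records; repeated detections of the same phylotype in
the same colony are collapsed to one (applied whenever a `colony_id` is
present; rows without colony ids are trusted as distinct observations).
The *assemblage* of a host species is the multiset of its records pooled
across colonies, studies and sites. Phylotype labels are compared
case-sensitively after whitespace trimming; no nomenclature
reconciliation is attempted, since merging similar ITS2 labels can
silently collapse genuinely distinct phylotypes. Records flagged as
potential intragenomic variants (P-IGV — uncodified ITS2 sequences
treated as their own phylotypes) can be excluded as a sensitivity
analysis; species falling below the inclusion threshold afterwards are
re-filtered.

Species with fewer than 15 records are excluded (`min_records = 15`,
coupled by default to the smallest rarefaction depth: a species that
cannot be rarefied to the shallowest standard depth contributes to no
cross-species comparison). Bathymetric/latitudinal/longitudinal ranges
per species are max − min over the records bearing the field; fields
missing on a record are omitted, species with fewer than two informative
records get a missing range, and longitude ranges do not wrap the
antimeridian (a known limitation for circum-global species).

## Rarefaction

Expected richness in a subsample of `n` of the `N` records,

    E(S; n) = Σ_i [1 − C(N − N_i, n) / C(N, n)],

is the hypergeometric expectation of the number of distinct phylotypes.
Numerically each binomial ratio is evaluated as the telescoping product
`Π_{j=0..N_i−1} (N − n − j)/(N − j)`: every factor lies in [0, 1], the
`n > N − N_i` boundary yields an exact zero, no large intermediates form
at any `N`, and the accumulated error is ~1e−15 — which matters because
the PIE and end-slope identities below are asserted to 1e−12. (A
log-gamma formulation was tried first and discarded: cancellation in the
difference of large log-factorials cost ~1e−12 absolute accuracy.)

Rarefaction here is interpolation only; `n > N` is refused rather than
extrapolated. Standard depths are 15, 20, 30, 40, 50, 60 records, with a
species eligible at depth `d` iff `N ≥ d` (at `n = N` the expectation is
defined and equals `P` exactly). Useful identities, used both as tests
and as cross-checks at run time:

- `E(S; 1) = 1`; `E(S; N) = P`; the curve is nondecreasing and concave;
- PIE `= E(S;2) − E(S;1)` (initial slope);
- slope-at-end `= s₁/N` where `s₁` is the singleton count.

Evenness conventions: Pielou's J′ is defined as 0 for monotypic
assemblages (`P = 1`) so every species receives a value on the 0–1
scale; PIE requires `N ≥ 2`. A Monte-Carlo estimator (subsampling the
record multiset without replacement) is retained purely as an
independent check of the analytic formula, with a mandatory seed.

## Phylogenetic comparative workflow

Trees are rooted, with mandatory branch lengths; pruning to the analysis
taxa collapses degree-2 nodes by summing branch lengths, so pairwise tip
path lengths are preserved exactly. Data always prune the tree, never
the reverse: taxa in the data but absent from the tree are dropped from
phylogenetic analyses with a logged warning.

**Pagel's λ.** The tip covariance under Brownian motion has
`C[i,j] =` root-to-MRCA path length (off-diagonal) and tip height
(diagonal); λ scales the off-diagonal only, which stays valid for
non-ultrametric trees. The Gaussian likelihood profiles the mean and the
rate analytically, leaving a 1-D bounded optimization of λ on [0, 1]
(`xatol = 1e−8`), with both endpoints evaluated explicitly so boundary
maxima are never missed. The search domain is fixed to [0, 1] — the
transform's standard identifiable range; the tree-dependent upper bound
above 1 used by some implementations is deliberately not implemented,
since the gate only consumes the significance decision, which is
insensitive to λ̂ > 1. The likelihood-ratio statistic `2(ℓ̂ − ℓ₀)` is
referred to plain χ²₁ with no 50:50 boundary mixture, matching common
practice and erring conservative. On a star tree the likelihood is flat
in λ and the test returns p = 1.

**Independent contrasts.** Felsenstein pruning: at each internal node of
a bifurcating tree, contrast `= (x₁ − x₂)/√(v₁ + v₂)`, ancestral value
the precision-weighted average, parent branch lengthened by
`v₁v₂/(v₁ + v₂)`. Polytomies are refused with an instruction to resolve;
`resolve_polytomies` breaks them deterministically (seeded) into
zero-length bifurcations. Zero-length *internal* edges are left exact —
the pruning variances accumulated below keep contrast denominators
positive, and exactness preserves the star-tree identity that the
contrast correlation equals the ordinary Pearson correlation — while a
degenerate cherry of two zero-length terminal branches receives a floor
of ε = 1e−8. The contrasts regression runs through the origin with
x-contrasts sign-positivized (the fit is invariant to the convention);
the reported phylo-r is the uncentered contrasts correlation
`Σuv/√(Σu²Σv²)`, with a two-tailed t test on `n_contrasts − 1` degrees
of freedom. OLS uses `n − 2`.

**The gate.** For each trait pair, OLS residuals are mapped to the
pruned tree and tested for λ signal; significant signal (p < α, default
0.05) switches the *interpreted* result to the PIC regression, otherwise
the OLS result stands. Both fits are always computed and reported, with
the accepted branch flagged. P-values are per-comparison and two-tailed;
no multiple-testing correction is applied (a documented limitation).
Cross-validation tests confirm the λ test against `phytools::phylosig`,
contrasts against `ape::pic`, and rarefaction against `vegan::rarefy`.

## Synthetic data

The generator reproduces the structural features of compiled
association datasets so that every pipeline stage can be tested against
known truth:

- **Effort**: lognormal with μ = ln 44 (median 44 records per species)
  and σ = 1.65, chosen so roughly 18% of species exceed 200 records —
  the long-tailed regime of literature compilations. Draws are rounded
  and floored at 1.
- **Assemblages**: geometric-series relative abundances
  `p_i ∝ k(1−k)^(i−1)` — a single decay parameter `k` sweeps evenness
  (and PIE) monotonically from equal abundances (k → 0) to single
  dominance (k → 1). Per species, `k ~ U(0.1, 0.8)` and latent pool
  richness `P_true = 1 + Poisson(35)` capped at 120, drawn independently
  of effort. These latent settings are calibrated so the *observed*
  assemblages match compiled data after multinomial sampling: mean
  observed raw richness ≈ 9.55 (sd ≈ 6), mean raw evenness ≈ 0.7, and a
  clear raw-richness/effort correlation. Latent pools far exceed
  observed richness because most such rarefaction curves are
  non-asymptotic. Because `P_true` is independent of effort by
  construction, any observed richness/effort correlation is pure
  sampling bias — exactly what rarefaction should remove, and what the
  debiasing test measures.
- **P-IGV flags**: Bernoulli per record, default 4%.
- **Geography**: per-species uniform boxes for depth (0–60 m), latitude
  (±30°) and longitude, with records uniform within the box.
- **Phylogeny and traits**: pure-birth (Yule) trees (ultrametric by
  construction); tip traits drawn MVN(0, σ²·C_λ) via a Cholesky factor
  of the λ-scaled Brownian covariance, plus optional linear coupling
  `β ×` a species covariate and iid noise. The full synthetic *study*
  couples a bleaching-response trait to each species' latent expected
  richness at depth 15 (the infinite-pool expectation
  `Σ 1 − (1−p_i)^15`), then rescales the trait affinely onto [5, 95] so
  it reads as a 0–100% index; affine rescaling changes no correlation.

All generators are pure functions of their seeds.

What the generator does **not** emulate: detection thresholds of the
underlying molecular assays, primer or protocol heterogeneity across
source studies, biogeographic structure in phylotype sharing between
host species (phylotypes are drawn independently per species from a
global pool of 377 labels), or non-Brownian trait evolution. Passing
tests therefore demonstrate correctness of the estimators and of the
bias-removal logic under the stated model, not robustness of the
biological conclusions to assay artifacts or model misspecification.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen to make the checked
properties sharp: exhaustive rarefaction oracles enumerate all
assemblage compositions with N ≤ 12; identity checks use 1000 random
assemblages; Monte-Carlo agreement uses 1e5 subsamples per assemblage;
λ recovery uses 100 replicate 200-tip datasets per simulated λ; the
type-I-error simulation uses 1000 replicate 50-tip studies; the
debiasing contrast pools six replicate 123-species studies (a single
123-species draw leaves a ±0.1 sampling error on a correlation, so the
pooled estimate is reported alongside per-study values). Optimizer
tolerance for λ is 1e−8; ties in phylotype ordering break
lexicographically so all outputs are deterministic given config and
seed.

## Known limitations

- Richness extrapolation (Chao1, ACE) and coverage-based standardization
  are out of scope: standardization is size-based interpolation only.
- No PGLS with simultaneous λ estimation; the gate is a binary choice
  between OLS and PIC, mirroring the decision rule it implements.
- The λ-gated procedure slightly inflates type-I error relative to
  nominal when the signal test misses true structure (measured ≈ 0.05 on
  Brownian nulls at n = 50, but the leakage grows for weaker signal or
  smaller trees).
- Longitude ranges ignore antimeridian wrapping.
- taxon-BRI is consumed as a published input; its derivation is out of
  scope.
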