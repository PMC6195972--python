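# Methods

## Model

Error reads at panel position *j* for a given alternate allele are modeled as
binomial, `X_ij ~ Binomial(N_j, π_ij)`, where `N_j` is the read depth and
`π_ij` the background mutation error rate (BMER) of that (position, alternate)
pair. Each pair is assigned to one of 96 tri-nucleotide contexts (TNCs): the
substituted base plus its immediate 5′ and 3′ neighbours, collapsed to the
pyrimidine strand (C/T center) as in the COSMIC mutational-signature
convention. Within a context, per-position rates are assumed exchangeable and
beta-distributed,

    π ~ Beta(μν, (1 − μ)ν),

with mean μ and concentration ν = α + β. The modeling unit is the
(position, alternate) pair — each of the three alternates at a position has
its own rate and its own context class; this is the only reading consistent
with 96 substitution classes rather than 32 reference contexts.

### Background estimation

For each healthy-cohort subject, the per-entry rate is the alternate count
divided by depth. Observations at or above the germline threshold (default
5%) are masked for that subject — a private SNP in one control must not
poison the cohort mean — and depth-zero positions contribute no observation.
The entry estimate `π̂_ij` is the unweighted mean of unmasked subject rates
(a depth-weighted variant is available behind a flag); entries with no
unmasked observation carry rate 0 with a `no_obs` flag. The across-subject
sample standard deviation is retained alongside (it drives the Gaussian
comparator).

Context priors come from the method of moments on the per-entry rates within
each context: μ̂ is the member mean, and inverting
`var = μ(1 − μ)/(ν + 1)` gives `ν̂ = μ̂(1 − μ̂)/v − 1` with `v` the
across-position sample variance. Degenerate cases (fewer than two member
positions, zero variance, or an inversion yielding ν ≤ 0) cap ν̂ at 10⁶, a
near-point-mass prior that preserves strong shrinkage to the common rate
without division by zero. Contexts absent from the panel fall back to the
pooled panel-wide mean and are flagged; they are reported, never silently
used as if estimated.

### Shrinkage and detection

The reported background is `π̃_ij = w μ̂_i + (1 − w) π̂_ij`. The default
("modified") weight `w = μ̂_i/(μ̂_i + π̂_ij)` shrinks less where the
position-specific rate is high, keeping genuinely noisy positions hot; the
degenerate case μ̂ = π̂ = 0 is defined as w = 1, π̃ = 0. The conjugate
("analytic") posterior weight `w = ν̂/(ν̂ + n)` is available as an optional
mode; since the conjugate update applies to "x errors in n reads" and the
choice of counts is open, this mode uses n = cohort mean depth and
x = π̂·n, so both modes consume the same aggregated data.

The detection threshold is the upper 1 − α/2 Clopper–Pearson bound

    B_ij = BetaQuantile(1 − α/2; N_j π̃_ij + 1, N_j (1 − π̃_ij)),

with the beta shape parameters kept as reals (no rounding) and `N_j` the
healthy-cohort mean depth — the threshold is a property of the background
model, not of the test sample (a sample-depth mode exists for exploration).
At π̃ = 0 the bound has the closed form `1 − (α/2)^(1/N)`, which the tests
use as an independent oracle. An observed alternate fraction below B is
polished — the alternate reads are reassigned to the reference allele so
depth is conserved — and a fraction at or equal to B is retained ("not lower
than B" retains, so ties retain; this matters for float comparisons at the
boundary). Observed fractions at or above the germline threshold pass
through retained with a `probable_snp` flag. No multiple-testing correction
is applied across the panel: the hierarchical prior pools information across
positions, which is the argument for treating the per-entry level α as
already calibrated; the healthy-only false-retain test below checks this
empirically. Default α = 0.01.

Positions whose context is undefined (contig edge, N in the 3-mer) and
entries without sample coverage are emitted with decision `unmodeled` rather
than dropped, so downstream consumers can account for every panel base.

## Gaussian baseline (PSGM)

The comparator models each entry with the across-subject mean and unbiased
sample sd of the same germline-masked rates and retains an observation iff

    observed ≥ mean + z(1 − α/2) · max(sd, sd_floor).

It is a simplified stand-in for conventional position-specific polishing,
not a bit-exact reimplementation of any published tool. The variance floor
(default 10⁻⁵, one read in 100,000) is required because ultra-deep count
data routinely yields zero across-subject variance, which without a floor
would retain any nonzero observation at any α. The one-sided level α/2
matches the one-sided upper Clopper–Pearson bound so the two methods share
an α scale on ROC grids.

## Synthetic data

No public cohort accompanies the method, so all cohort-scale testing runs on
synthetic data with the statistical structure the model assumes: per-entry
true rates drawn from the beta prior of their context, then per-subject
binomial counts at fixed coverage. Defaults follow the study design the
method targets: 14 healthy subjects at 12,000× cohort coverage, 10,000×
test-sample coverage.

The built-in 96-context prior preset emulates barcoded-consensus
(UMI-deduplicated) cfDNA error spectra: per-substitution base means
C>T 2×10⁻⁵ (×3 with a 3′ G, the CpG-deamination analog), T>C 10⁻⁵,
transversions 2–5×10⁻⁶, small multiplicative 5′-flank modulation
(0.8–1.2), ν = 1000. These values are anchored to two descriptive
constraints of the target regime rather than to any tuning target: raw
(pre-polish) data should be ~90% error-free positions at ~12,000× — the
preset yields ~94% — and signals of 0.075–0.1% allele fraction should sit
near the detection limit at 10,000× (the zero-background Clopper–Pearson
bound at α = 0.01 is 5.3×10⁻⁴, and the hottest contexts stay well below
the signal level). With α = μν < 1 the beta draws are highly skewed, so
most entries are effectively error-free while a minority are hot — the
zero-inflated character of real consensus error profiles.

What the generator does **not** emulate: across-subject overdispersion
(batch or subject-specific artifacts — every subject is binomial at the same
true rate), strand-biased artifact classes (strand splitting is simulated,
at Beta(50, 50) forward fraction, but carries no signal), non-binomial read
correlation from PCR families, and indels. Consequences are spelled out
under Limitations.

The benchmark protocol mirrors the field's in-silico dilution designs: the
simulation substrate is the **empirical cohort-average** rate matrix (so the
fitted models face data generated from their own training summary),
150 of 20,000 rows (about one signal per 140 panel bases, the density of
full-scale 147 kb benchmark runs with 1,000 signals)
receive a fixed allele-fraction signal on the largest-background alternate —
all-zero rows and ties resolve to the first alternate in A-C-T-G order —
and read counts are drawn binomially (a normal-model alternative exists with
sd = sqrt(BMER)/100; the grammatically possible reading sqrt(BMER/100) is
implemented behind a switch but gives noise ten times the mean at typical
rates, which is implausible, so it is not the default). ROC curves sweep
α over 25 log-spaced points in [10⁻⁶, 0.5]; AUC is the trapezoid over
(1 − specificity, sensitivity) with (0,0) and (1,1) anchors, since polishing
curves never reach the top-right corner on their own (zero-observation
entries are polished at every α). Specificity counts all modeled non-signal
(position, alternate) entries in the denominator, matching the per-alternate
decision granularity.

## Numerical choices

- Coordinates are 1-based inclusive internally; BED input (0-based
  half-open) is converted at the boundary.
- Germline masking threshold 0.05 applies both during background building
  and in the panel-wide error metric (numerator-only: the error-rate
  denominator is total reads).
- ν̂ cap 10⁶; prior-fallback entries are flagged `prior_fallback`.
- Negative normal-model draws truncate to zero; counts round
  half-away-from-zero. Structural zeros (rate exactly 0) stay exact.
- Pathological draws with alternate counts exceeding coverage are capped
  proportionally and logged (unobserved at realistic rates).
- All randomness flows through `numpy.random.default_rng`; identical seeds
  reproduce tables byte-for-byte.

## Test problem sizes

Desk-scale defaults keep the full suite fast while preserving the published
densities: 20,000-position panels with 150 spiked signals for benchmark
replicates (five seeds, cohorts of 7 and 14), 10,000 beta draws for
moment-recovery checks, and small hand-built panels for exact worked
examples. Full-scale (147k-position) runs are a matter of passing larger
arguments; nothing in the code is specific to the reduced sizes.

## Known limitations

- **The Gaussian baseline is strong under the generator's assumptions.** In
  a simulation where across-subject variation is exactly binomial and the
  baseline's per-entry mean equals the generative rate, the floored Gaussian
  ranks entries nearly optimally. In that regime the context model's
  measured advantage concentrates where it was designed to help — smaller
  cohorts: halving the cohort from 14 to 7 subjects costs the context model
  less ROC area than the Gaussian baseline in every replicate measured. At
  full cohort size the two methods' AUCs are within ~1% of each other, and
  which one leads can hinge on one or two spiked entries that draw ≤1 read:
  the Clopper–Pearson bound can never retain a single read at α ≤ 0.5
  (`B ≥ 1 − 0.25^(1/N) ≈ 1.2×10⁻⁴` at N = 12,000), while the floored
  Gaussian retains singletons at ~z·10⁻⁵. On real cohorts — with
  overdispersion and unstable empirical sds — the Gaussian baseline is
  expected to fare worse than it does here; passing or failing the
  synthetic benchmark therefore bounds behavior under the model's own
  assumptions, not on real data.
- The strand split is bookkeeping only; no strand-consistency filter enters
  the decision rule.
- Indels, multi-sample joint calling and downstream variant calling are out
  of scope: the polisher only edits counts.
- Real panels leave some contexts thinly populated; their priors rest on few
  positions and, for absent contexts, on the pooled fallback.
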