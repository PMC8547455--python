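# Methods

## The measurement model

A manipulation experiment relaxes two controls on a bacterioplankton
community: prefiltration (1.2 μm) removes nanoflagellate grazers
(top-down release, treatment F), and a phosphate amendment relaxes
phosphorus limitation on top of that (bottom-up release, treatment F+P);
an unmanipulated control (C) runs alongside. Each treatment is incubated
in replicate bottles and subsampled every ~12 h for sequencing.

Before filtration every subsample is spiked with a fixed volume of an
internal-standard cell suspension per volume of sample, so the standard
contributes a constant number of cells per ml across all samples. After
sequencing, the read count of phylotype *i* in sample *s* is modelled as
a multinomial draw whose expected share is proportional to
*b·A(t)*, where *A* is abundance (cells ml⁻¹) and *b* a
phylotype-specific amplification-bias factor assumed constant across
samples. The normalization ratio

r(i, s) = reads(i, s) / reads(standard, s) = (bᵢ/b_S) · Aᵢ(t)/S

is therefore proportional to absolute abundance; the unknown factor
bᵢ/b_S is constant per phylotype. Two exact invariances follow and are
enforced by tests: multiplying all counts of a sample by any factor
(sequencing depth) leaves its ratios unchanged, and multiplying one
phylotype's counts by a constant shifts its log-curve vertically without
changing any slope.

## Rate estimation

For exponential growth, ln r is linear in time with slope μ (day⁻¹).
Each replicate bottle's series is fitted separately by OLS of ln(ratio)
on time in days over a closed window, default 0–24 h — the period over
which growth in such incubations is exponential. The log-scale linear
fit (rather than nonlinear least squares on the ratio scale) is the
standard choice under multiplicative, approximately lognormal noise, and
makes R² well-defined on the regression actually performed.

Numerical choices:

- zero ratios inside the window are dropped, not pseudocounted; a
  replicate left with fewer than `min_points` (default 3) positive
  values fails. Phylotypes that are mostly absent thus fail the gate
  naturally instead of receiving invented counts;
- a fit passes only if R² > 0.6 (strict) — a reliability gate against
  non-exponential or noise-dominated series;
- a perfectly flat series has zero total variance; it is scored R² = 1
  (the line is exact) with slope 0 rather than undefined;
- window endpoints are inclusive; the per-phylotype rate is the
  arithmetic mean over passing replicates, with the sample SD (n−1)
  reported when at least two pass; a cell with no passing replicate is
  reported missing, never zero.

Community ("bulk") summaries are the mean, sample SD and quantiles of
the per-phylotype rates per treatment. Net growth rates from absolute
cell counts use μ = ln(n₂/n₁)/Δt; ratio-based rates track gene-copy
number and can transiently exceed count-based rates when DNA replication
runs ahead of division (unbalanced growth), which is why the comparison
table reports signed differences per group.

## Prevalence filter

A phylotype is kept iff it reaches `min_count` reads in at least
`min_fraction` of all samples (treatments pooled). Presets: 10 / 15 %
for whole-community 16S libraries, 3 / 15 % for sparser functional-gene
(*puf*M) libraries. On realistic long-tailed communities this removes
the large majority of features while discarding only a few percent of
reads. The internal standard is always protected from filtering, and is
excluded from every downstream community statistic.

## Response classification

For each phylotype with rates in the needed treatments, two fold changes
are formed: F/C (response to grazer removal) and F+P/F (response to
phosphate). A fold change is missing when its denominator is missing or
non-positive. With threshold T (default 1.3, the fixed literature value;
alternatively derived as a percentile — default the 25th, linear
interpolation between order statistics — of the pooled finite fold
changes), the partition is:

| | F+P/F > T | F+P/F ≤ T |
|---|---|---|
| **F/C > T** | I (both controls relax) | II (grazing-released only) |
| **F/C ≤ T** | III (P-stimulated only) | NR (no response) |

"Weak" is inclusive (≤ T). Records with a missing fold change get NA.
No significance testing is layered on top of the threshold rule: the
grouping is operationalized purely by the fold-change cut. Taxon-level
aggregation reports the mean of each finite fold-change column and the
group composition fractions per taxon at a chosen rank.

## Diversity summaries

Shannon H = −Σ pᵢ ln pᵢ (natural log by default; the 4–5 range typical
of coastal seawater at ASV level presumes natural-log units) and
Bray–Curtis dissimilarity, both computed with the internal standard
excluded and optional exclusion of whole-table singletons. Ordination is
out of scope.

## The synthetic-data generator

The generator emulates the statistical structure of the reference
design — 3 treatments × 3 replicates × 6 time points (0–60 h), library
sizes ~ Normal(127,018, 15,026) truncated at 1,000, spike of 2×10⁸
cells ml⁻¹ suspension at 5 μl per 100 ml of sample (10⁴ standard cells
per ml) — with deterministic exponential growth per phylotype and all
randomness entering through initial abundances, PCR bias, and
multinomial sequencing. Default archetypes (all day⁻¹):

- control rates U(0.1, 0.9): slow growth under grazing pressure;
- top-down release factor U(1.8, 5.5) for groups I and II, U(0.7, 1.2)
  for III and NR; filtered rates capped at 4.5, putting roughly
  two-thirds of them in 0.6–3.5 with a ~2 % tail above 4;
- bottom-up release factor U(1.4, 2.2) for groups I and III,
  U(0.5, 1.15) for II and NR; F+P rates capped at 6.0. The cap ratio
  6.0/4.5 ≥ 1.3 keeps every group-I phylotype's true fold-change pair on
  its own side of the classification threshold;
- group proportions I/II/III/NR = 0.50/0.15/0.25/0.10;
- initial abundances lognormal(ln 250, 0.8) cells ml⁻¹;
- per-phylotype bias lognormal(0, 0.5), constant across samples. The
  standard's own bias factor is fixed at 1: a shared constant only
  rescales every ratio uniformly and cancels in all slopes, and leaving
  it random merely injects a nuisance global scale;
- growth plateaus (hard truncation) at 24 h — the end of the exponential
  window, so the plateau never intersects the fitted region. Combined
  with the abundance scale and rate caps this was calibrated once, before
  freezing, so that the standard's read share stays within roughly
  0.2–14 % across samples and seeds: always quantifiable (no zero
  denominators), never dominant.

Seeding is hierarchical (one seed spawning per-phylotype and per-sample
substreams), so simulations are bit-for-bit reproducible and adding a
phylotype does not perturb the draws of the others. An expectation mode
replaces sampling with exact expected (fractional) reads, which makes
pipeline identities exact for fixture construction.

What the generator does **not** emulate: demographic stochasticity, lag
phases, death or predation dynamics in the control (slow exponential
growth stands in for the grazing-balanced state), reads-level artifacts
(sequencing error, chimeras), taxonomic misassignment, or covariation of
bias with abundance. Passing recovery tests therefore demonstrate that
the estimator chain is correct and bias-robust under the stated model,
not that real libraries satisfy that model.

## Problem sizes and determinism

Tests and the acceptance script run the default 200-phylotype design
(54 samples, ~1,800 replicate regressions), which completes in seconds;
property tests use smaller fixtures. All stochastic tests are seeded,
and the hypothesis profile is derandomized, so the suite is
deterministic end to end.

## Known limitations

- Ratio-based rates are gross gene-copy rates; under unbalanced growth
  they lead cell-division rates by up to one sampling interval.
- The bias-constancy assumption fails if amplification efficiency
  changes with template concentration; the ratio is then only
  approximately proportional to abundance.
- The R² gate preferentially discards slow growers (signal comparable to
  multinomial noise), so control-treatment coverage is lower than
  filtered-treatment coverage, and fold changes inherit that missingness.
- The percentile threshold depends on which fold-change distribution is
  pooled; the default pools both columns, and the fixed 1.3 default
  matches the published grouping exactly.
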