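# Methods

## The analysis model

`venomcomp` treats a bulk venom-gland RNA-seq experiment as a small-n,
two-group comparison of *compositions*. Each individual's expression is a
TPM vector on the 10⁶-sum simplex; only relative information is
meaningful. The pipeline makes three kinds of inference:

1. **Presence** of a transcript in an individual, from per-base read
   coverage (abundance is deliberately not used — paralog-aware mappers
   spread multi-mapping reads across family members, so absent transcripts
   can carry nonzero TPM).
2. **Per-toxin expression divergence** between venom types, tested pair by
   pair against an empirical null built from nontoxins.
3. **Summary statistics**: toxin-family composition percentages,
   per-individual toxin counts with a rank-sum comparison, and per-pair
   correlation measures.

### Presence rule

A transcript is present in a sample iff

    #{positions with depth ≥ min_depth} / length ≥ min_covered_fraction

with defaults `min_depth = 5`, `min_covered_fraction = 0.90`. The boundary
is resolved as *present*: only strictly more than 10% under-covered
sequence makes a transcript absent. The rule is monotone in depth (raising
any position's depth can never flip present → absent), which the tests
assert as a property. The same rule, restricted to a curated reference set
(e.g. the six PLA2 paralogs), produces reference-set profiles.

### Zero replacement and clr transform

Zeros must be removed before log-ratio analysis. Simple multiplicative
replacement substitutes δ for each zero and multiplies the nonzero parts by
`1 − n_zeros·δ/total`, so row totals — and all ratios among originally
nonzero parts — are preserved *exactly*. The default δ is 0.65 × the row's
smallest positive value (`fraction_of_min`), a common convention for
continuous compositions; an absolute-δ mode (`multiplicative_simple`) is
available, and the choice is recorded in the clr output's provenance
(`source_params`). δ must stay below the row's smallest positive value;
violating that is an error, not a warning, because the replacement would
then re-rank observed values.

The clr transform is `ln(x) − mean(ln x)` per row, taken over the full
transcript set supplied (toxins + nontoxins when both are available;
toxins-only matrices can be transformed but cannot feed the divergence
test, which needs a nontoxin null). clr is scale-invariant per row and
preserves within-row rank order; both are tested properties.

Per-type average pseudo-individuals are arithmetic TPM means over the
type's samples, appended **before** zero replacement so they flow through
the identical pipeline (average → replace → clr).

### Divergence test

For an (A, B) pair of clr rows, the null distribution is
`{|clr_A(k) − clr_B(k)| : k nontoxin}`; the threshold is its 99th
percentile (linear interpolation between order statistics; the exact
empirical quantile is available via the `interpolation` argument). A toxin
is an outlier iff its |Δclr| **strictly** exceeds the threshold — a tie is
not "outside" — with direction given by the sign. Aggregation over all
n_A × n_B pairs yields per-toxin UpB/UpA counts and Δ = UpB − UpA; the
AveB-vs-AveA comparison is classified Up / Down / No Difference with the
same rule. By construction the per-pair false-flag rate on exchangeable
toxins is (100 − percentile)% ≈ 1%, which the calibration tests verify by
Monte Carlo.

The OLS variant fits least squares of clr_B on clr_A through the
nontoxins and flags toxins outside the level-99% **prediction interval**
(not the narrower mean-confidence band; the choice is deliberate — single
transcripts are new observations, not means). It is a visualization
companion; pair aggregation always uses the absolute-difference rule. Where
both methods flag a toxin they agree on direction (tested).

Pair similarity is reported as Spearman's ρ (average ranks on ties),
Pearson's r, and R² = r², computed separately for toxin and nontoxin
subsets. Zero-variance input yields NaN ("undefined"), never 0.

### Rank-sum test

W = #{(a,b): a > b} + ½·#{(a,b): a = b} over cross pairs. Exact p-values
enumerate all C(n1+n2, n1) labelings of the pooled data (valid with ties;
capped at 2×10⁶ combinations); the approximation uses the tie-corrected
variance with a 0.5 continuity correction, the convention under which the
packaged toxin counts give W = 0, p = 0.019. `auto` picks exact only for
untied, feasible inputs. The `df` field on results echoes n1 + n2 − 2
purely for report fidelity with sources that print one; no t-distribution
is involved. An empirical note from the full enumeration grid
(n1 + n2 ≤ 10): wherever the exact two-sided p is ≤ 0.05 the corrected
approximation never under-states it, but at large p it can sit up to ~0.13
below the exact value (worst for n1 = 1); the approximation is for
moderate samples, not a substitute for exact inference at n ≤ 4.

## Packaged fixtures and their quirks

The study tables ship verbatim as TSVs (comma thousands separators
retained; the parser accepts them and scientific notation). Two internal
inconsistencies in the printed source are preserved rather than silently
fixed:

- The presence matrix's column sum for individual CLP1835 is **64**, while
  the printed "Toxins Present" totals row says **66**. The pipeline counts
  from the matrix; the printed totals ship separately
  (`table3_printed_totals.tsv`) and are the input to the rank-sum
  reproduction, whose published p = 0.019 arises only with the printed 66.
- The published Type A mean toxin count (48.6 ± 6.1) matches neither the
  matrix counts (mean 48.2) nor the printed totals; the package reports
  matrix-derived counts and leaves the discrepancy documented here.

The toxin catalog inferred from the TPM table carries no transcript
lengths (none are printed); lengths are optional in `TranscriptCatalog`
and required only for coverage-based presence calling.

Family assignment strips the trailing `-number` from a transcript id, with
an explicit override map sending the six PLA2 paralog names (Pla2gA1,
Pla2gB1, Pla2gK, Pla2gA2-MTXA, Pla2gB2-MTXB, PLA2-6) to family `PLA2`.
SVMPII and SVMPIII are distinct families. This yields the 17 families of
the source catalog.

## The synthetic-data generator

The generator emulates exactly the features the analysis consumes:

- **Design**: n_A = 5 vs n_B = 4 individuals (the study design) by
  default; a 75-toxin catalog with the real family sizes; 1889 nontoxins.
- **Presence structure**: per-family blocks (`A_only`, `B_only`,
  `shared`, `mixed`; `mixed` draws each transcript's pattern with
  probabilities 0.5/0.25/0.25). Defaults confine SVMPs to Type B and mix
  CTL/MYO/PLA2 patterns, mirroring the venom dichotomy.
- **Expression**: per-transcript baselines ~ Normal(5, 2) on the natural-log
  TPM scale, within-type noise sd 0.8, closure to 10⁶. Group-exclusive
  toxins get a +4 ln-unit baseline boost: venom-type-diagnostic toxins
  (Mojave toxin, SVMPIIIs) are dominant venom components at 10⁴–10⁵ TPM in
  the real data, and without the boost a trace-level "exclusive" toxin is
  not meaningfully distinct from its δ-replaced zero on the clr scale.
- **Spiked effects**: optional per-transcript ln-fold shifts between types
  (positive = up in B) defining the recovery truth; with none, the truth
  outlier set is empty.
- **Coverage**: per-base independent Poisson depth for present
  transcripts, mean proportional to relative abundance but floored at 12×
  (`present_depth_floor`) — a floor near the 5× calling threshold would
  leave >10% of positions under-covered and contradict the generator's own
  truth table, whereas at 12× fewer than 1% of positions fall below 5×
  and presence recovery is near-certain for lengths ≥ 300 nt. Absent
  transcripts get zero depth over a dropout stretch (default 50% of
  positions) and sub-5× depth elsewhere. Depth is simulated for toxins
  only by default (`coverage_transcripts`), since the presence stage reads
  nothing else; `"all"` is available.

What the generator does **not** model — and what passing tests therefore do
not establish about real data: count-level (negative-binomial) sequencing
noise, mapping ambiguity among paralogs, assembly and annotation error,
library-size and length biases within TPM, and correlated expression among
family members. The synthetic benchmarks validate the *procedure*
(calibration of the null, recovery of large planted effects, correctness
of the presence rule), not the biological error rates of a real study.

## Numerical choices

- Percentiles: linear interpolation between order statistics
  (`numpy.percentile` default), recorded alongside results.
- Strict inequality at the outlier threshold; ties are never outliers.
- clr row-sum tolerance: |Σ| < 1e-8 × D; zero-replacement row totals
  preserved to 1e-9 relative; these are asserted, not assumed.
- Random streams: a single integer seed per generated dataset
  (`numpy.random.default_rng`); replicate seeds in the acceptance script
  derive from the master seed via `SeedSequence` and stay below 2³¹.
- Benchmarks are sized for quick feedback: null calibration uses 200
  replicate 1×1-pair datasets of 1000 nontoxins + 75 toxins; recovery uses
  the full 5×4 design with eight ±12 ln-unit spikes.

## Known limitations

- The divergence test needs ≥ 2 nontoxins (practically, hundreds) in the
  matrix; the packaged toxin-only table supports presence/composition
  summaries and the rank-sum test, but not the pairwise null — the source
  study's 1889 nontoxin expression values are not published, so its
  pairwise outlier counts are validated structurally on synthetic analogs
  rather than numerically.
- Exact rank-sum enumeration is exponential; beyond ~2×10⁶ labelings the
  corrected approximation is required.
- The per-pair tests are not independent (each individual participates in
  several pairs); UpB/UpA counts are descriptive tallies, not calibrated
  joint inference, and no multiple-testing correction is applied — by
  design, matching the method being reimplemented.
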