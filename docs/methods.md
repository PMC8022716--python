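# Methods

## The detection model

A Chi-like motif is called in a species when two independent signals
coincide:

1. **Core-genome overrepresentation.** The word's count on the
   species' (pseudo-)core gene sequences exceeds its expectation under
   Markov null models of the sequence composition. Orders 0–5 are
   scored, i.e. from mononucleotide up to hexanucleotide composition,
   and the word must clear the z-threshold under at least
   `min_models` = 3 of them. Requiring several orders protects
   against a bias at one compositional scale masquerading as signal.
2. **Replication-strand polarity.** On the whole replicon, the start
   positions of forward-strand matches and of reverse-complement
   matches are compared with a two-sample Wilcoxon rank-sum test. A
   leading-strand-biased motif switches strand at ori and ter, so the
   two samples separate positionally even when ori/ter are unknown.
   Significance at `alpha` = 0.001 (two-sided) is required.

In `unpolarized` mode the second clause is dropped (it is still
computed and reported), mirroring the relaxed search for species where
polarity may not be required.

## Word statistics

For word *w* of length *h* under order *m*, the expectation is the
plug-in estimator built from the k-mer counts of the scored sequences
themselves:

Ê_m(w) = ∏_{j=1}^{h−m} N(w_j…w_{j+m}) / ∏_{j=2}^{h−m} N(w_j…w_{j+m−1}),

with N(empty) the total number of 1-mer windows. At h = m+1 the
denominator product is empty and the estimator degenerates to the
observed count — asserted directly in the tests. Counting is
overlapping, never crosses sequence boundaries, and skips any window
containing N. Counts are taken on the given strand only (core genes
are extracted coding-strand 5'→3'; no reverse-complement pooling),
because Chi function is strand-specific.

**Variance.** The normative estimator is a parametric bootstrap:
fit the order-m chain on the core, simulate B = 200 sequence sets with
the same per-gene lengths (initial contexts from the empirical m-mer
distribution; unseen contexts fall back to order 0), and take the
sample sd of the word count. It is fully specified, seed-controlled,
and verifiable. An analytic asymptotic variance

Var(N) ≈ Σ_seqs [ nμ(1−μ) + 2 Σ_{d=1}^{h−1} (n−d)(P_d − μ²) ]

(μ the stationary word probability, P_d the self-overlap joint
probability at lag d, covariances at lags ≥ h neglected) is provided
as a fast path; a gating test requires |z_analytic − z_bootstrap| ≤
0.3 at B = 1000 on fixture cores. The bootstrap remains the default.

**Calibration and its limits.** On cores simulated from the fitted
null, z for a non-self-overlapping octamer is standard normal to good
accuracy (measured mean within ±0.15, sd within 0.85–1.15 across
orders 0–2 at 500 kb). The *tail* is another matter: at desk-scale
core sizes an octamer's expected count is small (~3 per 200 kb), the
count distribution is Poisson-like and right-skewed, and the z ≥ 4
exceedance rate across all 65,536 octamers sits nearer the Poisson
tail (~10⁻³) than the normal tail (~3×10⁻⁵). The de novo scan's
calibration test therefore benchmarks exceedances against the Poisson
tail computed from the fitted expectations. The candidate criterion is
robust to this because planted signals score z ≫ 4 and the polarity
clause multiplies in an independent ~10⁻³ filter.

**Thresholds.** The per-order z-thresholds default to 4.0 with
K = 3 models required; both are explicit `DetectionConfig` fields, and
the z-scores of a reference motif in a reference species' core can be
used to recalibrate them where an anchor species is available.

## Polarity test details

Exact enumeration (no ties) is used when the smaller strand sample has
≤ 25 occurrences, the normal approximation with tie and continuity
corrections otherwise; an in-repo brute-force enumeration over all
rank placements serves as the oracle in tests. Fewer than
`min_per_strand` = 3 occurrences on either strand makes the test
indeterminate, which never counts as polarized — complete absence on
one strand is strand bias of a kind, but the two-sample test is
undefined there and a conservative fail is safer. Positions are used
as given in the assembly (no rotation optimization). Polarity is
evaluated on the largest replicon by default (the chromosome carries
the replication structure); pooling all replicons is available by
configuration. A complementary same-strand run statistic (fraction of
position-adjacent occurrences on equal strands, permutation null) is
provided; note that with the label-permutation null an occurrence set
living entirely on one strand is degenerate and yields p = 1.

## Pseudo core genome

Genes shared with the two phylogenetically closest species, by best
reciprocal hits. Choices the upstream literature leaves open are fixed
explicitly:

- **Distance:** p-distance (mismatches over mutually ungapped columns)
  on the trimmed concatenated marker alignment, or a user-supplied
  matrix. Ties in neighbor ranking break lexicographically.
- **Trimming:** a per-column gap-fraction filter (default ≤ 0.5)
  stands in for heavier alignment trimmers; only the distance ranking
  feeds the pipeline, not the trimming details.
- **Alignment:** global (Needleman–Wunsch) with match +1, mismatch −1,
  gap open −5, gap extend −1, via Biopython's PairwiseAligner;
  identity = matched columns / full alignment length (gap columns in
  the denominator — the stricter, deterministic variant). Identities
  are computed once per unordered pair, making the BRH relation
  symmetric by construction; best-hit ties break lexicographically.
- **Thresholds:** identity ≥ 0.70 and min(len)/max(len) ≥ 0.80.

Note the scales: the 70% threshold applies to *protein* identity. At
75% *nucleotide* identity, protein identity is near 50% and genes are
correctly excluded; the recovery bands quoted in the tests
(≥ 0.75 recovered, ≤ 0.60 excluded) are on the protein scale, measured
post hoc on the true (indel-free) alignment recorded by the trio
simulator.

## Synthetic data

The generator emulates the study conditions, not arbitrary inputs:

- **Backgrounds:** order-0 chains with configurable GC (default 0.5),
  or order-m chains fitted on a template. Genomes are circular by
  default so the junction-scan rule is exercised.
- **Planting:** Poisson(length/1000 × density) non-overlapping sites,
  default density 0.2/kb — one site per 5 kb, the *E. coli* Chi
  density. Each site goes on the leading strand of its replichore
  (forward on the ori→ter arc) with probability `polarization_level`
  (default 0.9, approximating "almost exclusively" leading-strand).
  Planting overwrites the background in place, preserving length and
  ori/ter geometry; chance background occurrences of the motif are
  possible and are simply additional true occurrences, so sensitivity
  is computed against planted sites.
- **Species trios:** ancestor genes as random sense codons; relatives
  derived by per-site point mutation to a target nucleotide identity,
  with codons that would introduce internal stops re-drawn. Realized
  nucleotide and protein identities per gene are returned as truth.

What the generator does *not* emulate: real gene-content evolution,
codon usage and amino-acid composition bias, repeats, horizontal
transfer, assembly gaps beyond literal N handling, or rearrangements
that decouple replichore structure from coordinates. Passing tests
demonstrate correctness and calibration of the statistics under the
stated model, not performance on any particular clade.

## Numerical and algorithmic choices

- Sequences are handled internally as int8 code arrays (A,C,G,T →
  0–3, N → −1); concatenating genes with a −1 break makes boundary and
  N handling fall out of the same window-validity rule. Chain
  simulation and word counting are numba-compiled; bootstrap
  replicates use a fused simulate-and-count kernel (all 4^h counts per
  replicate via a rolling window index), which is what makes the de
  novo scan over 65,536 octamers and B = 200 bootstraps tractable on
  one core.
- All randomness flows through `numpy.random.Generator` seeded
  explicitly; per-order and per-replicate streams are spawned from a
  root `SeedSequence`, so every table is bit-reproducible.
- Zero denominators in Ê, or zero bootstrap sd, mark the statistic
  non-evaluable; a non-evaluable order counts as NOT passed
  (conservative).
- Parsimony uses unit-cost Sankoff up/down dynamic programming
  (handles polytomies); per-node sets contain exactly the states
  achievable in some most-parsimonious reconstruction, so tied
  gain-vs-loss scenarios are reported, not resolved. Equal gain and
  loss costs.
- Problem sizes in the test suite (500 kb calibration cores, 1 Mb
  end-to-end genomes, 20 + 20 species, 100 bootstrap-calibration cores
  per order) were chosen as the smallest sizes at which the measured
  quantities are stable against their stated bands; the acceptance
  script uses 500 kb genomes with 8 + 8 species for the same reason.

## Known limitations

- The Gaussian z is anti-conservative in the extreme tail for
  low-expectation words (see calibration above); compound-Poisson or
  exact p-values for rare words are out of scope.
- The two-mismatch expansion uses a ball-exclusion rule (distance
  exactly 2 from ≥ 1 seed, ≥ 2 from all); under it the five frequent
  Chi variants yield 841 motifs. Published counts based on other,
  unstated redundancy rules (e.g. 830) are reported alongside, not
  forced.
- Polarity on heavily rearranged chromosomes (where replichore arcs
  are not coordinate-contiguous) loses power; no ori/ter inference or
  GC-skew analysis is attempted.
- Window-extracted cores that ignore gene strand will show a planted
  motif and its reverse complement as two signals (visible in the de
  novo example); coding-strand extraction via GFF features avoids
  this.
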