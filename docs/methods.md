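# Methods

This note documents the statistical procedures, their parameterisation, the
numerical conventions, and the design decisions taken where the published
record under-determines them. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A `Dataset` holds distinct haplotypes as state vectors over the *coded
polymorphic sites* of an alignment, plus per-population gene-copy counts
and coordinates. Indels are treated as substitutions: a gap run shared
across sequences collapses to one presence/absence site, so a 5-bp deletion
is one mutational step and the effective length is
`L_eff = L − Σ(run_length − 1)`. For the chloroplast fixture this gives
`L_eff = 858 − 4 − 8 = 846` (two multi-base runs of 5 and 9 bp; three
single-base indels leave the length unchanged). Diploid input contributes
two phased sequences per individual; phase is an input, never inferred
here.

The packaged fixtures transcribe the source study's tables: per-population
haplotype counts, the two haplotype state matrices, and degrees-minutes
coordinates (`deg + min/60`). The tables' per-population diversity values
reconcile only when the printed "n" column is read as the number of
distinct haplotypes and the true copy number is taken from the sampling
table (×2 for the diploid locus); the fixtures store copy numbers.
`fixture_alignment()` renders a synthetic per-copy alignment (filler bases
at monomorphic columns, gap runs of the published lengths at nominal
coordinates — exact indel positions are not recoverable and do not matter
for any statistic), which round-trips through the FASTA reader and
haplotype caller back to the tables.

## Diversity and neutrality

* `h` uses Nei's unbiased `n/(n−1)` correction and no further small-sample
  adjustment.
* `K` is computed from haplotype frequencies and the coded-site distance
  matrix; a brute-force mean over all expanded copy pairs is the test
  oracle.
* `π = K / L_eff`.
* Tajima's `D` uses the standard `a₁, a₂, b, c, e` coefficient chain with
  `S` = segregating coded sites. Fu & Li's `D*` uses the corrected
  closed-form variance coefficients with `η = S` (no multiple hits at these
  divergence levels) and `η_s` = sites whose rarer state occurs in exactly
  one copy.
* Significance is reported DnaSP-style as bands, not exact p-values:
  Tajima's `D` through the rescaled-beta approximation to its null range;
  `D*` against a conservative ±1.7/±2.1 envelope that brackets the
  published 5%/2% critical points at these sample sizes.
* `Rm` is the Hudson–Kaplan maximum number of non-overlapping site
  intervals failing the four-gamete test, restricted to biallelic coded
  sites; an exhaustive pair scan with optimal interval packing is the test
  oracle.

## Differentiation

`G_ST = 1 − h_S/h_T` and the ordered-allele `N_ST` share one construction:
a within-population diversity averaged across populations and a total
diversity from mean haplotype frequencies, with the 0/1 mismatch indicator
(G) or the pairwise mutational-step matrix (N) as the metric. The original
analysis program's exact estimator variant is unpublished; a systematic
comparison of weighting and correction variants against the study's printed
values selected:

* `h_S`: the **sample-size-weighted** mean of per-population unbiased
  diversities `n_k/(n_k−1)·(1 − Σ x²)` — the unweighted mean, despite
  being the textbook presentation, reproduces the printed values less well;
* `h_T`: the diversity of the **unweighted** mean haplotype frequencies
  across populations, with no additional sample-size correction.

This reproduces the printed chloroplast values to ~0.001 and the nuclear
G_ST exactly at three decimals; the nuclear N_ST agrees to 1.6%. No variant
we tested reproduces all four printed values at three decimals, so
acceptance asserts 2% agreement for this family.

The `N_ST > G_ST` test permutes haplotype identities in the distance
matrix (rows and columns jointly), holding frequencies fixed; `U` is the
permutation-standardised difference and `p` the one-tailed exceedance.
With 10,000 permutations the chloroplast difference is non-significant
(p ≈ 0.5) and the nuclear difference significant at 0.05 (p ≈ 0.03) — the
source reports p < 0.01 from an unpublished parametric U test; our
permutation construction does not reach that band and we report it as
computed.

**AMOVA** is the one-level Excoffier partition of squared inter-copy
distances with variance components from the moment equations
(`n' = (N − Σn_k²/N)/(K−1)`); negative components are reported as computed.
The default metric is **haplotype identity** (0/1): the study's printed
AMOVA table (sums of squares, variance components and percentages for both
loci) reproduces exactly under this metric and under no distance-weighted
variant, so the identity metric is the fixture convention; mutational-step
distances are available via `metric="steps"` and are what the simulator
calibration uses (the identity metric saturates when most copies carry
unique haplotypes). The permutation p reassigns copies to populations with
sample sizes fixed. Pairwise `F_ST` is the two-population case; pairs of
populations fixed for the same haplotype have no variance to partition and
are reported as NaN.

## Isolation by distance

Mantel correlation over population pairs between a transform of pairwise
`F_ST` and `ln(km)` (haversine, R = 6371.0088 km), excluding undefined
pairs and zero-distance pairs; significance by joint row/column permutation
of the genetic matrix, one-tailed for the observed sign. Two transforms are
provided: the default **Slatkin linearised distance** `F/(1−F)` and the
island-model gene-flow measure `M = (1/F − 1)/2`; `F` is clipped to
[0.0025, 0.9975] so fixed or undifferentiated pairs stay finite. The
distance-like default reproduces the study's nuclear correlation
(r ≈ 0.226 vs printed 0.234) with the printed significance; the study's
*negative* chloroplast correlation (−0.1134) is not reproducible under any
single transform we examined (the reconstructed chloroplast F_ST matrix
correlates weakly *positively* with distance once the 21 undefined
fixed-identical pairs are excluded; the gene-flow transform recovers the
sign but then inverts the nuclear result). The chloroplast value is
reported as computed; the qualitative conclusion — no significant
chloroplast isolation-by-distance signal — is unchanged.

## Networks and nesting

The 95% **parsimony connection limit** is the largest step count `j` with
`P_j = Π_{i<j}(1 − i/2m) > 0.95`, a birthday-type approximation treating
each successive change as needing to avoid the site×lineage combinations
already hit. It yields 11 steps at 627 bp and 13 at 858 bp — in line with
limits reported by statistical-parsimony software for such lengths — and
exceeds the maximum observed pairwise distance at both loci, so each
fixture network is a single component.

When all coded sites are mutually compatible (true for both fixtures —
`Rm = 0` — and for every infinite-sites simulation), the network is built
as a **perfect phylogeny**: binary splits become a laminar family of
carrier sets, internal nodes are shared inferred intermediates, and the
total edge length attains the parsimony bound of one step per mutation
(test oracle; note this beats a minimum spanning tree over observed
haplotypes, which cannot share intermediates). Incompatible data fall back
to ascending-distance Kruskal joining with chain intermediates, recording
equally short alternatives as ambiguities. Ties favour the
higher-frequency hub, then identifier order.

**Nesting** is tips-inward agglomeration: terminal nodes unite with their
interior neighbour; leftover adjacent nodes unite with each other;
stranded nodes join the adjacent clade with the *lower* total observed
frequency (both of the study's stated memberships — the western chlorotype
triple and the assignment of the widespread clade at the 2-step level —
force this tie-break). The procedure repeats on the clade graph until the
total cladogram. Inferred-intermediate-only units are retained as clades
(they are needed as nesting units) but excluded from geographic testing.
Consequence for the fixtures: the chloroplast design has 7 one-step and 3
two-step clades with the published memberships; the nuclear design has 3
two-step clades and 6 one-step units of which 5 contain observed
haplotypes — the source prints 5, evidently not counting an empty unit,
but applying that convention to the chloroplast network would yield 6, not
the printed 7, so no single counting convention matches both and we retain
all units.

**NCPA**: `Dc` is the frequency-weighted mean great-circle distance of a
clade's observations from their weighted spherical centroid (3-D vector
mean projected back — samples span >5° of longitude, so a planar mean
would distort); `Dn` uses the nesting clade's centroid. Permutation
reshuffles copies' subclade labels against locations within each nesting
clade (10,000 default); small/large flags at 5% feed an **inference key**
encoded as a versioned JSON decision tree (questions are named predicates
over the aggregate flag pattern plus a range-overlap predicate), returning
a conclusion category and the chain of answered steps. The number of
significant clades is scheme-sensitive and stochastic; acceptance asserts
it only within a broad band.

## Dating

K2P distance `d = −½ln(1−2P−Q) − ¼ln(1−2Q)` with transitions/transversions
classified per site; indel-coded sites are excluded and the denominator is
the substitution-eligible length. Net divergence weights haplotypes by
observed frequency (uniform weighting available). `T = d_A/2μ` is reported
in MYA for the rate range 1.0–3.0 × 10⁻⁹ substitutions·site⁻¹·year⁻¹
(synonymous chloroplast sites in seed plants), the fast rate giving the
lower bound; negative `d_A` is flagged non-estimable.

## Simulator

`simulate_island_model` draws from a finite-island structured coalescent
(msprime): `n_pops` demes of size `N0` (default 1000), `theta` the
per-locus scaled mutation rate of one deme (default 3), `migration` the
scaled migrant-copy number `2N0m` (default 1), samples of
`copies_per_pop` haploid copies (default 10 from 8 demes, emulating the
study's sampling design of ~10 copies per population). Mutations are
placed on a fixed-length site lattice with one column per mutation
(collisions resampled; an error is raised if mutations exceed columns), so
simulated data are always compatible — matching the haplotype-table data
model with no multiple hits and no recombination. Coordinates lie on a
0.5° lattice near 24°N 100°E; fragmentation scenarios offset the second
region eastwards, split the ancestral pools `fragmentation_split_time`
generations ago (regions stop exchanging migrants), and optionally seed a
corridor deme in region B from region A's pool.

What the simulator does *not* emulate: selection, recombination,
intra-population spatial structure, sequencing error, and phase
uncertainty. Passing calibration tests therefore demonstrate estimator
correctness and test validity under neutral, correctly phased,
non-recombining data — not robustness to those complications.

## Problem sizes used by the test suite

Calibration tests run at deliberately modest scale chosen to keep
Monte-Carlo error well inside the asserted bands: type-I error of the
`N_ST>G_ST` test on 300 seeded panmictic replicates (5 demes × 8 copies,
99 permutations; binomial SE ≈ 1.3%), G_ST monotonicity on a 5-point
migration grid × 25 replicates, fragmentation-inference calibration on 40
replicates with 99 permutations, and π-unbiasedness on 120 replicates of
50 copies. Fixture permutation tests use 10,000 permutations where a band
is asserted and 100–2,000 where only reproducibility is.

## Known limitations

* The G_ST/N_ST estimator family and the NCPA permutation scheme
  approximate unpublished program internals; residual disagreements with
  the printed values are enumerated above and asserted at the tolerances
  stated.
* The inference key covers the major conclusion categories (fragmentation,
  restricted gene flow ± isolation by distance, range expansion,
  long-distance colonization, inconclusive), not every leaf of the full
  published key.
* The connection-limit calculus is an approximation calibrated to the
  characteristic output of statistical-parsimony software, not a
  re-derivation of the original appendix.
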