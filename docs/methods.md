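# Methods

## Scope and model

`ehhscan` implements the haplotype-homozygosity family of selection scans for
a two-population SNP-array design: one test population contrasted with a
pooled reference of related populations.  The analysis chain is

1. marker QC (minor-allele frequency, call rate) and sample QC (missingness),
2. relatedness filtering by method-of-moments IBD (PIHAT),
3. LD pruning,
4. ancestral-allele polarization against outgroup species,
5. iHS within the test population; Rsb and XP-EHH between populations,
6. normal-theory p transform and sliding-window candidate-region calling,
7. cross-method intersection and gene annotation,

with IBS/MDS and neighbor-joining structure diagnostics alongside, and a
Wright–Fisher forward simulator that generates the phased two-population
input with known ground truth.

## EHH, iHH/iES and the three statistics

For a focal marker and core allele with `n_c ≥ 2` carriers, EHH at extent `t`
is the probability that two carrier haplotypes drawn without replacement are
identical at every marker from the core to `t`:
`EHH(t) = Σ_h n_h(n_h−1) / (n_c(n_c−1))` over identity classes `h`.  The
pooled site-EHH (EHHS) applies the same formula to *all* haplotypes, with
identity classes seeded by the core-allele split, normalized by its value at
the core so every curve starts at 1.  Both are computed by incremental
partition refinement walking outward from the core, which is exactly
equivalent to hashing full haplotype substrings at every extent (asserted
against such an oracle in the tests).  Curves are non-increasing by
construction.  A monomorphic core yields a well-defined flat EHHS curve; such
markers are excluded from iHS (undefined there) but scored by the
cross-population statistics, whose very target is alleles fixed in one
population.

A side of a curve ends when it falls below the **cutoff** (default 0.05, the
conventional choice; configurable) or at the chromosome border.  Integration
is trapezoidal over physical distance in bp, clipped by linear interpolation
at the first cutoff crossing; the two side areas are summed into iHH
(allele-specific) or iES (site-specific), in bp·EHH units.  Under the default
**border policy** (`discard`) a marker whose curve reaches a chromosome end
before crossing the cutoff is dropped, matching the behavior users of the
standard toolchain expect; `keep` integrates the truncated side as observed.
Physical distance is used throughout (array data rarely come with a genetic
map); there is no gap penalty by default, but a `max_gap` guard can drop a
side that jumps a larger inter-marker gap.

- **iHS**: `ln(iHH_A / iHH_D)` per marker, binned by derived-allele frequency
  into 20 equal-width bins merged left-to-right until each holds ≥ 10 scored
  markers, then standardized to zero mean / unit sd within each bin (the bin
  counts are package defaults; the binning variable and standardization are
  the statistic's definition).  Markers with < 2 carriers of either allele,
  a discarded integral, or a non-positive integral are excluded with a
  per-marker status.
- **Rsb / XP-EHH**: `ln(iES_test / iES_ref)` per marker, centered on the
  median (Rsb, robust as in its source definition) or the mean (XP-EHH) and
  scaled to unit sd.  Positive scores mean elongated homozygosity in the
  test population.  One pooled, normalized EHHS definition feeds both
  statistics; they differ only in centering.  This shared definition is a
  known divergence risk against implementations that use slightly different
  site-EHH normalizations for the two statistics.

Scores are mapped to `pscore = −log10(1 − 2|Φ(z) − 0.5|) = −log10(2Φ(−|z|))`,
computed through the log survival function so extreme scores never overflow.
`pscore = 2.5` corresponds to `|z| ≈ 2.9515`.

## Window rules and intersection

Markers with pscore ≥ 2.5 are significant.  Windows are anchored at position
0 of each chromosome (the anchor is a package convention) and cover
`[k·step, k·step + window)`; a window qualifies with ≥ `min_sig` significant
markers — 2 Mb / 20 kb / 3 for iHS, 1 Mb / 10 kb / 4 for Rsb and XP-EHH.
"Neighboring SNPs" is read as "within the same window", the only reading
compatible with the window/step machinery.  Overlapping or abutting
qualifying windows merge, and each merged span is trimmed to its outermost
significant markers, so reported bounds are marker positions.  Region calling
re-sorts markers by position and is order-invariant; each region stores a
recountable significant-marker total and peak pscore.

Intersection enumerates every combination of ≥ 2 methods with one region per
method; a non-empty common overlap (≥ 1 bp) is reported with the
*intersection* interval (the conservative choice; `--union` reports unions)
and the union of contributing methods.  Pairwise overlaps strictly dominated
by a higher-order overlap are dropped, so a three-way hit is reported once
with all three methods.  Single-method regions are retained separately.
Annotation reports any gene interval overlapping a region by ≥ 1 bp (genes in
BED 0-based half-open convention, regions 1-based inclusive internally; BED
conversion happens only at the file boundary).

## QC and relatedness

Markers with MAF ≤ 0.01 or call rate ≤ 0.95 are removed (inclusive cutoffs),
then samples with > 5% missing calls, then relatedness, then LD — a fixed,
logged order so the data-reduction arithmetic is auditable (every stage
records input − removed = output and the chain is checked).

PIHAT follows the method-of-moments IBD construction: observed IBS 0/1/2
counts per pair are equated to their expectations under sample allele
frequencies to solve for P(IBD = 0, 1, 2), truncated to [0, 1] and
renormalized; PIHAT = P(IBD=2) + ½·P(IBD=1).  It is computed within each
population by default (a pooled flag exists).  One member of each pair with
PIHAT ≥ 0.15 is removed, deterministically: higher missingness first, then
higher mean PIHAT to the remaining samples, then the lexicographically later
id.  On a *single simulated chromosome* PIHAT is noisy — the markers form one
linkage block, so the effective number of independent loci is small and some
unrelated pairs cross 0.15 by chance; on genome-wide input the estimator
behaves as intended (verified on unrelated/parent–offspring/duplicate HWE
simulations: 0 / 0.5 / 1 within tolerance).

LD pruning is the greedy 50-marker / 5-step sliding window on squared Pearson
correlation of {0,1,2} dosages (r² > 0.5 removes the lower-MAF member, ties
drop the later position), repeated until a full pass removes nothing —
idempotent by construction, and never comparing markers across chromosomes.

## Polarization

The ancestral allele is the strict majority among outgroup-species calls that
match one of the marker's two alleles (one call per species; the table must
be pre-harmonized to the array's allele coding, third-allele votes are
discarded).  Ties, vote-less markers and third-allele-only markers are
*unresolved* and dropped from the iHS chain — a data outcome, not an error —
and resolved + unresolved always add back to the input count.  With flip
probability ε per species and three outgroups, the majority vote mispolarizes
with probability 3ε²(1−ε) + ε³, which the simulator reproduces within
binomial error.

## Structure diagnostics

IBS distance is 1 − (shared alleles) / (2 · jointly observed markers), with
per-marker sharing 2 − |dosage difference|; the difference-count distance
counts jointly observed markers with unequal genotypes.  Classical
(metric) MDS double-centers −D²/2 and eigendecomposes; dimensions with
non-positive eigenvalues are dropped, and each dimension's sign is fixed by
making its largest-magnitude loading positive so coordinates are reproducible
across platforms.  Neighbor joining is the standard Saitou–Nei agglomeration
with the Q criterion, ties broken on the lowest index pair, negative branch
lengths clamped to zero with the deficit logged; it recovers additive
matrices exactly and its topology matches an independent implementation on
random additive inputs.

## The simulator

The generator emulates what the scan consumes, not any particular breed
history.  Founder haplotypes are mosaics over a small set of template
haplotypes: per-marker derived-allele frequencies are drawn from a Beta law
truncated to [0.05, 0.95] (flat by default — an array-ascertainment-like
spectrum), and each founder copies along the chromosome from a template,
switching templates at rate 5e-6 per bp.  This produces LD that decays
monotonically with distance and a narrow effective founding base, as in a
bottlenecked breed.  Realized founder frequencies outside the bounds are
redrawn (bounded retries, then an exact-count fallback at that marker).

Evolution is diploid Wright–Fisher with Poisson recombination and **no new
mutation** (standing array variation): `g0 = 50` generations in a common
population of `n1 + n2` diploids, a split into sizes `n1 = n2 = 800`, and
`g1 = 50` further generations.  Desk-scale sizes force a rescaling: the
per-bp recombination rate is 1e-7 so that `N·r` (and hence population-scaled
recombination and the ratio of sweep-haplotype length to background
haplotype-sharing length) stays in a realistic regime.  At substantially
smaller N the background EHH decay scale — set by recent coalescence, which
is proportional to N — collapses onto the sweep-haplotype scale
(∝ 1/(r·sweep duration), with duration ≈ 2.8/s ≈ 55–110 generations at
s = 0.05), and no method could detect the sweep; N = 800 keeps the two
scales separated.

The sweep preset selects, at the split, the segregating marker in the
central half of the chromosome whose pop1 frequency is nearest `p0 = 0.05`
(central so that both decay sides are observable; a rare standing variant so
the sweep is effectively hard) and gives its derived allele genotype fitness
1 : 1+s : 1+2s in pop1 only, s = 0.05.  After `g1` generations both
populations keep evolving (up to 150 extra generations) until the focal
frequency reaches the 0.8 target or fixes; a lost focal allele triggers a
fresh draw (bounded retries).  The full per-generation frequency trajectory
in both populations, the focal marker and the true ancestral allele of every
marker are recorded as ground truth.  Scan panels sample 70 and 160
individuals from the two populations, mirroring the retained sample sizes of
a typical two-breed array study.

Outgroup tables are derived from the true ancestral states, flipped to the
derived allele with probability `outgroup_error` (default 0.05) and set
missing with probability `outgroup_missing` (default 0.02), independently per
species and marker.  Genotype missingness for QC tests is created by masking
at `mask_rate` when writing PED.

All randomness flows from one mandatory seed through named
`numpy.random.default_rng` streams (founders, evolution, outgroups, masking),
so a fixed seed reproduces every file byte for byte.

**What the simulator does not emulate:** multiple chromosomes (so
genome-wide PIHAT behaves noisily here, see above), genotyping error in the
study panels, a genetic map with hotspots, new mutation, ascertainment bias
beyond the truncated frequency spectrum, and any real breed's demography.
Passing tests therefore show the machinery is correct and the statistics are
calibrated and powered *under these conditions*; they do not certify power on
any particular real dataset.

## Numerical and degenerate-input choices

- Missing genotypes use an explicit sentinel (−1) internally and `0 0` / `.`
  on disk; haplotype panels admit no missingness (phased, imputed input is
  assumed).
- Positions are 1-based inclusive in memory; BED output is converted at the
  file boundary only.  Unsorted marker maps are rejected, never sorted
  silently.
- The p transform uses `log(2) + logsf(|z|)`; no naive `1 − Φ` subtraction.
- Integration interpolates the cutoff crossing linearly; a side with no
  markers beyond the focal is border-truncated with zero area.
- Zero-variance bins or score sets standardize to z = 0 rather than dividing
  by zero; undefined PIHAT pairs (no jointly observed markers) are flagged
  NaN, not crashed on.
- Deterministic tie-breaks everywhere a choice is arbitrary: LD pruning
  (lower MAF, then later position), relatedness pruning (missingness, mean
  PIHAT, sample id), NJ (lowest index pair), MDS sign (largest loading
  positive).

## Performance

The partition-refinement walk and the Wright–Fisher gamete builder carry
numba-compiled kernels with pure-NumPy fallbacks of identical semantics
(agreement asserted in tests).  A full default-size replicate — simulate,
polarize, all three scans — takes on the order of ten seconds on one CPU;
the acceptance script (including 20 sweep replicates) runs in about three
minutes.

## Problem sizes used by tests and acceptance

Unit tests use toy fixtures and small random panels (≤ 60 haplotypes × 300
markers) against brute-force oracles.  Calibration and power use the
generator defaults: 5,000 markers / 20 Mb, N = 800 per population, neutral
calibration on one fixed-seed replicate (≈ 4,600 scored markers), power on
20 sweep replicates.  These sizes are the package's chosen study conditions,
balancing statistical resolution against a desk-scale runtime.
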