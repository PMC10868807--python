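# Methods

## System and scope

The package analyses (and simulates) barcoded amplicon sequencing of
single-strand annealing (SSA) repair products from a pair of diverged
~200-bp repeats, F and A. The repeats differ at seven sites: MM1 and MM3–MM7
are single-base substitutions; MM2 is a one-T insertion inside a poly-T
homopolymer. MM1 is itself a T that forms the first base of the run, so the
run is 12 T's on F and 10 T's on A, and MM3 is the first base right of the
run. After SSA, each colony carries a two-strand (duplex) genotype over the
seven sites; a site whose strands disagree was retained as heteroduplex.

## Reference geometry

Real repeat sequences are not bundled; `make_reference_pair` generates
synthetic repeats with the study geometry: F length 205 nt, A 204 nt, MM1 at
position +17, the 12-T run at 17–28, MM3 at 29, MM7 at 135 (70 bp from the
right end), and MM4–MM6 evenly spaced between them (55, 82, 108) — the even
spacing is a design choice, and every position is overridable so real
sequences can be dropped in. Each site carries exact 8-mer anchors taken
from the flanking invariant sequence; generation redraws until every anchor
occurs exactly once in both full amplicons (bounded retries, then an error).
Coordinates are 0-based, half-open; all reads are oriented to the top
strand, as fixed primer orientations guarantee in the real protocol.

## Repair model (the genotype generator)

A colony's duplex genotype is drawn from a four-way outcome: all-F, all-A,
fully heteroduplex, or mixed (probabilities `p_all_f, p_all_a, p_het,
p_mixed`). In a mixed event each site either resolves to F (probability
`site_f_bias[i]`) or stays heteroduplex; all-A strands enter through the
all-A outcome or through explicit per-colony genotype lists. Per-site
decisions share a single uniform draw with probability `rho` (a copula):
`rho=0` gives independent sites, `rho=1` with a flat bias gives all-or-none
correction — the signature of the tailless strains, under which the mixed
outcome class empties. `end_gradient` mode uses one shared uniform against a
non-increasing bias vector, so corrected sites always form a left-anchored
tract with a single left-to-right switch point while per-site marginals
still equal the bias vector — the generative form of the observed correction
gradient. The default bias vector (0.87 … 0.53) matches the wild-type
cohort's end-to-end F-correction range (87% at MM1 to 53% at MM7).

## Error and depth models

* Substitutions: per base, per mate, independently (default experiments use
  0.002/base). An error at a variant site usually produces an N call; in an
  anchor it hides the site (N); both kinds of reads stay in the read set but
  are excluded from frequency tables.
* Homopolymer slippage: with probability ε the *template of a read pair*
  (it is a PCR artifact, shared by both mates) shifts the poly-T run by ±1,
  directions equiprobable. Defaults: ε = 0.05 for high-fidelity runs,
  0.24 for Taq-like runs.
* Qualities: Phred ~ Normal(37, 3), clamped to [2, 41].
* Depth: negative binomial with mean 186 and sd 112
  (r = mean²/(var − mean) ≈ 2.8), floored at 7 — the study's per-colony
  read-count statistics. Experiments that require reliable duplex calls
  floor depth at 20 or 50 (see "Thresholds" below).
* Within-colony strand mixture: the fraction of read pairs from the top
  strand is Beta(20, 20) per colony (mean 0.5, sd ≈ 0.08), a stand-in for
  sectoring and PCR drift; no empirical within-colony mixture model exists,
  so the parameter is exposed.

## Read processing

Merging reverse-complements R2 and enumerates candidate overlaps with two
12-mer seeds from its prefix; an overlap qualifies at length ≥ 30 with at
most `max_mismatch` mismatches. No qualifying overlap rejects the pair
(`no_overlap`); more than one rejects it as `ambiguous`. In the overlap the
higher-Phred base wins and the consensus quality is the per-base maximum.
With `max_mismatch=0` the seed enumeration is exhaustive; with mismatches
allowed, a pair whose first 24 overlap bases all carry errors can be missed
(rejected as `no_overlap`) — at the error rates used this affects ≪1% of
pairs. "Highest stringency" merging is `max_mismatch=0`; at substitution
rate 0.002 that discards ~58% of pairs (any error in the ~219-bp overlap),
so the error-rate experiments run with `max_mismatch=2`, and the zero-error
validations keep 0.

The length/quality filter is strict on both thresholds (length > 250,
mean Phred > 35), and Q is interpreted as the mean Phred of the merged
read — a per-base threshold of 35 would reject nearly everything.
Demultiplexing requires both 8-bp barcodes to match exactly; barcode sets
have pairwise Hamming distance ≥ 3, so an optional 1-mismatch rescue is
safe and available but off by default. Merging precedes demultiplexing; the
merged read retains both barcodes at its ends, and they are trimmed on
assignment.

## Variant tracing and the MM2 call

Substitution sites are read at the base immediately after their unique left
anchor — except MM3, whose left context is the run itself (no unique 8-mer
exists inside a homopolymer), so MM3 is read immediately before its unique
right anchor. Any failed or duplicated anchor yields N.

For the run region: the first base between the run anchors decides MM1
(T → F, the A allele → A, else N). With n the contiguous T count and
n' = n − 1 when MM1 contributed a T, MM2 reads F when n' ≥ 11 and A when
n' ≤ 10; there is no N band, so slippage produces definite miscalls — which
is precisely what the downstream MM2 fix exists to repair. Two run-length
observables are recorded per read: the contiguous T count (drives the MM2
call) and the inter-anchor span (insensitive to substitutions inside the
run, so it isolates slippage indels; it drives the discordance statistic).

**Raw MM2 discordance** is the fraction of reads whose inter-anchor span
contradicts the template implied by their MM1 call. Measured on pure-F /
pure-A fidelity-control colonies it converges to the slippage rate ε
(≈5% high-fidelity, ≈24% Taq-like). On mixed cohorts it also counts genuine
recombinant strands whose MM1 and MM2 truly differ, so control colonies are
the right substrate for fidelity estimation — matching how the polymerase
controls were actually run.

## Genotype calling

The MM2 fix rewrites a read's MM2 to match MM1/MM3 when those two agree and
MM2 differs; when MM1 ≠ MM3 the read is left untouched (the rule is defined
only on flank agreement). The fix is idempotent and touches only position 2.
Its known cost: a genuine strand such as F**A**FFFFF is erased into FFFFFFF;
cohorts where such strands are the estimand should disable the fix (see the
parameter-recovery experiment below).

Frequencies are computed over reads with no N call (N reads are counted
separately). The duplex rule takes haplotypes with frequency strictly
greater than 0.19, sorted by descending frequency with lexicographic
tie-break (the tie-break is a determinism choice; ties are otherwise
unspecified): two or more → the top two are the strands (extras are flagged
`ambiguous_extra`, not errors); exactly one → homoduplex; none → `no_call`.
No-call colonies are excluded from spectra and reported separately.

## Spectra and statistics

Per-site status comes from the strand pair (F/F → F, A/A → A, else HET);
outcome classes are all-F, all-A, unrepaired (all HET) and mixed, over a
configurable scored-site mask — the six-site view omitting MM2 reproduces
the Sanger-style summaries from the same code path. The correction gradient
is tested with a two-sided Fisher exact test on (F, not-F) counts at two
sites; the test suite verifies scipy's implementation against exhaustive
hypergeometric enumeration for every 2×2 table with n ≤ 30. Pairing of
colonies across sites (McNemar) would be an alternative; the independent-
proportions test is the default. Reported percentages round to the nearest
integer. Plate-level SSA frequency is selective/permissive colony counts as
a percentage, and diagnostic PCR products classify to the nearest expected
size within ±10% (285 bp SSA vs 632 bp parental by default).

## Experiment sizes and thresholds

* Zero-error round trip: one 96-colony library at default depth (floor 20);
  every called duplex equals the truth. The 19% rule is exact from ~20
  informative reads up; at depth 7 a 50:50 heteroduplex colony can
  legitimately drop its minority strand below threshold.
* Error robustness: 192 colonies (two libraries), substitutions 0.002,
  slippage 0.05, depth floor 50, merger at `max_mismatch=2`; genotype
  accuracy ≥ 99%.
* Fidelity controls: 96 pure-F/pure-A colonies per polymerase setting.
* Parameter recovery: 500 colonies under the independent-site gradient bias
  (0.90 … 0.55), error-free, MM2 fix disabled — on clean data the fix would
  systematically rewrite genuine (HET, F, HET) patterns at sites 1–3 and
  bias the MM2 estimate by ≈1.8 points. Recovery is checked against
  simultaneous 95% binomial intervals, Šidák-adjusted across the seven
  sites (per-site z ≈ 2.68) so family-wise coverage is 95%.

The full test suite runs in ~1 minute and `scripts/acceptance.py` in ~30 s
on one CPU; sizes above were chosen to keep Monte-Carlo bands tight at that
scale.

## What the simulator does and does not capture

It reproduces the features the pipeline's correctness depends on: the
variant geometry (including run-length ambiguity of the MM2 indel),
dual-barcode structure, overdispersed depth, within-colony strand mixtures,
substitution error and template-level slippage. It does not model PCR
cycle-by-cycle amplification, chimeras, index hopping, quality-by-position
profiles, adapter read-through, or resection/annealing kinetics — passing
tests therefore validate the analysis logic under the stated generative
assumptions, not the behaviour of any particular sequencer. Fig-style
experimental spectra from wet-lab colonies are inherently not reproducible
from scratch; the printed colony counts are used as fixed inputs to the
classifier/statistics code instead.

## Known limitations

* The MM2 fix erases genuine MM1≠MM2 recombinant strands by design; all
  MM2-bearing conclusions should be read with that in mind (the six-site
  view exists for exactly this reason).
* Anchored extraction assumes locally intact 8-mers; there is no alignment
  fallback, so indels outside the run or dense errors produce N calls
  rather than rescued calls.
* The heteroduplex (HET) status conflates true retained heteroduplex with
  colonies mixed by post-replication segregation; the data cannot separate
  them and no attempt is made to.
* `simulate_duplex_genotype`'s mixed branch resolves sites F-vs-HET;
  cohorts rich in partial A-correction are expressed via explicit genotype
  lists rather than the parametric model.
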