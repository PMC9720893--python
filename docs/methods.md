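# Methods

## Duplex model

A candidate siRNA duplex is a pair of reads — a reference (guide
candidate, File A) and a query (potential passenger, File B) — whose
reverse-complement alignment is ungapped and exact over the paired span.
Gaps are never allowed: the duplex model is a base-paired stem, and an
indel would not be a duplex.  G:U wobble pairing and thermodynamic scoring
are out of scope; pairing is strict Watson–Crick over {A,C,G,T} (U is
normalised to T on ingest, and reads containing N are excluded from duplex
finding — they cannot satisfy zero-mismatch pairing — while still counting
toward library sizes).

A placement of reverse-complement(query) at offset *o* on the reference is
accepted when the overlap span (the intersection of the placed query with
the reference) is at least `min_overlap` bases long and contains at most
`max_mismatches` mismatches (default 0).  Because the span is always the
full intersection, at each duplex end at most one strand can protrude;
"both strands extend at the same end" geometries can only arise when
ingesting foreign local alignments from SAM/BAM, and are rejected there as
invalid duplex ends.

**All placements are reported**, not a best hit.  Small RNAs multimap;
read-vs-read all-pairs enumeration is exactly what removes the best-hit
arbitration loss of genome-based detection, so collapsing to one hit would
defeat the method's purpose.  When File A and File B are the same file
(unbiased scans of a whole library against itself), mirrored pairs (a, b)
and (b, a) are both reported — downstream percentages count reads, not
unordered pairs — and a read pairs with itself only in the palindromic
case where its sequence is its own reverse complement.

### Parameters

| parameter        | default                         | meaning |
|------------------|---------------------------------|---------|
| `min_overlap`    | shortest File B read length     | minimum paired bases; the default lets every query pair over its full length |
| `max_mismatches` | 0                               | mismatches tolerated inside the paired span; >0 admits non-canonical duplexes at the cost of false positives |

## Alignment engine

`find_duplexes` is seeded by an exact k-mer index over the reference
sequences, with k = min(`min_overlap`, 12).  Any zero-mismatch span of
length ≥ `min_overlap` ≥ k necessarily contains a full query k-mer placed
exactly on the reference, so probing every k-mer of the
reverse-complemented query finds a superset of all valid (reference,
offset) placements, each of which is then verified over the full span.
The cap of 12 bounds index memory while keeping expected random collisions
(4⁻¹²) negligible for library-scale inputs.  With `max_mismatches > 0`
seeds can be disrupted, so the engine falls back to the exhaustive offset
scan.  `brute_force_duplexes` implements that scan directly and is kept as
a deliberately simple independent oracle; the test suite asserts multiset
equality between the two engines on randomized collections.

## End-distance classification

Distances are defined in reference orientation (reference 5′ end =
leftmost reference base): `d5 = q_ext5 − ref_ext5`,
`d3 = q_ext3 − ref_ext3`, negative = reference overhang, positive =
reference underhang, 0 = blunt.  The sign fully determines the end type,
and `ref_len − query_len + d5 + d3 == 0` for every duplex.

SAM/BAM interop follows the SAM specification: a minus-strand record
stores SEQ and CIGAR in reference-forward orientation, so the *leading*
softclip counts query bases protruding past the reference 5′ end and the
trailing softclip those past the 3′ end — no per-strand flipping.
Coordinates are 0-based internally (pysam converts SAM's 1-based POS at
the boundary).  Records with I/D/N CIGAR operations raise (a spliced or
gapped alignment is not a duplex); forward-strand records are skipped with
a warning during bulk ingest.

## Enrichment statistic

For the counts at one end, the mean is the arithmetic mean over the
distance classes present in the table (tallies omit empty classes; a
zero-count class appears only if the caller tabulates it explicitly, and
then contributes to the mean and receives a −∞ log-odds sentinel, never a
significance flag).  For a class with count c and mean c̄:

    log_odds = ln(c / c̄)
    z        = log_odds / sqrt(1/c + 1/c̄)

The standard error is the asymptotic SE of a log ratio of two Poisson
counts; this construction is a design choice documented here because other
Wald constructions (different variance terms, log base) would shift the
absolute z values while preserving the qualitative calls.  Significance is
one-sided at z > 1.645 (p = 0.05); depletion is reported but never
flagged.  No multiple-testing correction is applied across distance
classes.  An optional pseudocount rescues zero classes when smoothing is
wanted; none is applied by default.  A degenerate single-class table gives
log-odds 0 and z 0.

Counting modes: `expression` weights each duplex by its reference read's
copy count (collapsed multiplicity), reflecting how much cleavage occurs;
`unique_reference` counts each distinct reference sequence at most once
per distance class, reflecting how many distinct sequences carry the
signature.

## Synthetic data

The simulator emulates a small-RNA library reduced to its duplex
structure.  Defaults are the study conditions: 20,000 distinct random
21-nt reads; 797 of them are duplex-forming references (File A); 1,365
passengers are constructed against them with planted signed distances
whose 3′ marginal is {−4: 40, −3: 125, −2: 550, −1: 275, 0: 200, +1: 125,
+2: 25, +3: 25}; the remaining 19,203 reads are background noise; File B =
passengers + background.  The 5′ marginal is not pinned by the study
conditions, so the default cycles d5 over {−2, −1, 0, +1, +2} within each
3′ class — a realistic mix of short 5′ overhangs/underhangs that keeps
every passenger 15–26 nt and every paired span ≥ 15 nt (≥ the default
`min_overlap`, so every planted duplex is detectable).  Duplexes are
distributed round-robin so every reference owns at least one.

A passenger for planted (d5, d3) is the reverse complement of the
reference core (the reference minus its overhanging ends) flanked by
random bases where the passenger underhangs.  Construction is verified:
each passenger must place at exactly its planted offset against the whole
reference set, and background reads are rejection-sampled to form no
qualifying duplex with any reference.  This is stricter than simply
trusting 4⁻¹⁵ collision odds; it makes the 100 %-recovery check exact
rather than probabilistic.  Everything is deterministic given the seed.

49 % of duplexes are flagged multimapping, realised as 2–6 duplicated loci
in the concatenated pseudo-genome (reads joined by 5 random nt, built by
`build_simulated_genome` for comparisons against genome-based detectors).
Read-vs-read duplex finding is unaffected by construction — that
insensitivity to multimapping is the property the dataset demonstrates.

Spike-ins are fixed-geometry control duplexes mixed into any dataset:
`single_reference` mode replicates one template reference n times with n
identical passengers (expression-style; e.g. a 26-nt guide with d5=0,
d3=−1 gives the canonical 25-nt passenger, a 22-nt guide with d5=d3=−2 an
18-nt passenger) — note that n identical references × n identical
passengers yields the full n×n pairing under all-hits enumeration, so
expression-mode counts scale accordingly; `variable_reference` mode draws
n distinct random references (default 24 nt, optional fixed 5′ base so
spikes cannot shadow an existing class) each with one passenger (default
d5=−1, d3=−2, hence 21-nt passengers), giving exactly n planted duplexes.

### What the simulation does and does not show

The generator plants exact, mismatch-free duplexes in uniform random
background; it does not simulate sequencing error, adapter contamination,
quality scores, expression-level skew, or the sequence composition biases
of real libraries.  Passing the recovery tests therefore demonstrates the
correctness of the alignment/classification machinery and its robustness
to multimapping — not end-to-end performance on noisy biological data,
where degraded passengers and non-Dicer reads dilute (but, at realistic
depths, do not erase) the signature.

## Outputs

Five CSVs per run (`<prefix>_overhang.csv`, `_unique_overhang.csv`,
`_passenger_number.csv`, `_passenger_length.csv`, `_overhang_type.csv`),
comma-separated with a header row, distances as signed integers sorted
ascending within end; the two overhang tables carry `end, distance, count,
log_odds, z, significant` columns.  Runs are deterministic: identical
inputs and configuration give byte-identical files, and an existing output
is never overwritten without `--force`.  With `--write-alignments`, one
SAM file is written per observed (end, distance) class; each duplex
appears under both its 5′ and its 3′ class (grouping by a single end would
discard half the signature), and re-ingesting any class file reproduces
its label.  Zero duplexes is a warned, successful run with header-only
tables.

## Problem sizes used in the checks

The acceptance script and the full-scale tests run the complete default
simulation (20,000 reads, 797 references, 1,365 duplexes) plus a
5,000-spike detection run and 100 randomized oracle-equivalence trials
(collections of up to 60 reads, lengths 15–30 nt, randomized minimum
overlap).  These sizes exercise the seeded index well past the regime
where naive scanning is feasible while completing in seconds.

## Known limitations

* Only canonical fully complementary duplexes are found by default;
  `max_mismatches > 0` admits near-canonical duplexes but currently takes
  the exhaustive path.
* The Wald SE construction is one defensible choice among several; compare
  z values across tools qualitatively, not digit-for-digit.
* Adapter trimming and miRNA removal are upstream of this package.
* `unique_reference` tallies deduplicate by reference sequence only when
  the reference collection is supplied; otherwise read ids stand in.
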