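# Methods

This note documents the models, parameters and numerical choices behind
`mircos`, what the synthetic data generator does and does not emulate, and
the known limitations. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## The comparative screen

The pipeline assumes two EST collections from related species, close
enough that orthologous transcripts align at the nucleotide level over
hundreds of bases. Its central claim is a *selection criterion*: a
predicted miRNA target is far more credible when the same mature miRNA
has predicted sites at corresponding positions of a conserved
orthologous sequence (COS) region in both species, and when its
prediction count stands out against shuffled controls. The pipeline is a
composition of standard sequence-analysis parts; the value is in the
intersection logic and the statistical filter, so each part is
implemented in a transparent, testable form rather than shelling out to
external binaries.

## Inverted-repeat detection (`irfinder`)

Candidate stem-loops are local gapped alignments of an EST against its
own reverse complement, in which an alignment column pairs a left-arm
base with a complementary right-arm base. Scoring follows einverted's
defaults — match +3, mismatch −4, gap −12 per position (linear), report
threshold 50 — because those defaults define the behaviour space of the
tool this stage emulates. "Longer than 30 bp" is interpreted as the
total repeat span (arm + loop + arm ≥ 30 nt); the loop may be at most
300 nt. N never pairs.

The search runs a vectorised Smith–Waterman over the sequence versus its
reverse complement. An endpoint cell is eligible when its implied loop
is within range; because the loop length decreases monotonically along
any alignment path, constraining endpoints suffices. Overlapping repeats
are reduced to a non-overlapping set by iterated best-hit extraction:
report the top-scoring eligible repeat (ties: leftmost, then longest),
mask its arm positions so no later alignment can include them, repeat.
The test suite checks this against an O(n⁴) enumeration of all
arm-start pairs on sequences up to 80 nt.

Consequence worth knowing: a 21-bp arm with two substitutions scores
19·3 − 2·4 = 49 < 50, so hairpins whose star arm has diverged at two or
more positions are (correctly, per the scoring model) invisible to this
stage. Synthetic recovery of precursors is therefore asserted at zero
arm divergence, and recall is monotone non-increasing in divergence.

## Duplex scanning (`duplexscan`)

The target scan finds miRNA binding sites under the plant-target
constraints: at most one mismatch; at most one bulge event with at most
one unpaired nucleotide per side (a 1×1 internal loop is counted as a
mismatch, not a bulge; bulges must be interior); unpaired miRNA terminal
overhangs of at most 2 nt at each end; both strands scanned.

Energies use a pair-sum model: GC/CG −3, AU/UA −2, GU/UG −1 (model
units), mismatches 0, +2 per bulge event. This is deliberately *not* a
nearest-neighbor thermodynamic model: the selection rule is relative —
a site is kept when its energy reaches 70% of that miRNA's
perfect-match energy (the miRNA bound full-length to its Watson–Crick
complement, never using wobble) — and a pair-sum model preserves that
ratio structure while remaining exactly enumerable, which is what makes
the brute-force oracle test possible. Absolute kcal/mol values are out
of scope; the folding backend is pluggable where they matter.

The implementation sweeps a small state machine along the miRNA from its
3′ end (which pairs the 5′-most base of the site), vectorised over all
candidate site starts; states track the mismatch budget, bulge type and
a pending-bulge flag (bulges must be followed by a paired/mismatch
step). For one site interval only the best structure is kept (lowest
energy, then fewer bulges, then fewer mismatches); *overlapping* site
intervals are all reported, since site multiplicity is biologically
meaningful. Exhaustiveness is verified against explicit per-start
enumeration on 50 seeded 300-nt ESTs.

Surviving-start compaction and float32 state vectors make dataset-scale
scans practical; the optimisation is checked by hit-set equality with
the unoptimised enumeration.

## Precursor assembly and fold validation (`precursor`)

Within an inverted repeat, the mature is located by ungapped sliding
comparison (Hamming ≤ 2) on either strand of either arm; the star is the
reverse complement of the matched orientation on the opposite arm
(Hamming ≤ 3), searched with 4 nt of flanking slack for the canonical
2-nt 3′ offset. The outer mature-to-star span must match an orthologous
precursor length of the same family within ±20%. The mismatch
tolerances and the ±20% are package choices (the source procedure states
only "equivalent" spacing); all are configurable.

A 200-nt window centred on the mature/star midpoint (truncated at EST
ends, never padded) is folded with an energy-weighted Nussinov-class DP
over the pair-energy table: minimum hairpin loop 3 nt, no pseudoknots,
structure energy = sum of pair energies. The DP is exact for that model
(verified against exhaustive structure enumeration up to 30 nt). A
candidate is **validated** when

* ≥ 75% of mature bases are paired,
* the longest contiguous stacked helix through the mature (consecutive
  positions whose partners descend by one) covers ≥ 45% of the mature,
* fold energy density ≤ −0.15 units/nt.

The stacked-helix criterion is the discriminating one and deserves a
note. Nussinov-style folds of *random* sequence pair many bases and even
cluster partners locally into short helices, so "fraction paired" or
"partners on one side" alone barely separates a real hairpin window from
a shuffled one. What random folds do not produce is one long
uninterrupted helix: on the default synthetic conditions, planted
hairpins (including star arms with up to two substitutions) show
stacked-run fractions ≥ 0.48 while 40/40 shuffled windows stay ≤ 0.43.
The 0.45 default sits in that gap; the mononucleotide-shuffle test
asserts ≥ 18/20 shuffled windows dropped.

## COS detection and E-values (`cosalign`)

COS regions are found BLAST-style: exact 12-mer words of the query are
looked up in a hash of the database; each seed-diagonal bucket of an EST
pair is extended once by Smith–Waterman–Gotoh restricted to a band of
±32 diagonals around the seed, with x-drop 20 early termination. Gap
costs are affine: a gap of length g costs 5 + 2g (existence +
extension). HSPs must pass a discovery E-value of 10⁻⁴; per EST pair,
overlapping HSPs are reduced to the highest-scoring; survivors qualify
as COS when they span ≥ 400 alignment columns (gaps included, matching
how BLAST reports alignment length) with identity > 75% and E < 10⁻¹⁰.

E = K·m·n·e^(−λS) with m the query length and n the total database
length. λ solves Σ pᵢpⱼe^(λsᵢⱼ) = 1 by Brent root-finding (tol 1e−12);
K uses the standard lattice-case series
K = δλe^(−2σ)/(H(1 − e^(−λδ))) with
σ = Σₖ k⁻¹[E(e^(λSₖ); Sₖ<0) + P(Sₖ≥0)], the walk distributions computed
by convolution and the series truncated when a term falls below 1e−12
(terms decay geometrically). For +1/−2 at uniform composition this gives
λ = 1.3327, K = 0.6210, matching the ungapped constants NCBI BLAST+
prints. Using ungapped λ, K with gapped scores is a documented
approximation — E serves only as a pass/fail threshold here. Word size,
gap costs and band width are configurable; defaults are package choices
where the source procedure names only the tool.

Each COS region carries a column map (parallel position arrays over the
aligned, non-gap columns). Interval projection maps through this map;
positions deleted on the far side collapse to the nearest aligned
boundary, so projecting the full query interval returns the full
subject interval.

## Conserved-target intersection (`conserved`)

For every COS region and every miRNA with at least one predicted site
inside both COS intervals, each query-side site is paired with the
subject-side site of maximal overlap after projection, and reported when
that overlap is ≥ 10 nt (about half a site). Whether the original screen
demanded positional correspondence or mere co-occurrence within the COS
is ambiguous; strict positional mode is the default and a relaxed
co-occurrence mode is available (`require_position=False`).

## Shuffle statistics (`shufflestats`)

Per miRNA, observed = real-vs-real hit count (TP + FP together). Two
null schemes, 10 randomisations each: (1) dinucleotide-preserving
shuffles of the miRNA versus the real ESTs; (2) the real miRNA versus
mononucleotide-preserving shuffles of the ESTs. FP = mean of the two
scheme means (both scheme means are also reported so either convention
is recoverable). Then SNR = (TP+FP)/FP and S = TP/(TP+FP), linked by
S = 1 − 1/SNR; a miRNA passes at SNR > 2 (strict) and S ≥ 0.85. Edge
conventions: FP = 0 with hits observed gives SNR = ∞, S = 1; observed =
0 with FP > 0 gives SNR = 0, S = 0; both zero is flagged not evaluable.
S is clamped to [0, 1] when the shuffle estimate exceeds the observed
count.

The dinucleotide shuffle is the Euler-walk construction: designated
last-edges are drawn until they form an arborescence toward the final
vertex, remaining out-edges are permuted, and the walk is replayed —
preserving all 16 dinucleotide counts and both terminal bases exactly.
Randomness in FP estimation is derived from
(seed, miRNA name, scheme, replicate), so estimates are reproducible
and independent of evaluation order.

**Null-suite conditions.** The pure-null pass-rate property (≤ 5% of
miRNAs passing on data with no planted targets) is asserted at
n_ests = 150, lengths 400–800 nt, panel of 4, seeds 100–119. The size
matters scientifically: the SNR/specificity thresholds are meaningful
when expected background counts are of order ≥ 0.5 per miRNA — the
regime real screens operate in. On very sparse data a single
Poisson-fluke hit accompanied by a small shuffle estimate passes the
thresholds with probability of several percent *regardless of
implementation*; that is a property of the statistic at tiny counts,
not of this code, and the chosen conditions keep the suite out of that
regime.

## Synthetic data (`synthetic_data`)

The generator emulates the *structure* the pipeline keys on, at reduced
scale: i.i.d. background ESTs of 400–800 nt (uniform base composition by
default); planted precursors built as mature + random loop (30–60 nt) +
reverse-complement star, the star carrying 0–2 seeded substitutions to
exercise the mismatch tolerances; orthologous segment pairs of 500 nt
diverged at a controlled substitution rate (an exact substitution count
outside the planted site, so realized divergence matches the configured
rate by construction); conserved target sites planted at corresponding
positions inside those pairs, non-conserved sites planted outside any
pair; sites and precursors land on either strand with probability 1/2.
Defaults: 200 ESTs per species, 20 precursors, 15 conserved + 15
non-conserved targets, divergence 0.10, seed 7. Identical configurations
produce byte-identical FASTA and manifest.

It does **not** emulate: expression-level abundance, sequencing error
models, vector/adapter contamination, poly-A tails, paralogy,
composition bias, or length-dependent EST quality. Passing recovery
tests therefore demonstrates the pipeline's selection logic under its
own assumptions — they say nothing about robustness to the noise
profile of real dbEST data, where thresholds would likely need
re-tuning.

## Numerical conventions

* Coordinates are 0-based half-open internally; serialized reports are
  1-based inclusive.
* ESTs are DNA (U→T on input), matures are RNA; cross-alphabet
  comparisons always go through explicit conversion.
* Integer alignment scores make every traceback an exact-equality walk;
  fold energies are sums of small multiples of 1.0, compared exactly.
* Energy-ratio cutoffs use a 1e−9 absolute slack to absorb float
  summation order.
* Tie-breaks: duplex structures at one locus — lowest energy, fewer
  bulges, fewer mismatches; inverted repeats — score, then leftmost,
  then longest; HSPs — score, then intervals.
* Records with > 10% N are dropped with a warning (EST data is noisy);
  duplicate EST ids are a hard error because downstream joins key on id.

## Problem sizes

Test and recovery suites run at deliberately small scale: oracle
equivalence on 60–300-nt sequences, end-to-end recovery at 200 ESTs per
species, the null sweep at 150 ESTs × 20 replicates. These sizes were
chosen so the full suite completes in minutes on one CPU while keeping
every statistical check in a regime where its premise holds (see the
null-suite note above).

## Known limitations

* The duplex energy model ranks structures; it does not predict
  measurable free energies. Published per-site mfe values computed with
  full thermodynamic models are not comparable and not targeted.
* The headline dataset-scale counts of the original screen (tens of
  thousands of ESTs from a dated dbEST release, era-specific BLAST
  binaries) are irreproducible at desk scale and are not asserted.
* Hairpin validation is tuned for ~21-nt matures in 200-nt windows;
  very long loops (> ~160 nt) would push the star outside the window.
* `find_cos` indexes 12-mers in plain dictionaries — fine for thousands
  of ESTs, not engineered for millions.
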