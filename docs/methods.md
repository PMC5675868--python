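# Methods

This note documents the models, rule sets and design choices behind
`relaxkit`, what the synthetic-data generators do and do not emulate, and
the numerical conventions used throughout.

## Coordinates and formats

Internal intervals are 0-based half-open; everything user-facing (GFF3,
TSV, function arguments documented as "positions") is 1-based inclusive.
GFF3 and FASTA are read with gffutils and Biopython; the canonical writer
in `seqio` produces byte-stable round trips for the fields the package
stores (id, interval, strand, phase). CDS translation uses NCBI genetic
code 11 with alternative start codons read as M; a CDS whose length is not
a multiple of three is kept, flagged, and left untranslated. Ambiguity
codes other than N are rejected at parse time — none occur in scope.

Published coordinate ranges are not always 1-based inclusive: when a
printed range is one base longer than its stated length, the only
consistent reading is start-inclusive/end-exclusive. `extract_segment`
therefore takes an explicit convention flag rather than guessing, and both
candidate segments of an ambiguous printed range are retrievable.

## Homology search

The search is a deliberate desk-scale stand-in for iterated
large-database BLAST. Optimal local alignment scores come from Biopython's
`PairwiseAligner` (C implementation) under BLOSUM62 with affine gaps — a
gap of length *g* costs 11 + *g*, the NCBI convention. Significance is the
Karlin–Altschul expectation *E = K·m·n·e^(−λS)* with the standard gapped
BLOSUM62/11/1 parameters λ = 0.267 nats/score-unit and K = 0.041, using the
raw product of query length and summed database length (no edge-effect
correction). Family thresholds default to 1e-15 for relaxase queries and
1e-6 / 1e-7 for the small/large auxiliary queries, all configurable.

Deduplication collapses 100 %-identical sequences (first-seen id kept,
mapping returned); in the mining pipeline hits on a representative are
expanded back to every identical gene copy, so co-occurrence counting
remains per gene while search effort stays per unique sequence.

The optional PSSM iteration builds position-specific scores from the
ungapped columns of round-1 alignments (pseudocount 1, uniform background,
log-odds divided by λ so the E-value formula still applies), re-searches
with an affine-gap Gotoh DP, and repeats until no new subjects appear or
ten rounds have run. It is off by default: the package's point is the
neighborhood crossing, not search sophistication, and the tests that
matter run in one round.

## Secondary structure and the RHH signature

`predict_ss` is a classical propensity predictor, fully rule-defined so it
is deterministic and auditable (no model weights). Using the published
single-residue helix/strand propensity table (shipped as
`data/chou_fasman.tsv`):

* helix nucleation: 6-residue window with ≥ 4 residues of P(helix) ≥ 1.0
  and window mean > 1.03; extension one residue at a time while the
  trailing 4-residue window mean stays ≥ 1.00;
* strand nucleation: 5-residue window with ≥ 3 residues of P(strand) ≥ 1.0
  and mean > 1.05, extended the same way;
* class conflicts are resolved per contiguous overlap run by the larger
  mean propensity (ties to helix); the rest is coil.

The RHH call requires, starting within the first 50 residues, a strand of
≥ 3, then (gap ≤ 6) a helix of ≥ 6, then (gap ≤ 8) a second helix of ≥ 6.
The window and segment minima encode CopG-family geometry (a short β1 and
two helices); all five numbers are exposed in `RHHParams`. The K/R count
across the helix1-end/helix2-start junction — the face that approaches the
DNA backbone in solved RHH structures — is reported as supporting evidence
and never used as a filter.

Measured operating characteristics under the package's own generators:
recall is 1.0 on `generate_rhh_protein` output at zero noise (checked for
lengths 45–147 over hundreds of seeds), and poly-P controls are always
negative. On uniform-composition random decoys, chance strand–helix–helix
arrangements do occur and their rate grows with length: specificity is
about 0.91 at 50 residues and about 0.75 at 147, i.e. roughly 0.8 over the
generator's 50–150-residue decoy range. The regression test floors it at
0.75. This matters only for interpreting the screen on arbitrary proteins;
in the mining pipeline the RHH screen runs downstream of the homology
filter, so decoys never reach it.

## Neighborhood mining

"Upstream" means the nearest co-oriented CDS on the 5′ side of a gene in
its own transcription direction, within 1000 bp by default; opposite-strand
genes are ignored (operon semantics), and genes containing the query gene
are excluded. Distances follow the 1-based-inclusive gap convention
(next start − previous end − 1), so a stop/start overlap sharing one base
gives −1, and `coupled` flags distance ≤ 0. Replicons are linear by
default with a `circular` option; plasmids are circular, but neighbor
lookup in sequence databases is effectively linear and the synthetic
replicons place genes away from the origin.

The crossing is nested by design: a relaxase row has `has_aux2` iff its
adjacent upstream gene product is in the aux2 hit set, and `has_aux1` iff
additionally the next gene upstream is in the aux1 hit set. An
aux1-without-aux2 architecture is therefore reported as neither — the
summary mirrors the "preceded by …, and of these …" counting scheme of
relaxosome surveys. Unresolvable hit ids yield flagged rows, not drops.
Summary percentages are rounded to one decimal, ties away from zero.

## Synthetic data

The generators define the study conditions; they are not tuning knobs.

* **Replicons.** Each carries one mutated copy of a fixed ~400-residue seed
  relaxase; with probability 0.27 an aux2-like gene (147 codons) directly
  upstream, and conditional on that with probability 0.22 an aux1-like gene
  (79 codons) further upstream — the default prevalences mirror the
  observed fractions in MOB-family surveys (roughly 387/1453 and 87/387).
  Intergenic gaps draw from 0–200 bp; with probability 0.3 the
  aux2/relaxase junction is translationally coupled (the classic
  ...TA[A/ATG]... single-base overlap). Three decoy CDSs of uniform random
  composition (50–150 codons, random strand) flank the cluster, and about
  half the replicons are emitted reverse-complemented. Proteins are
  back-translated with random synonymous codons (code 11, ATG start, TAA
  stop). The seed queries are fixed synthetic literals
  (`_seed_proteins.py`); the two auxiliary families use disjoint residue
  pools for their motif cores so they stay separable by homology search
  (cross-family local alignment scores ~25–30, far below any threshold).
* **oriT-like sequences.** 500 bp at ~61 % AT with one palindrome
  (`TGGTACCA`) planted inside a fixed 25-bp window (positions 201–225, the
  interval that eight consecutive fragments of the 200/25 design share),
  and three same-strand copies of `TGTGCAT` in the 5′ half, two embedded in
  `TTTATGTGCATT`. Flanks of the palindrome are pinned non-complementary so
  it is maximal exactly as planted, and accidental extra motif copies are
  scrubbed, making planted counts exact.
* **Hydrodynamics.** (s, D) samples come from the sphere/frictional-ratio
  forward model and the Svedberg relation at the same mass, with
  multiplicative Gaussian noise of a given CV on each. SE gradients follow
  the single-species exponential with additive Gaussian noise.

All draws flow from one `numpy.random.default_rng` (PCG64) per generator
call, so identical seeds give byte-identical outputs. What the generators
do **not** emulate: phylogenetically realistic evolution (substitutions
only, no indels), compositional bias in decoys, overlapping gene nests,
or real oriT sequence context. Passing closed-loop tests therefore
demonstrates the pipeline's internal consistency, not its performance on
real, diverged families.

## Hydrodynamic conventions

Internal arithmetic is cgs: R = 8.314462618×10⁷ erg mol⁻¹ K⁻¹,
s in 10⁻¹³ s, D converted from μm²/s, radii in cm, ω in rad/s. Default
conditions are water at 20 °C (ρ = 0.99823 g/mL, η = 1.002 cP) and the
generic protein partial specific volume v̄ = 0.735 mL/g — with exactly
these values the three reference frictional ratios (1.5 for a ~42.4-kDa
tetramer at 2.9 S, 1.6 and 1.2 for the ~111.6/74.4-kDa hexamer/tetramer
readings at 5.1 S) reproduce to one decimal. A Cohn–Edsall
composition-based v̄ calculator is provided for user sequences but is not
used in those reference checks, because the buffer and tag-specific v̄
behind published values is generally unrecoverable; Svedberg-mass
reproduction is accordingly bracketed at ±2 %, not exact. The
s₂₀,w correction requires explicit buffer density and viscosity for the
same reason.

Oligomer assignment minimizes the relative deviation |M − n·monomer| over
n = 1..12, assigns when it is ≤ 10 % (generous against the ~0.3–0.5 %
deviations of well-determined SE masses), and breaks numerical ties toward
the smaller n.

SE fitting pins the reference radius r₀ to the innermost data point (it is
fully degenerate with the amplitude), seeds the nonlinear refinement with a
60-point log-spaced scan over M in which amplitude and baseline are solved
linearly, then refines (M, c₀, baseline) with `scipy.optimize.curve_fit`.
Noiseless recovery is exact to solver tolerance; with 1 % noise on an
80-point gradient the mass comes back well within 2 % (checked over 50
seeded replicates at both reference masses, rotor speeds 15,000 and
10,000 rpm chosen so the gradient spans a realistic ~10–20× dynamic
range). Fixed-mass comparison fits report RMSD per candidate
stoichiometry; fewer than 20 radial points is an error.

## Problem sizes in the test suite

The closed-loop study uses 20 replicons (~120 genes, ~36 k database
residues), sized so the whole suite runs in a few seconds on one CPU while
still exercising every stage; the alignment-vs-brute-force oracle runs on
sequences ≤ 12 residues where the O(mn) reference DP is instant, and the
palindrome oracle enumerates all substrings of sequences ≤ 60 bp.

## Known limitations

The homology module does not reproduce any particular BLAST release's
scores or E-values (no composition-based statistics, no length
corrections); the secondary-structure predictor is a classical propensity
method and will not match machine-learned predictors on real proteins;
database-scale co-occurrence counts depend on the database snapshot and
are out of scope; inverted-repeat detection covers perfect, spacer-free
palindromes only; and binding-constant estimation from EMSA titrations,
c(s) distribution modeling and DLS autocorrelation analysis are consumed
as inputs, never computed.
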