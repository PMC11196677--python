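# Methods

This note records the model underlying `mitocompare`, the default parameter
choices and their rationale, what the synthetic-data generator does and does
not emulate, and the known limitations. Everything here is implemented in the
modules named in parentheses.

## Sequence and feature model (`mitocompare.io`)

A genome is a `CircularSequence` (uppercase residues, `circular` or `linear`
topology) plus a list of `Feature`s. Coordinates are 0-based, half-open, on
the forward strand; a feature that spans the replication origin is stored as
two intervals `[(s, L), (0, e)]` rather than special-cased arithmetic.
Feature sequences are the concatenation of their intervals,
reverse-complemented for `-` strand features. CDS and ORF features must have
lengths divisible by 3. Translation uses the invertebrate mitochondrial code
(NCBI table 5: ATA→Met, TGA→Trp, AGA/AGG→Ser); only TAA/TAG act as stops.
GenBank parsing maps `tRNA-Xxx` products to `trnX` names (duplicates
suffixed `1`/`2` in parse order), 16S/12S rRNAs to `rrnL`/`rrnS`, and CDS
named `orf*` to ORF features.

## ORF scan (`mitocompare.orfs`)

Six reading frames are scanned by walking codons over the doubled sequence
(circular topology), so origin-spanning ORFs are found naturally and
reported as two-interval features. Within a frame, each stop closes at most
one ORF, attributed to the *earliest* start codon since the previous stop
(the maximal ORF). Defaults: minimum length 300 nt including the stop, start
codons {ATG, ATA, ATT, GTG} — a conservative subset of the table-5 starts
reflecting starts actually annotated in bivalve mitogenomes. An ORF is
*unassigned* when less than half of its span overlaps annotated non-ORF
features; the 0.5 threshold tolerates the small terminal overlaps common in
compact mitogenomes while rejecting ORFs that merely re-read an annotated
gene in its own or a shifted frame.

## Alignment (`mitocompare.align`)

Global (Needleman–Wunsch) alignment with affine gap costs; the first residue
of a gap costs `gap_open + gap_extend`, each further residue `gap_extend`.
Terminal gaps are penalized (true global alignment). Defaults: gap open 3,
gap extend 3 at both levels; nucleotide match +1 / mismatch −1; protein
scoring by BLOSUM62. When several alignments are optimal, the first traceback
of the underlying dynamic program is returned — deterministic for a given
input, and all downstream statistics depend only weakly on the choice (the
score, and the null distribution built from scores, not the traceback, carry
the inference). Correctness is checked in the test suite against brute-force
enumeration of every monotone alignment on short pairs.

## Divergence statistics (`mitocompare.divergence`)

`p_distance` uses pairwise deletion: columns containing a gap or N (and at
protein level X or `*`) are excluded; `p = P + Q` with `P` the transition
fraction (A↔G, C↔T) and `Q` the transversion fraction over compared sites.
The Tamura 3-parameter distance uses the pooled GC content θ of both rows
over compared sites, `h = 2θ(1−θ)`:

d = −h·ln(1 − P/h − Q) − ½(1 − h)·ln(1 − 2Q)

Saturation (non-positive log argument) is reported as a flag with `d = NaN`,
never an exception, because saturated pairs are an expected observation when
comparing F-type against M-type genes. Sliding-window profiles slide over
alignment columns (window 100, step 25 by default — fine enough to localize
a divergence breakpoint to ±(window/2 + step) while keeping per-window
binomial noise moderate). Skew profiles (`(A−T)/(A+T)`, `(G−C)/(G+C)`,
GC content relative to the genome mean) slide over the circular genome and
can be restricted to codon-position or noncoding site classes.

## Homology null test (`mitocompare.homology`)

To ask whether an unassigned ORF is a diverged copy of a known gene, the
observed alignment distance is compared with the distances obtained after
composition-preserving shuffles of the gene. The reported p-value is the
left-tail add-one estimate `(#{null ≤ observed} + 1)/(n_reps + 1)`: exact,
and conservative in the presence of ties (its mid-p variant is uniform under
the null; the test suite verifies both calibration and ≥95% power at amino
acid p = 0.30). The ORF × gene screening grid applies a Bonferroni threshold
`alpha / n_tests`; since the smallest achievable p is `1/(n_reps + 1)`, the
screen defaults to `n_reps = 500` so that grids up to ~25 tests remain
decidable at alpha = 0.05, and emits an explicit flag when the floor exceeds
the corrected threshold. Untranslatable features (internal stops) are
reported as flagged rows, not errors.

## Gene order (`mitocompare.gene_order`)

A genome's order is canonicalized by sorting features by start, flipping the
whole order if the anchor gene (default cox1) lies on the minus strand, and
rotating the anchor to the front — making the representation invariant to
rotation and to which strand was sequenced. Breakpoint distance counts
strand-aware circular adjacencies (canonical spelling
`min((x,y), (flip y, flip x))`) present in one order but not the other,
restricted to shared labels; it is 0 iff the orders are equal up to rotation
and reflection-with-strand-flip. `minimal_scenario` searches for a shortest
sequence of operations (contiguous block relocation, two-element swap)
transforming one order into the other by iterative-deepening search with the
admissible bound that one operation changes at most 4 adjacencies (a swap of
two non-adjacent elements touches 4; relocations touch 3): depth `d` with
breakpoint distance `b` is pruned when `b > 4·(limit − d)`. Minimality is
therefore exact within `max_ops` (default 4), and is verified in the tests
against exhaustive enumeration.

## Synthetic data (`mitocompare.simulate`)

The generator builds an F-type template of 37 features (13 CDS including the
seven nadh genes, 2 rRNAs, 22 tRNAs; two tRNAs on the minus strand) at
realistic lengths, separated by TTAA-repeat spacers (stops in all six frames
within a few codons, so annotation boundaries also break reading frames),
targeting ~19.5 kb. Coding sequence is sampled codon-wise from an AT-rich
distribution; afterwards every non-coding frame is patched with randomly
placed, randomly spelled stop trinucleotides (TAA/TAG forward, TTA/CTA on
the reverse strand — both Leu in the coding frame) until no stop-free run
exceeds 30 codons. This guarantees the ORF scan recovers exactly the planted
reading frames, and — because patch positions and spellings are random per
sequence — independently generated "non-homologous" sequences share no
systematic motifs that a shuffling null would detect.

The M-type genome is derived from F by (i) in-place substitution of each
kept gene at a planted divergence (`exact_planting` substitutes exactly
`round(p·L)` positions, never creating an in-frame stop, making distance
recovery a sharp deterministic check; `stochastic_jc` substitutes per-site
for exercising saturation behavior; transition bias kappa = 2), (ii)
dropping the seven nadh genes, (iii) planting 3 random ORFs
(4002/951/852 nt), (iv) extending cox1 3′ by 999 nt of novel coding
sequence, and (v) applying up to 3 template rearrangement moves. A
`TruthTable` records realized per-gene divergence, the homologous
correspondence and its extent, ORF coordinates and the applied moves, so
that every estimator can be replayed against ground truth. Defaults
(divergence 0.45, genome ~19.5 kb, 3 ORFs, 7 dropped genes) are the study
conditions for all reported results.

Deliberately **not** modeled: tRNA/rRNA secondary structure (placeholders
are random sequence of realistic length), split genes (all planted genes are
contiguous; split-feature *parsing* is still supported and tested in the io
layer), read-level data, coverage, assembly, and phylogenetic tree building.

## Pipeline determinism (`mitocompare.pipeline`)

All randomness flows from one top-level seed: per-stage seeds are derived via
`numpy.random.SeedSequence` (each below 2³¹). Re-running with the same config
and seed reproduces every output file byte-identically, which the test suite
asserts.

## Limitations

- The Tamura 3-parameter correction assumes a stationary, homogeneous
  process; at the divergences typical of F/M comparisons it frequently
  saturates, which is reported rather than extrapolated.
- The homology test's add-one p-value is conservative under heavy score
  ties (short or low-complexity sequences); power claims hold for the
  default scoring at the tested lengths.
- Scenario minimality is exact only within the operation set {block
  relocation, swap} and `max_ops`; biological scenarios using other
  operations (inversions, tandem duplication–random loss) are out of scope
  of the search.
- The simulator's composition model is a single genome-wide codon
  distribution; it does not reproduce strand-asymmetric skew structure.
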