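# Methods

This note documents the model behind each pipeline stage, the defaults
and why they hold, the numerical conventions, and what the synthetic
benchmark does and does not demonstrate.

## Homology search

The search treats a hit as an **ungapped** alignment window between a
mature miRNA (RNA, U matched as T) and an EST (DNA, both strands).  A
window is a hit when all four conditions hold:

* length within [`min_len`, `max_len`] = [18, 24] nt — the observed
  range of plant mature miRNAs;
* at most `max_mismatches` = 3 mismatches ("less than 4");
* percent identity **strictly** above `min_identity_pct` = 85 — both
  printed bounds are applied jointly as printed, so a 20-nt window with
  3 mismatches (exactly 85.0%) fails;
* at least one exact run of `word_size` = 7 consecutive matches.

The last condition is deliberately part of the hit definition, not just
an implementation detail of the seeded search: a word-seeded aligner is
blind to windows whose mismatches break every seed word (an 18-nt
window with 3 evenly spread mismatches has a longest exact run of 6),
and making word survival part of the contract is what lets
`find_hits` (seed per diagonal, enumerate windows on seeded diagonals)
and `brute_force_hits` (enumerate *every* window, numpy-vectorized)
agree exactly — which the test suite asserts on randomized instances.
Gapped alignment is not offered: at 18–24 nt and >85% identity a gap
costs more than the mismatch budget allows, so short-word BLASTN
alignments in this regime are effectively ungapped.

No e-value is computed.  The identity, mismatch and length bounds
dominate selectivity at these lengths, and an e-value would add a
dependence on database size without changing which windows survive.

Overlapping windows of the same (miRNA, EST, strand) collapse to the
one with the most identities (ties: leftmost, then shortest, then
smallest query offset).  The tie-break is orientation-dependent by
construction, so strand symmetry holds at the level of merge clusters,
not individual representatives.  Coordinates are 0-based half-open
internally, 1-based inclusive only in written reports.

## Precursor extraction

The window is `flank` = 100 nt on each side of the hit, **including**
the mature: a 20-nt hit with full flanks yields a 220-nt precursor
(LP = LM + 200).  ESTs shorter than 200 nt contribute their entire
sequence; flanks truncated by an EST edge are kept rather than the hit
discarded, since short-EST fallback is tolerated anyway.  Minus-strand
hits are reverse-complemented so precursors always read 5'→3' with the
mature in sense orientation, then transcribed to RNA.

Protein-coding screening is pluggable because a live protein-database
alignment cannot be part of an offline pipeline: users who run one
externally feed the flagged EST ids back as an exclusion list, and an
optional built-in ORF screen (default off) drops candidates containing
an ATG→stop frame of ≥ `min_orf_aa` codons.  Note that at the default
window size an 80-codon ORF (243 nt) cannot fit a 220-nt window, so the
default threshold only bites with larger flanks; it is retained as a
conservative default rather than silently lowered.

## Folding and statistics

Folding is a backend contract: sequence in, MFE dot-bracket structure
plus energy (kcal/mol at 37 °C) out.  The reference backend is the
ViennaRNA library; energies are rounded to 0.01 kcal/mol (the model's
own resolution) so that folds written to the Vienna-triplet text format
replay byte-identically through the `PrecomputedFolds` backend, which
is accepted anywhere a backend is — no stage requires a folding library
at run time if folds are supplied.  Temperature and other model options
are defaults; N bases are unpairable, count toward length, and count
toward neither G+C nor AU.

Statistics: AMFE = MFE/L·100 (sign preserved), MFEI = |AMFE| / G+C%.
MFEI is reported as a positive magnitude, matching the convention of
published pre-miRNA tables in which MFE is negative but MFEI positive.
The formula reproduces all three published worked rows of the
reference analysis to 8 decimals, which is how it was confirmed.

## Hairpin criteria

All six criteria are evaluated on every candidate with no
short-circuit, so a report line explains every failure:

1. a stem exists (`no_stem`);
2. the mature lies on one arm, 5p or 3p (`mature_not_in_arm`) — the
   terminal loop is that of the stem owning the most base pairs, ties
   toward the leftmost closing pair; matures with fewer than half their
   positions paired are `unpaired`;
3. at most 5 mature positions unpaired or mispaired against the star
   (`too_many_star_mismatches`); G·U wobble counts as paired, since it
   is a structural pair in every folding model;
4. the star has no loop overlap and no break — a run of more than 2
   consecutive positions without a valid partner in the mature
   (`star_loop_or_break`); the tolerance of 2 accommodates both the
   canonical 2-nt overhang and 1–2-nt bulges, which real miRNA/miRNA*
   duplexes contain;
5. MFEI within [0.65, 0.85] inclusive, **after rounding to 2 dp**
   (`mfei_below_min` / `mfei_above_max`).  Rounding is deliberate: the
   reference analysis accepted a candidate whose 8-decimal MFEI
   (0.85361208) exceeds the stated 0.85 ceiling, which is consistent
   only with a rounded, inclusive comparison;
6. AU% within [30, 70] (`au_below_min` / `au_above_max`).

The star sequence is the span of the mature's pairing partners shifted
2 nt toward the star's 3' side and clipped to the precursor — the Dicer
duplex geometry, in which *both* strands carry a 2-nt 3' overhang.  The
published tables print star sequences whose lengths track the mature's
(LS ≈ LM), which a one-sided 2-nt extension would not produce.  Duplex
mismatches (criterion 3) are counted against the *unshifted* pairing
span, so a perfect duplex scores 0 and k engineered star mutations
score exactly k; counting against the shifted interval would charge the
overhang itself as 2 permanent mismatches.

## Target prediction

Complementarity is scored over the 5'-most `hsp_size` = 20 nt of the
miRNA, the served default for "length for complementarity scoring".
Each alignment column, indexed from the miRNA 5' end, contributes:
Watson–Crick 0, G:U wobble 0.5, other mismatch 1, gap 2, with penalties
doubled inside the seed region (positions 2–13).  The expectation is
the sum; sites at or below `max_expectation` = 3 are reported.  Gaps
are limited to band 1 (site length within ±1 of the scored miRNA
length), with the cheapest single-gap placement taken — a site needing
two gaps is already past the expectation threshold on gap penalties
alone.  These penalty constants follow the cited target server's
published schema and are all configurable; the thresholds (3, 20,
9–11) are the analysis' own printed parameters.

A site is classified as **translational inhibition** when any penalized
column faces miRNA positions 9–11 (the RISC slicing window), otherwise
**cleavage**.  Target accessibility (the UPE ≤ 25 energy bound) is
carried in the configuration for fidelity but not computed: it needs a
partition-function model and does not change the expectation filter,
which is the primary, offline-testable computation.

## Phylogeny

Distances are p-distances (differing sites / pairwise-alignable sites)
over a global alignment with match 1, mismatch −1, gap −2; columns
gapped in either sequence are excluded from the denominator.  Trees are
built with canonical Saitou–Nei neighbor joining: deterministic Q-tie
breaking toward the smallest active index pair, negative branch
estimates clamped to zero with the deficit moved to the sibling so path
lengths are preserved, and the final three nodes joined by the
three-point formulas.  NJ is consistent on additive matrices, which the
tests exploit: matrices generated from random trees are inverted
exactly (path lengths to 1e−9, topology at Robinson–Foulds 0 against an
independent NJ implementation).  Both mature and precursor input modes
are supported.  Bootstrap support and likelihood models are out of
scope; the tree is a deterministic baseline for relationship inspection.

## Synthetic benchmark

`simulate` generates the study conditions end to end: 21-nt matures
(the modal plant length) at 45% G+C; ESTs of 300–900 nt (typical
single-pass cDNA reads); precursors built as GC-clamp + mature + 8-nt
A/C-biased loop + mutated reverse complement + clamp.  The 3-bp clamp
anchors the helix end so the mature duplex is interior — without it a
weak terminal A-U pair is sometimes left open by the folding model and
would read as a spurious duplex mismatch.  Every generated precursor is
folded and *verified* (dominant stem, mature on 5p, exactly the
requested number of duplex mismatches) before use, with redraws on
failure, so fixtures mean what tests assume.  Star mutations are placed
at interior positions, never 3 consecutive, and substituted with bases
that pair neither canonically nor by wobble.  Mature-region mismatches
planted in ESTs spare the first 8 nt so a 7-mer seed always survives
and the homology stage can find the locus.  Half the positives are
reverse-complemented to exercise minus-strand handling.  Negatives are
iid-random or dinucleotide-shuffled positives (Eulerian-path shuffle,
preserving exact dinucleotide counts).

What this does not emulate: EST error profiles (chimeras, poly-A
tails, vector contamination), genuine genomic flanking context around
precursors, multi-hairpin clusters, or realistic miRNA family
structure.  Passing on synthetic data therefore demonstrates
correctness of the algorithms under the stated model — recovery of
planted signal, agreement with brute-force oracles, exact
bookkeeping — not sensitivity or specificity on real EST collections,
which depend on database snapshots outside this package's scope.

## Problem sizes and determinism

The test and acceptance workloads use small instances chosen to make
exhaustive oracles practical — ESTs of a few hundred nt against
brute-force window enumeration, transcripts of a few hundred nt against
an all-window duplex scorer, trees of 4–12 taxa — since the algorithms'
complexity is linear-ish in input size and the oracle comparisons are
what establish correctness.  Every stochastic fixture is driven by a
single seeded numpy generator; pipeline outputs are formatted with
fixed float precision and relative manifest paths, and two runs on
identical inputs are byte-identical, which is asserted in the suite.
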