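# Methods

## Scope and data

The package analyzes mature RFamide peptides of two families: chordate
GnIH-family peptides (LPXRFamide, X = L or Q, in jawed vertebrates;
PQRFamide in lamprey and amphioxus) and the FMRFamide-like peptides (FLPs)
of *C. elegans*.  The packaged catalog was curated from the primary
biochemical literature on these families and is frozen as TSV:

* 26 chordate peptides from human, quail, newt, coelacanth, zebrafish,
  gar, lamprey and amphioxus; identification flags mark peptides whose
  mature structure was confirmed by mass spectrometry or purification.
* 71 distinct FLPs encoded by the 31 *flp* genes (*flp-1* … *flp-28*,
  *flp-32* … *flp-34*; *flp-29/30/31* do not occur in *C. elegans* and are
  recorded as absent genes, not zero-peptide genes).  41 FLPs carry the
  biochemically-identified flag.  Multi-copy peptides (e.g. FLP-6,
  encoded six times) carry a `copy_number` but count once in
  distinct-peptide totals, which is why the totals are 71 and 97.
* A predicted quail RSamide peptide (APNLSNRSa) is packaged in a separate
  file and excluded from the grouped 97-peptide set, since it carries no
  curated group assignment.
* A 51-record precursor manifest (accessions only; 8 GnIH + 9 NPFF +
  1 FMRFamide + 32 FLP precursors + 1 hydra insulin-like outgroup)
  documents the precursor-level analysis.  Sequences are deliberately not
  distributed and are never fetched; users may attach their own FASTA.

Amidation is a boolean flag, not a sequence character: sequences stay pure
residue strings for distance computation, and the display layer renders
the conventional trailing lowercase "a".

## Prohormone processing model

An amidation cassette is `G[KR]{1,2}`: the glycine donates the C-terminal
amide and the following mono- or dibasic run is the endoproteolytic site.
Coordinates are 0-based half-open, and neither the glycine nor the basic
run belongs to the peptide body.

The upstream boundary is the nearest upstream K/R that leaves a body of at
least `min_len` residues.  A literal "nearest basic" rule is unusable for
this family: essentially every RFamide peptide has an arginine at position
−2 (the R of the R-F-amide), so the nearest basic would truncate every
true peptide to one residue.  Skipping basics that leave a body shorter
than `min_len` recovers the intended cut while still accepting monobasic
upstream sites and peptides with internal K/R (e.g. SIKPSAYLPLRFa).  If no
upstream basic leaves a valid body, the nearest one is used and the call
falls to the length filter; with no upstream basic at all the body starts
at position 0 and the call is flagged `n_terminal_open` (signal-peptide
prediction is out of scope).  Overlapping and nested calls are all
reported; downstream filtering is the caller's choice.  Non-RF amide
termini (e.g. the RSamide of human RFRP-2) are labeled, never dropped,
unless `require_rf_family` is set.

Defaults `min_len=4`, `max_len=40` bracket the catalog (shortest body
AMMRF, 5 residues; longest FLP-33, 24) with headroom; no minimum or
maximum mature-peptide length is established for these families, so the
bounds are deliberately loose.

A substring-enumeration brute-force scanner (`rfamide.bruteforce`)
re-derives the same call set independently and backs the oracle tests.

## Five-group classification

Decision order: (1) exact-sequence exception table; (2) `PQRF` suffix ⇒
PQRFa; (3) the −3 rule — residue −2 is R, residue −1 ∈ {F, Y, S, L}, and
residue −3 ∈ {M, L, V, I} names the group; (4) UNRESOLVED.  Evaluating the
PQRF suffix before the −3 rule keeps the PQRFa group pure (LPQRF termini
would otherwise land in LRFa).  The −1 tolerance set is the minimal set
covering the catalog's non-F amides (MRYa, LRSa, LRLa); widening it
changes nothing on the packaged catalog, which the test suite asserts.

The default exception table has exactly one entry: FLP-33
(APLEGFEDMSGFLRTIDGIQKPRFa), whose −3 residue is P but which is curated
into the LRFa group from its evolutionary placement.  Users can extend the
table via TSV.  Classification is a pure function of sequence plus table —
independent of the rest of the input set — and on the packaged catalog it
reproduces the curated grouping 97/97 with sizes 14/32/16/16/19.

## Peptide phylogeny

Because the families are conserved at the C-terminus and grouped by their
last residues, the default alignment right-anchors peptides: rows are
left-padded with gaps to the maximum length.  An externally aligned FASTA
can be substituted.  No canonical alignment exists for these short
peptides, so the peptide tree is scored by *clade concordance* with the
five groups rather than against any fixed reference topology.

p-distance: fraction of differing residues over shared non-gap columns
(pairwise deletion, default) or over gap-free columns (complete deletion).
Complete deletion over right-anchored short peptides keeps only
`min(length)` columns and is therefore not the default.  Pairs sharing
fewer than `min_shared=3` columns raise an error naming the pair; the
bootstrap relaxes this to `min_shared=1` and scores a fully undefined pair
as distance 1.0, since column resampling of short peptides occasionally
leaves near-empty overlaps.

Neighbor joining follows the canonical Saitou–Nei agglomeration.  Numerical
determinism choices: ties in Q break to the lowest (row, column) index in
the current matrix order (new nodes append at the end); negative branch
lengths are clamped to zero with the original value logged; the final
three nodes are resolved by the three-point formulas, yielding an unrooted
binary tree stored with a trifurcating root.  On additive matrices the
implementation recovers the generating topology and path lengths to 1e−9,
verified against an exhaustive oracle that enumerates all (2n−5)!!
unrooted topologies and least-squares-fits branch lengths (practical to
n = 8).

Bootstrap support resamples alignment columns with replacement per
replicate (NumPy generator, explicit seed required — there is no silent
default RNG state); the support of an internal edge is the fraction of
replicate trees containing the same bipartition.  Default 50 replicates.

Clade concordance reports, per group, whether the group's leaves form one
side of some tree edge and otherwise the minimum number of leaves to
remove to make them do so.  That minimum is computed exactly for every
group size by scanning all edges — pruning leaves cannot create a
separating edge that does not correspond to an original edge — so no
greedy fallback is needed.

Newick output is a fixed dialect (branch lengths and supports at six
decimals, supports as internal labels, single-quoted labels containing
metacharacters) whose write→read→write composition is byte-idempotent.

## Synthetic precursor generator

The generator emulates the architecture of real RFamide precursors: spacer
sequence, then for each payload an upstream basic residue, the body, the
amidation glycine and a mono/dibasic run.  Spacers are drawn from an
alphabet without K, R or G so every cassette in the sequence is either a
payload or a labeled decoy; a "hard mode" is deliberately not the default
because clean spacers separate recall and precision failure modes.  Decoy
kinds: a glycine followed by a non-basic residue (`g-no-basic`), a stray
basic in a spacer (`basic-no-g`), and a genuine cassette with a body
shorter than `min_len` (`short-body`), which the generator places more
than `max_len` residues from any upstream basic so the length filter
removes every candidate call.

Default conditions: 3 payloads per precursor, uniform motif mix over
{LPXRFa-L, LPXRFa-Q, PQRFa, generic-RFa}, spacer lengths 8–24, body
lengths 4–20, decoy rate 0 (benchmarks use 0.3).  De novo payload bodies
contain no K/R/G outside the requested motif and rejection-sample away
accidental upgrades (e.g. a PQRF body acquiring an LPQRF terminus), which
makes coordinate-exact recovery provable.  "catalog" mode embeds real
cataloged peptides instead; peptides beginning with K/R (KSAYMRFa,
KPNFLRFa, …) or containing internal G-R motifs are then genuinely
ambiguous — no sequence-local rule can tell the peptide's own lysine from
a cleavage site — so exact-coordinate guarantees apply to random mode
only.  Per-record seeds derive from the master seed by a fixed integer mix
(`(master · 1000003 + 10007 · index + 1) mod 2³¹−1`), so regenerating any
subset of a dataset is stable.

What passing synthetic tests do *not* show: performance on real
precursors, which contain signal peptides, occasional non-canonical
processing sites, and basic residues inside spacer regions.  The synthetic
recall/precision of 1.0 certifies the implementation of the stated rules,
not the biological completeness of the rules themselves.

## Problem sizes used in checks

The automated checks run at desk scale, chosen to keep everything
exhaustively verifiable: 200 random additive matrices on 4–8 leaves for
the NJ oracle (topology enumeration is (2n−5)!!, 10,395 at n = 8), 1,000
random sequences of length ≤ 200 for the scanner oracle, 50 precursors at
decoy rate 0.3 for the round trip, 50 bootstrap replicates over the full
97-peptide catalog, and 100 random trees for Newick idempotency.

## Known limitations

* The exact published peptide-tree topology for these families depends on
  an alignment procedure that is not reproducible from printed data; this
  package therefore treats the tree as a derived, concordance-scored
  artifact rather than a fixed expected output.
* Prohormone convertase preferences (PC1/PC2), signal peptides, and
  modifications other than C-terminal amidation are not modeled.
* Right-anchoring is a deliberate, simple alignment choice; supplying an
  external alignment changes distances and tree accordingly.
* The receptor table ships as static metadata only; no receptor-level
  computation is performed.
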