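# Methods

## Scope and model

`tcmariner` implements the desk-scale analysis chain for characterizing
Tc1/mariner (ITm) DNA transposons: mining-filter → profile alignment →
DDD/E motif classification → element annotation → copy census → phylogeny
→ tanglegram congruence → horizontal-transfer (HTT) screening.  The
package assumes amino-acid transposase sequences for classification and
phylogeny (slower-evolving, alignable across the superfamily) and
nucleotide element sequences for structural annotation and identity-based
screening.

## Coordinates and identity

Internally all coordinates are 0-based half-open; the 1-based inclusive
convention of BLAST tabular files exists only at the parse/write
boundary, and minus-strand subject hits are normalized to
(min, max) + strand.  Percent identity is defined once, everywhere, as
identical columns divided by total alignment columns **including gap
columns** (the EMBOSS `stretcher` convention).  This matters: the HTT
thresholds (95/92/80) and the TIR identity floor are all expressed in
this one currency.

## Pairwise and profile alignment

Global pairwise alignment is Needleman–Wunsch with affine gaps via
Bio.Align.PairwiseAligner (BLOSUM62 for protein, +5/−4 for nucleotide;
gap open 10, extend 0.5 — the cited tools' conventional defaults, all
configurable).  Sequence-to-profile alignment is a hand-written affine
DP of the query against per-column mean BLOSUM62 scores with the seed
columns frozen: existing profile rows are never modified, query residues
either occupy a seed column or are recorded as insertions between
columns.  End gaps are charged, keeping the alignment global on both
axes.  The catalytic columns of the seed profile are a required
configuration input (three increasing column indices); the synthetic
seed profiles record them in their truth tables.

## Motif spacing convention

The family signature counts residues **strictly between** the second and
third catalytic positions: DD34E means pos3 − pos2 − 1 = 34.  An
off-by-one here corrupts every downstream classification, so the
convention is fixed in `MotifCall.spacing` and covered by construction
tests.  The first interval (pos1→pos2) is reported but never used for
classification.  Degenerate residues at catalytic columns are kept
verbatim in the signature (DD34S, DA30P, …) and flagged as
domesticated-gene-like; they are never silently rejected.  The DD34E
signature maps to the candidate set {Tc1, Tec, TBE, HvSm} because those
families are separable only phylogenetically; DD(30–35)D not otherwise
claimed maps to pogo, whose subgroup spacings are clade-dependent.

## TIR detection

Elements are assumed pre-excised (TIR-to-TIR), so the search is
terminal-anchored: candidate lengths up to a window (default 150 nt) and
per-end offsets up to a slack (default 5 nt) are scanned, scoring the
ungapped identity of the 5′ segment against the reverse complement of
the 3′ segment.  Candidates are ranked by identity, then length, then
terminal-most placement.  Ranking by identity first (rather than raw
match count) prevents chance matches just beyond a clean repeat from
inflating the reported length; with the defaults (min length 10, min
identity 80% — below the shortest printed TIR of 15 bp) planted TIRs of
15/20/56 bp are recovered at their exact lengths, and random 800-nt
sequences yield a false positive in ≤ 1% of replicates.

## ORF scanning

Every ATG is paired with its nearest in-frame downstream stop in all six
frames (stop included in the coordinates, excluded from the codon
count), so nested ORFs sharing a stop are all reported, longest first.
Random sequence can contain incidental long frames, which is why
downstream consumers (the HTT screen) treat "transposase = longest ORF"
as a heuristic and degrade to `unverifiable` when no catalytic triad is
detectable in its translation.

## Copy census

Hits are clustered into loci by single-linkage on the subject within a
gap of 2× element length (same subject, same strand).  Classification
precedence is full-length → MITE → partial → non-autonomous →
unclassified, all boundaries inclusive.  MITE outranks partial because a
locus covering both TIRs at high identity can incidentally satisfy the
weaker partial rule, and the TIR-specific evidence is the more specific
claim.  Coverage for full/partial/non-autonomous is the single best
hit's span on the element; the MITE rule accepts either one hit spanning
both TIRs or separate hits on each, with the minimum identity over the
TIR-overlapping hits as the conservative locus identity.

## Phylogeny

p-distances use pairwise deletion of gap columns (a pair with no
comparable columns is an error naming the pair).  Neighbor-joining is
the canonical Q-criterion agglomeration with ties broken by the smallest
taxon-index pair and negative branch lengths clamped to zero with the
deficit moved to the sister branch — bit-reproducible by construction.
Bootstrap resamples columns with one seeded generator; support is the
percentage of replicate trees containing the same bipartition.
Likelihood inference is deliberately not reimplemented: externally
computed Newick trees (support values read from internal-node labels)
are first-class inputs to rooting, clade extraction and the tanglegram.
Outgroup rooting places the root on the edge separating the smallest
clade containing the outgroup; a non-monophyletic outgroup roots at the
edge maximizing the outgroup fraction and flags the result.  Supported
clades are maximal nodes with support ≥ 70% (default) whose parent edge
does not qualify; leaves outside every group are reported as isolated.

## Tanglegram

The host tree is the taxonomy table's rank hierarchy (kingdom → species)
rather than a molecular tree, matching how host relationships enter this
kind of analysis.  Crossings are counted as strict inversions of the
link permutation (O(n log n), links sharing a row never cross).
Minimization alternates barycenter sweeps over both trees, then applies
a greedy adjacent-child-swap (sifting) pass that escapes
equal-barycenter local optima; the result never exceeds the initial
crossing count.  The congruence statistic is the crossing count
normalized by the number of link pairs.  Zero crossings for congruent
inputs requires the TE tree to be *rooted* compatibly with the host
hierarchy — an unrooted NJ tree whose trifurcation falls inside a host
clade cannot be rotated into agreement — which is why the workflow roots
on an outgroup before tangling.

## HTT screen

Pairs are evaluated only when their hosts differ at or above a gate rank
(default phylum; "distantly related" pairs named in this literature are
kingdom- or phylum-level).  The decision table, in order: single genomic
copy in either genome → rejected contamination suspect (a resident
transposon leaves multiple copies); per-copy identity below 92% in
either genome, or full-element identity below 80% → rejected divergent;
per-copy identities ≥ 95% in one genome but < 95% in the other →
rejected contamination suspect with the asymmetry flag; genome hit table
missing → unverifiable; otherwise candidate.  The 92% and 80% constants
are the observed rejection conditions of the screening procedure, not
tuned values.  Tightening any threshold can only move verdicts away from
candidate.

## Synthetic data: what it emulates, what it does not

The generators produce the statistical structure each stage assumes, with
machine-readable truth tables; recovery tests read truth, never re-derive
it.

* **Families** — an ancestor with the planted triad; descendants by
  i.i.d. uniform substitutions at non-catalytic sites only.  Catalytic
  immutability guarantees exact motif ground truth at any divergence;
  this favors testability over realism (real domesticated elements do
  degrade their triads — that case is covered by explicit degenerate
  signatures instead).  The non-catalytic background excludes D/E so the
  planted triad is unique at divergence 0.
* **Elements** — flank+TA+TIR+internal(ORF)+inverted TIR+TA+flank, with
  the 3′ TIR mutated down to a target identity and the base adjacent to
  the TIR forced non-complementary so the planted boundary is sharp.
* **Hit tables** — per planted copy, identity/coverage drawn inside its
  class band (bands coincide with the census rules, so boundary
  inclusivity is exercised); one scaffold per copy.
* **Cophylogeny** — hosts on a balanced binary rank hierarchy; sequences
  evolve down the same hierarchy at 4% per site per level (200 aa
  default); each transfer event replaces a recipient's sequence with a
  lightly mutated copy of a donor from the other top-level clade while
  the host link stays put.  An optional deeply diverged, unlinked
  outgroup sequence supports rooting.
* **HTT benchmark** — transfer cases (distant hosts, 1–3% diverged
  elements, 3–5 copies ≥ 96% identity in both genomes), contamination
  cases (one genome single-copy) and vertical cases (same phylum).
  Pair divergence touches only frame-safe positions (outside the ORF, or
  third codon positions that cannot create a stop) so the planted
  transposase remains the detectable ORF.

No indels, rate heterogeneity, nested insertions or genome-scale
background are simulated; passing tests demonstrate the correctness of
the decision logic and estimators under their stated assumptions, not
performance on raw survey data.

## Problem sizes and numerical choices

The acceptance benchmarks run at sizes chosen for tight statistics on a
single CPU: 50 six-taxon additive matrices for NJ recovery, exhaustive
enumeration to length 8 over {A,D,E} (plus 50 random length-60
sequences) for the de novo motif oracle, 100 random census
configurations, 60 replicates × 24 hosts per transfer level for the
tanglegram, and 50 cases per class for the HTT benchmark.  Boundary
sweeps step identity by 0.1 point and coverage by 1 nt on a 1000-unit
scale, matching the printed precision of the thresholds they recover.

Rooting the cophylogeny simulations depends on NJ attaching the outgroup
to the root edge; with 200-site sequences the distance noise very rarely
(≈1% of replicates at some seeds) misplaces it, in which case a congruent
replicate shows a small positive crossing count.  This is honest
estimator behavior, not a bug in the crossing minimizer; the fixed-seed
suite and the reported means are robust to it.

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give byte-identical outputs,
including the pipeline's report bundle (logs carry no timestamps for
exactly this reason).

## Known limitations

* The mining loop's novelty clustering (single-linkage at the novelty
  identity threshold) is a deterministic stand-in for interactive
  preliminary-phylogeny inspection; it is tree-free by design.
* The profile aligner handles one query at a time against a fixed
  profile; it is not a progressive multiple aligner.
* NJ + bootstrap is a desk-scale engine; superfamily-scale trees should
  be imported as Newick and flow through rooting, clades and the
  tanglegram unchanged.
* The MITE rule depends on TIR annotation of the reference element; an
  element without detectable TIRs can never yield MITE calls.
* The HTT screen's copy evidence comes from supplied hit tables; it does
  not run genome searches itself.
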