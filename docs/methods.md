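# Methods

## Scope and model

`pyomine` maps *Pseudomonas* genome sequence to pyoverdine function along
three axes: (i) the NRPS assembly line that synthesizes the molecule,
(ii) the substrate selected by each adenylation (A) domain, and (iii) the
FpvA receptor that re-imports the iron-loaded product.  The guiding design
principle is that whole-gene similarity is dominated by phylogeny and is a
poor proxy for function; short *feature sequences* — the Amotif4-5 region of
A domains, and a handful of variable receptor regions — carry the
functional signal.

## Sequence distances

All distances are fractions; percent identity and distance interconvert as
`identity = (1 − d) × 100`.  The p-distance counts mismatches over
comparable columns (both residues ungapped and not 'X'); a pair with no
comparable column raises an error rather than returning 0, because an
unalignable pair must never masquerade as identical.  The Jukes–Cantor
correction is the 20-state protein form

    d = −(19/20) · ln(1 − (20/19) · p),

chosen because it maps 50% identity to d ≈ 0.7099, which is the scale on
which the substrate-calling threshold of 0.7 is defined (the 4-state
nucleotide form would give 0.824 and break that correspondence).  `log1p`
keeps the correction exact near p = 0.  Saturated pairs (p ≥ 19/20, where
the logarithm diverges) receive a sentinel distance of 5.0 and are flagged;
this keeps distance matrices finite for clustering while marking the pair
as uninformative.  Pairwise global alignment uses BLOSUM62 with affine gaps
(open 10, extend 1); the first optimal traceback is taken, which fixes
tie-breaking and makes alignments deterministic.

## Profile HMMs

Models are built from seed alignments: columns with < 50% gaps become match
states; emissions receive Laplace +1 pseudocounts (a six-row seed must not
produce zeros) and transitions +0.1; the background is uniform 1/20
(configurable).  Scores are Viterbi log-odds in bits — emission log-odds
plus log2 transition probabilities — with a global mode (whole sequence
through the whole model) and a local mode in which flanking residues
outside the reported envelope are free.  Insert states emit at background
(log-odds 0), so the self-loop chain solves in closed form and the dynamic
program vectorizes over sequence positions column by column.

Absolute bit scores depend on seed composition and background, so every
gate (STN 25, Plug 50, TonB 80, R1 50, R2 30) is configuration with the
published operating point as default, re-calibratable per model.  On the
shipped fixtures the margins are wide: domain consensus scores run 2–3 bits
per match column, so a 10% point-mutation load costs well under half the
gate margin.

## Synthetase mining

Cluster location deliberately avoids gene prediction: contigs are
translated in six frames, split at stop codons, and segments ≥ 200 aa are
scanned with profile HMMs of condensation/adenylation anchor motifs; a
segment with at least two anchor hits above 12 bits is NRPS-positive, and
positive segments within 2 kb merge into one cluster.  Ordering encodes the
biosynthetic logic — the cluster carrying the co-enzyme-A-ligase marker is
Flu and goes first, the TE-bearing cluster is Pep and goes last, with
two-cluster genomes falling back to genome order and more than three
clusters flagged for manual review rather than silently ordered.  QC:
a line is `truncated` when a cluster sits within 100 bp of a contig edge
and the line lacks Flu or Pep; a line lacking Flu or Pep anywhere is also
`truncated` (it cannot be a producer by definition); a genome with no
cluster at all is a `non_producer`.

Within a synthetase, modules are delimited by condensation-motif anchors
and the motifs (A1–A10, T, E, TE) are located by best-scoring
BLOSUM62-window hits assigned greedily in canonical order; Amotif4-5 spans
from the start of motif A4 to the start of motif A5.  A module missing
either anchor is flagged and excluded from substrate prediction, but the
structure is still emitted with `unknown` at that position.

## Substrate decision rules

With X1 ≤ X2 the Jukes–Cantor feature distances from a query Amotif4-5 to
its two nearest reference substrate clusters (query-to-cluster distance is
the minimum over cluster members, avoiding centroid construction on
sequences):

| condition | rule | call |
|---|---|---|
| X1 < 0.7 ≤ X2 | 1 | nearest substrate |
| X1, X2 < 0.7 and (X2−X1)/X2 > 0.2 | 2a | nearest substrate |
| X1, X2 < 0.7 and (X2−X1)/X2 ≤ 0.2 | 2b | dual (`A\|B`, alphabetical) |
| X1 ≥ 0.7 | 3 | unknown |

The relative difference is taken against the farther cluster, which keeps
it in [0, 1] and well defined at X1 = 0.  Boundary values route to the
larger-distance rule (0.7 itself is "not below threshold"), making the rule
set total on 0 ≤ X1 ≤ X2.  OHOrn is an umbrella label: feature-sequence
comparison cannot separate the three ornithine-hydroxamate derivatives, and
the validation harness likewise counts Lys↔Orn confusions as a separate
category rather than true mismatches.  The substrate vocabulary is open —
new labels enter through the reference TSV without code changes.

## Receptor identification and grouping

Candidates are six-frame ORFs ≥ 700 aa (or user CDS).  The Fpv-like gate
requires length 750–850 aa and STN/Plug/TonB scores strictly above their
gates; equality at any boundary routes to the more conservative class, so
an uncertain candidate is never promoted towards FpvA.

R1 and R2 are *discovered*, not hard-coded: the labelled reference
alignment is profiled for conservation (per-column modal-residue frequency
among non-gap rows; the top decile of columns, ties to the lower index, are
conserved sites), variable regions between consecutive conserved sites are
scored with the FpvA identification score I = mean(positive-vs-negative
p-distance) / mean(positive-vs-positive), and the two highest-I regions
become R1 and R2.  I is a between/within ratio, so it is invariant to
rescaling of distances; zero within-class distance yields an infinite
sentinel (flagged), and a region invariant in both classes scores a neutral
1.  The R1 model is built from the FpvA rows of the R1 slice, the R2 model
from the FpvB rows of the R2 slice.

Group-feature regions (the grouping analogue) are ranked by a multi-class
between/within ratio using group labels from whole-gene single-linkage
clustering of the FpvA references at 60% identity; when that labelling is
degenerate (a single whole-gene group, as on the shipped desk-scale
fixtures), the ranking falls back to pure within-FpvA region diversity,
which selects the same specificity-bearing regions.  The four top regions,
concatenated in alignment order, form the feature sequence; genome
receptors are mapped onto the regions by global alignment to the ungapped
anchor row.  Grouping is single-linkage at 70% feature identity (members
joining at identity ≥ the cut share a group — the transitive closure of the
≥-identity graph).  Note the full-scale study derives group regions from
the annotated proximate receptors themselves; deriving them from the
labelled reference panel is this package's choice, made because a
desk-scale batch is too small to re-estimate conservation stably.

Pep proximity is the base-pair gap between the receptor CDS and the nearest
Pep cluster on the same contig (0 when overlapping, infinite/flagged across
contigs; proximate ≤ 20 kb).  Clade diversity is the Shannon entropy of the
clade's receptor-group counts, natural log by default.

## Dereplication

Non-producers cluster on phylogenetic identity alone, producers on the
conjunction of phylogenetic and whole-synthetase identity (both > 95%);
clusters are transitive closures, and the representative is the most
integrative genome — fewest contigs, ties by total length, then
lexicographic id (the term is not otherwise defined; this is the package's
reading).  Phylogenetic distances are an input matrix, not computed here.

## Synthetic fixtures: what they emulate and what they don't

The generator plants every fact it later asserts: 101 substrate-labelled
reference A domains across 13 substrates plus 2 derivative labels (each
substrate owns a distinct Amotif4-5 signature, references carry 5%
within-cluster noise); a 35-receptor panel (21 FpvA in 5 groups, 6 FpvB,
8 other; all 809 aa, matching the panel's reported mean length) laid out
with exactly ⌈10%⌉ = 81 fully conserved anchor columns so that conserved-
site discovery recovers the designed region boundaries (a post-pass forces
every non-anchor column to vary — shared domain blocks would otherwise go
unanimous by chance); genomes with Flu+Pep lines built from the motif
templates, including a three-cluster strain, an edge-truncated strain
(cluster 53 bp from the contig end, Flu absent) and a non-producer; and
receptor genes at controlled distances from Pep, including a 740-aa
truncation and a corrupted-Plug decoy that must be rejected.  Reference
R1/R2 regions carry deliberately contrasted within-class noise (0.6× and
1.6× the panel noise) mirroring the empirical pattern that R1 is the more
class-conserved of the two peaks — this fixes which discovered region plays
which role.

Deliberately not modelled: insertions/deletions inside feature regions (all
planted features are equal-length, so the alignment path is never
stressed), tailoring enzymes, codon-usage bias (reverse translation uses
one codon per amino acid), phylogenetic autocorrelation of noise, and
receptors split across contigs.  Passing fixture tests therefore
demonstrates the correctness of the decision logic, coordinate bookkeeping
and determinism — not robustness to real-data alignment ambiguity, which
the mutation-load tests probe only partially.

Desk-scale sizes (5 genomes, 4–6 Pep modules, ~60 kb contigs, 300-receptor
classification panels) were chosen as the smallest sets that exercise every
code path, including multi-receptor strains and every QC category.

## Numerical and determinism notes

Every stochastic step flows from one `numpy` Generator seeded by the
fixture spec; the same spec and seed reproduce byte-identical files
(SHA-256-checked in tests), and a pipeline re-run writes byte-identical
outputs.  Tie-breaks are fixed throughout: alignment traceback takes the
first optimum, conserved-site ties take the lower column index, cluster ids
are renumbered in order of first appearance, nearest-cluster ties rank
alphabetically by substrate, and region ranking ties keep alignment order.

## Known limitations

* Motif templates are literature-style consensus strings shipped with the
  package; real synthetases diverge from them more than the fixtures do,
  and motif recovery under heavy divergence degrades (tracked, not
  asserted).
* The Flu/Pep boundary inside single-cluster genomes is left undetermined;
  such lines report all modules and are flagged.
* pHMM bit scores are not comparable across implementations; gates must be
  re-calibrated when models are imported from elsewhere (an optional
  HMMER3 reader is provided for that purpose).
* Lys vs Orn, and the OHOrn derivatives, are inherently indistinguishable
  at the feature-sequence level.
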