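# pyomine

Feature-sequence genome mining of pyoverdine biosynthesis and uptake
machinery in *Pseudomonas*.

Pyoverdines are the fluorescent, high-affinity siderophores of fluorescent
pseudomonads: a conserved chromophore (synthesized by the Flu gene cluster)
carries a strain-specific peptide (synthesized by the Pep cluster) that is
assembled one residue per module by non-ribosomal peptide synthetases
(NRPS).  The adenylation (A) domain of each module selects the amino-acid
substrate; a downstream epimerization (E) domain flips the residue from L to
D; a terminal thioesterase (TE) releases the peptide.  Iron-loaded
pyoverdine is re-imported through FpvA, a TonB-dependent outer-membrane
receptor that is hard to tell apart from related siderophore receptors
(FpvB and others) by whole-sequence homology.

`pyomine` reconstructs this whole pathway from (draft) genome assemblies:

1. **Synthetase mining** — six-frame translation (no gene prediction, so
   fragmented drafts don't break annotation) scanned with NRPS anchor
   profile HMMs; clusters ordered Flu before Pep with TE last; lines within
   100 bp of a contig edge that lack Flu or Pep are dismissed as truncated.
2. **Substrate prediction** — each A domain's *Amotif4-5* feature sequence
   (from motif A4 to motif A5, the substrate-binding pocket region) is
   compared against substrate-labelled references under the 20-state
   Jukes–Cantor distance `d = -(19/20) ln(1 - (20/19) p)`.  With `X1 ≤ X2`
   the distances to the two nearest reference clusters and threshold
   `0.7` (≙ 50% identity):
   rule 1 (`X1 < 0.7 ≤ X2`) → nearest substrate; rule 2a (both `< 0.7`,
   `(X2−X1)/X2 > 0.2`) → nearest substrate; rule 2b (both `< 0.7`, relative
   difference `≤ 0.2`) → dual call; rule 3 (both `≥ 0.7`) → unknown.
   Chirality is D wherever the module carries an E domain.
3. **Receptor mining** — ORF candidates are gated on length (750–850 aa) and
   on profile-HMM bit scores of the STN, Plug and TonB domains (> 25 / 50 /
   80), then classified by two region scores discovered from a labelled
   reference alignment: R1 (Plug/barrel intersection) separates Fpv
   receptors from other siderophore receptors (gate 50), R2 (N-terminal
   signaling domain) separates FpvB from FpvA (gate 30).  FpvA receptors are
   grouped by single-linkage clustering (70% identity) of a feature sequence
   concatenated from the four most group-discriminative Plug-adjacent
   regions, checked for proximity to the Pep cluster (≤ 20 kb), and
   summarized per clade by Shannon entropy.

A deterministic synthetic-fixture generator (`pyomine.simulate`) builds
genomes, reference tables and ground truth emulating the study conditions,
so the whole pipeline installs and tests offline.

## Worked example

```sh
pyomine simulate --seed 1 --out fx/
pyomine run-all --input fx/ --out results/
```

prints `5 strains (3 producers); 4 FpvA receptors; 3 groups` and writes,
among other tables:

```
$ cat results/qc.tsv
strain  qc_status     producer
S01     producer      True
S02     producer      True
S03     producer      True
S04     truncated     False
S05     non_producer  False

$ head -5 results/predictions.tsv
strain  module  X1        X2        rule  call
S01     0       0.018358  1.547324  1     Glu
S01     1       0.018358  1.547324  1     Dab
S01     2       0.018358  1.547324  1     Dab
S01     3       0.000000  1.547324  1     Rsc
```

`X1` is the Jukes–Cantor feature distance from the module's Amotif4-5 to its
nearest reference substrate cluster (well below 0.7, so rule 1 fires and the
call is unambiguous); `X2` is the runner-up cluster (beyond 0.7, unrelated).
The predicted structure of S01 — `structures.json` — is
`Glu(L), Dab(D), Dab(D), Rsc(L), OHAsp(L)`: five Pep modules, two of them
epimerized to D-residues.  `receptor_groups.tsv` assigns the four annotated
FpvA receptors to three specificity groups, and `diversity.tsv` reports the
per-clade Shannon entropy of those groups (ln 3 ≈ 1.0986 for the clade
holding three distinct receptor groups).

S04 is dismissed because its only synthetase cluster sits 53 bp from a
contig edge and the Flu cluster is missing (a likely assembly truncation);
S05 has no pyoverdine cluster at all and is a non-producer.

## Layout

```
src/pyomine/
  seqcore.py    distances, alignment, clustering, conservation, regions
  phmm.py       profile HMMs: build from seed alignments, Viterbi bit scores
  nrps.py       synthetase location, Flu/Pep ordering, QC, motif parsing
  substrates.py reference sets, X1/X2 decision rules, structure assembly
  receptors.py  receptor gating, R1/R2 classification, grouping, diversity
  simulate.py   deterministic synthetic fixtures + ground truth
  pipeline.py   orchestration, dereplication, result writing
  config.py     every gate/threshold, YAML-serializable
  cli.py        `pyomine` subcommands (simulate, run-all, mine-*, ...)
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
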