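# Methods

## Identification model

A query protein is accepted as a MAPK when two conditions hold.

1. **Kinase-domain signature chain.** The library ships nine N-terminal
   anchor consensuses (N1–N9: `I-G-x-G-x-Y-G-x-V`, `I-K-K-I-x_3-F`,
   `D-A-x-R-x-L-R-E`, `F-x-D-I-Y-x_3-E-L-M`, `D-L-x_2-V-I`,
   `D-x-L-x_2-E-H`, `Q-x-L-R-x-L-K-Y-x-H`, `H-R-D-L-K-P-x-N`, and the
   catalytic-loop/D-F-G signature) and three C-terminal anchors (C1–C3:
   `T-R-W-Y-R-A-P-E-L`, `I-D-x-W-S-I/V-G-C`, `Q-x-L-L-x-F-D-P`).  Two
   spellings of the D-F-G signature circulate in the literature
   (`L-x-N-x-N-C-…` and `L-x-L-x-N-C-…`); both are shipped under slot N9
   and either satisfies the anchor.  Anchors are chained greedily left to
   right (leftmost match starting after the previous anchor's end); the
   annotation is *ordered-valid* when ≥ 6 of 9 N-terminal and ≥ 2 of 3
   C-terminal anchors chain.  The thresholds leave headroom so the decay
   of a single motif does not flip a call; they were chosen as part of the
   design, not fitted.

2. **Activation loop.** The loop is the region strictly between the end of
   the N9 match and the start of the C1 match.  The *last* contiguous
   `[T/M/S]-x-[Y/M/C]` triplet that spells one of the ten recognised
   variants (TEY, TDY, MEY, TEM, TQM, TRM, TVY, TSY, TEC, TQY) is taken.
   If no contiguous variant exists, a discontiguous fallback looks for the
   last `xY`-type pair that combines with the nearest compatible upstream
   T/M/S into a recognised variant — this is the insertion case observed
   in real sequences where the phospho-acceptor T and the E/D-Y pair are
   separated by an inserted stretch.  Failing both, the `T-x-Y`-like
   triplet closest to the C1 anchor is recorded with variant `other`.

Ordered-valid + recognised variant ⇒ **MAPK**; ordered-valid without a
recognised variant ⇒ **MAPK-like**; everything else ⇒ **rejected**.

'X' (unknown residue) matches no pattern element, wildcards included, and
is excluded from alignment coverage; low-quality stretches therefore never
create motif calls.

## Group assignment

Rule order: TDY → D; TSY/TEM/TQM/TRM → E; TQY → A; MEY/TEC/TVY → B;
TEY is disambiguated first by the group-tagged common-docking consensus
downstream of the loop (ties between equal-width CD hits leave the site
unassigned as ambiguous), then by the secondary N-terminal motifs, else
`unresolved`.  Where the group→variant tables and the running text of the
source literature disagree on T-E-M, the tabulated assignment (group E) is
used.  N-terminal TEY/TDY/SEY/SDY motifs are treated as *evidence* for
group D, not a requirement.  Tree placement — majority group among the
k = 3 nearest labelled reference leaves by patristic distance, ties
unresolved — overrides motif calls and is the only route to group F.
Window sizes are configurable constants: secondary N-terminal motifs are
sought within 30 residues after an N-terminal TxY hit, post-loop motifs
within 40 residues after the loop end.

## Sequence statistics

Molecular weight uses average residue masses plus one water (18.0153 Da).
The isoelectric point solves `Q(pH) = 0` by bisection on [0, 14] to
|Q| < 1e-4, with an EMBOSS-style pKa set (N-term 8.6, C-term 3.6, K 10.8,
R 12.5, H 6.5, D 3.9, E 4.1, C 8.5, Y 10.1) kept in a single constants
table; published per-protein pI values from unnamed web tools are not
expected to reproduce exactly, only their range.  Composition is reported
in percent over the 20 standard residues.  Intron counts are
`len(exons) − 1` per mRNA; the 7–14-intron band typical of group D genes
is flagged.

## Evolution statistics

* **p-distance.** Columns with non-gap, non-X coverage below the cutoff
  (default 0.95) are removed (*partial deletion*); residual gaps are
  skipped pairwise.  Cutoff 1.0 degenerates to complete deletion, 0 keeps
  all columns.  The overall mean distance carries a site-bootstrap
  standard error (default 2000 replicates, seeded).
* **Neighbor joining** stands on scikit-bio's implementation; negative
  branch lengths are clamped to zero.  NJ on a p-distance matrix is this
  package's deterministic desk-scale surrogate for a maximum-likelihood
  tree; group assignment tolerates the substitution because labelled
  references anchor the clades.
* **Relative-rate test** uses complete deletion, classifies each column
  (identical / unique to A / unique to B / unique to C / all different),
  and evaluates `X² = (mA − mB)²/(mA + mB)` with
  `p = erfc(√(X²/2))` (df = 1 closed form; `mA + mB = 0` gives X² = 0,
  p = 1).
* **Tajima's D** implements the 1989 coefficient chain explicitly; the
  result object carries all intermediate coefficients for diagnostics.
  From an alignment, S counts surviving columns with ≥ 2 states and π is
  the pairwise difference count rescaled to the surviving length; S = 0
  flags D as undefined rather than raising.  The number of sequences m is
  always caller-supplied in count mode, never inferred.
* **Duplication z-score.** The published pipeline behind the tabulated
  z-scores is closed, so the statistic is reinterpreted transparently:
  observed = best local-alignment score (BLOSUM62, affine gaps) against
  the rest of the proteome; null = the same maximum against
  composition-preserving shuffles of those partners (default 200
  replicates, seeded); verdict `duplicated` at z ≥ 4.  A zero-variance
  null is refused as degenerate.

## Nomenclature

Queries inherit the ortholog number of the reference with the highest
global-alignment score normalised by the query self-score (a deterministic
surrogate for BLASTP ranking); monocots are expected to be named against a
rice-style reference set and other species against an Arabidopsis-style
set, with the lineage declared by the caller, not inferred.  Queries of
one species sharing a number are ranked by similarity and suffixed
`-1, -2, …`; a lone query carries no suffix.  All ties break
lexicographically so re-runs are byte-stable.  Species prefixes are the
genus initial plus the shortest epithet prefix unique among taken
prefixes, with an override table for irregular published abbreviations
(e.g. Crein, Csub, Pper).

## Synthetic data

The generator assembles proteins from the real consensus architecture:
N-terminal block (with a TxY/SxY motif and a secondary motif for group D),
the nine N-terminal anchors in canonical order with random spacers, an
activation loop carrying the planted variant plus a group-appropriate
post-loop motif, the three C-terminal anchors, a group-specific CD site
(groups A–D), and a tail; lengths fall in 300–600 residues.  Activation-
loop spacers avoid Y/M/C so no recognised variant can arise downstream of
the planted one.  Default mixture weights follow the published family
structure: group weights 89/128/100/258/10/4 (A–F), intron-count
distribution matching the published census bins (intronless 7, single 41,
…, nine introns 126, up to fourteen), group-D genes restricted to 7–14
introns, ~10 % MAPK-like decoys, ~10 % random decoys, ~20 % paralogs
produced by duplicating a parent and drifting it ~2 %.  Point mutations
hit each position independently; with `protect_motifs` (default on, the
intended setting for low-rate conditions) planted anchor positions are
exempt, which models motif conservation under purifying selection.  With
protection off, anchors decay like background — the regime exercised by
the robustness tests.

Controlled alignments are exact by construction: the triplet generator
emits precisely the requested relative-rate site-class counts, and the
polymorphism generator plants derived alleles at exactly S columns with
allele counts chosen greedily to approach the target diversity, returning
the realised (S, π) recomputed from the construction.

What the generator does *not* emulate: indel evolution, codon structure,
compositional heterogeneity across sites, and correlated substitution
processes.  Passing tests therefore demonstrate correctness of the
algorithms under the stated generative model, not performance on real
proteomes.

## Problem sizes and numerical choices

Tests and the acceptance script run at desk scale: proteomes of 20–60
sequences, alignments up to ~10⁴ sites, 40–200 shuffle/bootstrap
replicates — sizes chosen so the whole suite runs in seconds while the
law-of-large-numbers checks still bind.  Bisection tolerance for pI is
1e-4 on net charge; Newick branch lengths round-trip at 6 decimals;
distance/bootstrap computations are float64 throughout.  All stochastic
stages consume a single seed.

## Known limitations

* The signature chain is a motif heuristic, not an HMM; diverged kinases
  with degraded anchors are called MAPK-like or rejected.
* The NJ surrogate does not reproduce maximum-likelihood topologies on
  hard datasets; it is exact only on additive distances.
* The duplication z-score is a declared reinterpretation; absolute z
  values are not comparable to the published table, only the z ≥ 4
  decision rule is shared.
* Group F is undetectable from motifs alone by construction.
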