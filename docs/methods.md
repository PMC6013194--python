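# Methods

This note documents the models behind each pipeline stage, the parameters
that matter, the synthetic data the package is validated on, and the design
choices taken where the design was genuinely open.

## Repeat detection and subfamily classification

The scanner is a per-column log-odds profile (PSSM) rather than a full
profile HMM: no insert/delete states, so a repeat is matched as a rigid
window. For the 50–53-residue MYB repeat, whose length is strongly conserved,
this is an acceptable fidelity trade-off; it would miss repeats with internal
indels.

- **Profile.** Columns with >50 % gaps in the seed alignment are dropped;
  scores are `log2(((c + α·b)/(n + α))/b)` with pseudocount α = 1 and a
  uniform background by default (both configurable).
- **Thresholds.** Score cutoffs are self-calibrating: mean + 5 SD of window
  scores on residue-shuffled copies of the input proteins (30 shuffles,
  seeded), computed separately for the full width and for the smallest (40 %)
  partial sub-profile. A fixed bit-score can be supplied instead.
- **Partial repeats.** Prefix and suffix sub-profiles covering 40–99 % of the
  width are scored at every position, not only at sequence termini. Truncated
  repeats do occur mid-sequence, and greedy score-descending overlap
  resolution already guarantees that a genuine complete repeat beats its own
  sub-windows, so unrestricted partial scanning does not inflate the Atypical
  class.
- **Completeness floor.** A hit covering ≥80 % of the profile counts as a
  complete repeat. Under point substitutions, the best-scoring placement on a
  real repeat sometimes sheds a mutated edge column (the sub-window scores
  higher than the full window); biologically that is still a whole repeat.
  Genuinely truncated (atypical) repeats cover 40–60 % and are unaffected.
- **Classification.** The longest run of complete hits with inter-hit gaps
  ≤30 residues gives the repeat count (1→MYB-related, 2→R2R3, 3→R1R2R3,
  4→4R; >4 clamps to 4R with a warning); partial-only proteins are Atypical;
  hit-free proteins are not MYBs.

## Alignment and trees

- **Pairwise/profile alignment** is Gotoh affine-gap dynamic programming
  over residue profiles; a gap of length k costs `gap_open + k·gap_extend`
  (defaults 10 and 0.5, BLOSUM62 — ClustalW-like). Traceback ties prefer
  match, then gap in the first profile, then gap in the second, making
  alignments deterministic.
- **Progressive alignment** uses a 3-mer-distance + UPGMA guide tree and
  merges profiles leaf-to-root; formed columns are never realigned.
  Profile–profile column scores are expected substitution scores with gaps
  contributing zero.
- **Distances** are p-distances with pairwise gap deletion (the common
  default for distance-based trees in this workflow); a Poisson correction
  is deliberately not applied. A pair with zero comparable sites is an error
  naming the pair.
- **Neighbour joining** follows Saitou–Nei with the standard Q criterion.
  Ties in Q are broken on the label-sorted pair (a cluster is labelled by
  its smallest leaf name). Negative branch lengths are clamped to zero with
  the deficit moved to the sibling branch, preserving the joined pair's
  summed length; on additive inputs the tree metric is reproduced exactly
  (tested to 1e-8).
- **Bootstrap** resamples alignment columns with replacement; an internal
  edge's support is the percentage of replicate trees containing its
  bipartition. Tests run 100–1000 replicates; the pipeline default is 0
  (supports off) because group assignment does not require them.

## Anchor-guided group assignment

The group boundaries of a published census are typically drawn by eye on a
circular tree. Here the rule is deterministic: each query takes the majority
anchor label of the smallest edge-bounded subtree containing it and at least
one anchor (ties → nearest patristic anchor, then lexicographic). A query
whose nearest anchor is farther than the 90th percentile (configurable) of
within-group anchor–anchor patristic distances is *species-specific*.
Classification is two-stage: all candidates against the 2R/3R anchors first;
stage-1 species-specific queries join the 1R/4R/atypical anchors in a second
tree, so stage-2 input = total − stage-1 labelled by construction.

## Motif discovery

The ZOOPS model: a sequence of length m contains a width-W motif occurrence
with prior λ at a uniformly chosen position, or none. EM maximises the
observed-data likelihood; the trace is non-decreasing by construction and
asserted in tests. Numerical choices:

- M-step pseudocount 0.01 × background per cell.
- Starts are seeded from observed windows: 30 sampled windows are ranked by
  one-E-step likelihood and the best 2–3 run to convergence.
- **Phase-shift refinement:** EM often converges a few columns out of
  register; after convergence, the model is re-seeded from occurrence
  windows shifted by ±1–3 columns and any shift that raises the likelihood
  is adopted (repeated up to 6 rounds).
- **Width selection:** among candidate widths, the winner maximises
  *penalized information* — total relative entropy minus one bit per column.
  Per-column relative entropy is width-neutral and lets a sub-window of a
  wide conserved motif tie with the full motif; the penalty also stops motifs
  from padding themselves with background columns.
- Found occurrences are masked with background-sampled residues before the
  next motif; occurrences therefore never overlap across motifs. Discovery
  stops at `max_motifs` or when the best motif drops under 0.3 bits/column.
- The practical width grid is 6–50 in steps of 2 (the full 2–250 range is
  accessible); EM at width 250 is degenerate on proteins of ordinary length.

## Homology

Local alignment scores come from exact Smith–Waterman (same gap convention
as above); edge weight = score / √(self_a · self_b) ∈ (0,1], with the edge
threshold at the 99th percentile of scores between residue-shuffled pairs.
RBH keeps a pair only when each member is the other's unique best
cross-species partner; ties are discarded. MCL adds self-loops equal to each
node's maximum incident weight and alternates expansion with inflation
(default 2.0, 1.5–4.0 sensible). Edge weights are raised to a cubic contrast
before clustering: self-score-normalised weights have a compressed dynamic
range (within-family ≈0.9 vs between ≈0.25 on synthetic data) compared with
the log-significance weights classic orthology clustering consumes, and
without the transform a domain-sharing family graph collapses into one
cluster. Ortholog pairs are RBH pairs whose ends share a cluster; paralog
pairs are within-species, within-cluster edges at least as heavy as the
cluster's mean cross-species weight (clusters without cross-species edges
keep all their within-species edges).

## Physicochemical profiling

Average (not monoisotopic) residue masses; water 18.01524 Da. pI is found by
bisection of the net-charge function (strictly decreasing in pH); the loop
converges on the interval (1e-7) rather than on |charge| < 1e-4 alone,
because near the root the charge curve can be flat enough to leave the pH
off by several hundredths while the charge criterion is already met. Two pKa
sets ship: EMBOSS-style (N-term 8.6, C-term 3.6, …) and the ExPASy-style
Bjellqvist values (default; residue-specific N-terminal corrections are not
modelled). GRAVY is the plain Kyte–Doolittle mean; the instability index
uses the Guruprasad DIWV dipeptide table. Non-standard residues raise an
error by default or are skipped with a warning when tolerated.

## Expression

ΔCt pairs target and reference within each replicate; ΔΔCt compares
condition means against the calibrator, which defaults to the first
developmental stage within each (gene, cultivar) — configurable.
Amplification efficiency is fixed at 2 (Livak assumption); efficiency
correction is out of scope. Fold SE uses the delta method on the replicate
SDs of ΔCt; a fold range [2^−(ΔΔCt+SE), 2^−(ΔΔCt−SE)] is reported alongside.
The replicate column is the aggregation unit, whether replicates are
technical or biological. Trend calls over ≥3 stages: *decreasing* if every
successive ratio ≤ 1 + tol and last/first < 1; *increasing* symmetrically;
otherwise *none* (tol default 0.05).

## Synthetic data: what it emulates, and what it does not

The generator plants exact or mutated copies of a 52-residue repeat
consensus (with the conserved tryptophan spacing) into uniform-random
background, organised into families sharing a mutated common ancestor so
that phylogenetic grouping and homology clustering have recoverable
structure. Defaults define the study population: 200 proteins split
96/44/51/2/1/6 across none/1R/2R/3R/4R/atypical (mirroring the roughly
half-2R, 40 %-1R, few-3R/4R/atypical composition of plant MYB censuses,
plus an equal mass of non-MYB background), substitution rate 0.05 per site,
background segments of 60–160 residues, inter-repeat gaps of 1–12 residues,
3 anchors per anchored family, and two unanchored 1R families providing
ground-truth species-specific queries. Gene models place one gene per
protein uniformly without overlap on 8 chromosomes; Ct tables are generated
by inverting the 2^−ΔΔCt model with Gaussian replicate noise (default SD 0.2
cycles, 3 replicates, stages 51/64/75/84/93 days after full bloom, two
cultivars).

What the generator does **not** emulate — so passing tests say nothing about
these aspects of real data: realistic residue composition or codon usage,
repeat-length variation and internal indels, domain architectures beyond
tandem repeats, intron phase, chromosome-end gene-density bias, isoform
complexity, cross-species divergence beyond point substitution, or qPCR
efficiency differences. A single integer seed drives one named RNG stream
per generator (proteome 0, gene models 1, qPCR 2, seed alignment 3,
pipeline 4, scan null 5); adding a stream never perturbs existing ones, and
regeneration at the same seed is byte-identical.

## Problem sizes and runtime

The shipped configurations are desk-scale by design: the census and
classification checks use the 200-protein population above; the end-to-end
pipeline run (and its committed golden manifest, seed 42) uses a 60-protein
population, motif width grid {11, 21, 31, 41}, 5 motifs, bootstrap off. The
full test suite runs in well under a minute on one CPU; the acceptance
script in about half a minute.

## Known limitations

- The rigid-window PSSM cannot represent insertions within a repeat.
- Progressive alignment never revisits columns; deep or gappy families
  would benefit from iterative refinement.
- Group labels transfer only as well as the anchors represent the family;
  sparse anchor sets inflate the species-specific class.
- MCL granularity depends on the weight contrast and inflation; counts of
  ortholog/paralog pairs are parameter-sensitive, as they are in any
  clustering-based orthology pipeline.
- The two-stage classifier assigns exactly one group per query; chimeric
  proteins are not modelled.
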