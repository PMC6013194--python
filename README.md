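# famcensus

A genome-wide census toolkit for the plant MYB transcription-factor
superfamily — for researchers who want to identify every MYB gene in an
annotated genome, classify the proteins by repeat architecture and phylogeny,
and characterise their motifs, gene structures, homology relationships,
physicochemical properties and expression, all with a synthetic ground-truth
generator so every stage is testable without downloading a genome.

## The science

MYB proteins carry a DNA-binding domain of 1–4 adjacent **imperfect tandem
repeats** (R1–R4), each 50–53 residues folding into three α-helices whose last
two form a helix-turn-helix. The repeat count defines the subfamilies:
MYB-related (1R), R2R3 (2R), R1R2R3 (3R) and 4R, plus an *Atypical* class
whose members retain only part of a repeat. The pipeline mirrors the standard
census workflow:

1. **Repeat scan** (`repeat_scan`). A position-specific scoring matrix is
   built from a seed alignment of the repeat:
   `S(j,a) = log2(((c_ja + α·b_a)/(n_j + α)) / b_a)` with pseudocount α and
   background frequencies *b*. Proteins are scanned with the full-width
   profile and with prefix/suffix sub-profiles (≥40 % of the width) so that
   truncated repeats are found; overlaps are resolved greedily by score, and
   the longest run of adjacent complete repeats assigns the subfamily.
2. **Phylogenetic grouping** (`msa_phylo`). Progressive multiple alignment
   (3-mer distance + UPGMA guide tree, affine-gap profile alignment,
   BLOSUM62, gap open 10 / extend 0.5), p-distances with pairwise gap
   deletion, and Saitou–Nei neighbour joining minimising
   `Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, with column-resampling bootstrap.
   Queries inherit the majority label of the smallest edge-bounded subtree
   that also contains a labelled anchor protein; queries farther from every
   anchor than the 90th percentile of within-group anchor–anchor patristic
   distances are called species-specific. Classification runs in two stages:
   first against 2R/3R anchors, then the remainder against 1R/4R/atypical
   anchors.
3. **Motif discovery** (`motif_discovery`). MEME-style ZOOPS expectation-
   maximisation (zero or one motif occurrence per sequence, occurrence prior
   λ), with phase-shift refinement, width selection by penalized information
   content, occurrence masking between motifs, and information-content logos
   (`IC_j = log2 20 − H(θ_j)`).
4. **Gene structure** (`gene_structure`). GFF3 parsing (representative mRNA =
   longest CDS), exon/intron derivation, chromosome distribution and a
   terminal-density statistic.
5. **Homology** (`homology`). Smith–Waterman all-vs-all scores normalised by
   self-score geometric means, reciprocal best hits, Markov clustering
   (expansion/inflation), ortholog pairs = RBH pairs sharing a cluster,
   paralog pairs = strong within-species edges inside a cluster.
6. **Physicochemical profiling** (`protparam`). Average-mass molecular
   weight, theoretical pI by bisection on the Henderson–Hasselbalch net
   charge (EMBOSS or ExPASy pKa sets), Kyte–Doolittle GRAVY, and the
   Guruprasad instability index `II = (10/L)·Σ DIWV(x_i, x_{i+1})`
   (unstable if II > 40).
7. **Expression** (`expression`). Livak 2^−ΔΔCt relative quantification with
   replicate pairing, delta-method fold standard errors, and monotone-trend
   calls over developmental stages (days after full bloom).

The `synthetic_data` module generates proteomes with planted repeat
architectures, anchor sets, GFF3 gene models and Ct tables produced by
running the 2^−ΔΔCt model in reverse — every downstream result can be scored
against known truth.

## Worked example

```python
from famcensus import FamilySpec, generate_proteome, build_profile, census
from famcensus.synthetic_data import generate_seed_alignment
from famcensus.repeat_scan import ScanParams

spec = FamilySpec(seed=1)                       # 200 proteins, substitution rate 0.05
bundle = generate_proteome(spec)
profile = build_profile([s for _, s in generate_seed_alignment(seed=1)])
cens, archs = census(bundle.proteins, profile, ScanParams(seed=1))
print(cens.counts)
print("MYB members detected:", cens.total)
a = archs["syn0100"]
print(a.subfamily, [(h.start + 1, h.end, round(h.score, 1)) for h in a.hits])
```

prints

```
{'MYB_RELATED': 44, 'R2R3': 51, 'R1R2R3': 2, 'FOUR_R': 1, 'ATYPICAL': 7, 'NOT_MYB': 95}
MYB members detected: 105
MYB_RELATED [(48, 99, 202.1)]
```

Of 200 synthetic proteins, 105 carry MYB repeats: 44 single-repeat
(MYB-related), 51 two-repeat (R2R3), 2 three-repeat, 1 four-repeat and 7 with
only a partial repeat (Atypical); the rest have none. Protein `syn0100`
carries one complete repeat at residues 48–99 (1-based, closed) scoring 202
bits against the profile — hence the 1R call. Against the generator's ground
truth this census is 99.5 % accurate.

The same flow is available from the shell:

```bash
famcensus all --seed 42 --out out/      # synth -> scan -> trees -> ... -> manifest
famcensus scan --out out/               # re-run a single stage on prior outputs
```

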