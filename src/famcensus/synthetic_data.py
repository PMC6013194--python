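"""Synthetic proteome / gene-model / anchor / qPCR generators with ground truth.

The generators emulate the statistical structure a genome-wide MYB-superfamily
census assumes: proteins carrying 1-4 adjacent imperfect tandem copies of a
~52-residue DNA-binding repeat embedded in unrelated background, atypical
members carrying only a partial repeat, gene models laid out on a small set of
chromosomes, and a Ct table produced by running the 2^-ddCt model in reverse so
that downstream quantification can be checked against planted fold changes.

Every generator draws from one named RNG stream derived from a single integer
seed (see ``stream``); adding a new generator therefore never perturbs the
output of existing ones.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "AMINO_ACIDS",
    "MYB_REPEAT_CONSENSUS",
    "FamilySpec",
    "GroundTruth",
    "ProteinTruth",
    "GeneTruth",
    "SyntheticBundle",
    "GenerationError",
    "stream",
    "generate_repeat",
    "generate_proteome",
    "generate_seed_alignment",
    "generate_gene_models",
    "generate_qpcr_table",
    "generate_bundle",
    "write_fasta",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# A realistic 52-residue R2-like MYB repeat consensus: note the spaced
# tryptophan triplet characteristic of the DNA-binding helix-turn-helix.
MYB_REPEAT_CONSENSUS = "LNRGAWTAEEDRLLRQYIQKHGEGNWRNLPKRAGLKRCGKSCRLRWTNYLRP"

# First codon per amino acid in the standard table; synthetic CDSs only need
# length/frame consistency, not realistic codon usage.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "TTA",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_STOP = "TAA"

# Documented stream order: a single integer seed fans out into one independent
# RNG per generator.  Never renumber; append only.
_STREAMS = {
    "proteome": 0,
    "gene_models": 1,
    "qpcr": 2,
    "seed_alignment": 3,
    "pipeline": 4,
    "scan_null": 5,
}

CLASSES = ("NONE", "1R", "2R3R", "3R", "4R", "ATYPICAL")
_N_REPEATS = {"1R": 1, "2R3R": 2, "3R": 3, "4R": 4}

SPECIES_SPECIFIC = "species-specific"


class GenerationError(ValueError):
    """Raised when a request cannot be realised (impossible geometry etc.)."""


def stream(seed: int, name: str) -> np.random.Generator:
    """Return the named RNG stream for *seed* (independent across names)."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[name],))
    )


# ---------------------------------------------------------------------------
# Specification & ground truth containers
# ---------------------------------------------------------------------------

def _default_counts() -> Dict[str, int]:
    # Mirrors the subfamily proportions of a typical plant MYB census
    # (roughly half 2R, ~40% 1R, a handful of 3R/4R/atypical members) plus an
    # equal mass of non-MYB background proteins; totals 200.
    return {"NONE": 96, "1R": 44, "2R3R": 51, "3R": 2, "4R": 1, "ATYPICAL": 6}


def _default_groups() -> Dict[str, int]:
    return {"2R3R": 8, "1R": 6, "3R": 1, "4R": 1, "ATYPICAL": 2}


def _default_group_labels() -> Dict[str, List[str]]:
    return {
        "2R3R": [f"C{i}" for i in range(1, 36)],
        "1R": ["CCA1-like", "CPC-like", "TBP-like", "I-box-binding-like",
               "R-R-type"],
        "3R": ["3R-MYB"],
        "4R": ["4R-MYB"],
        "ATYPICAL": ["Atypical-A", "Atypical-B", "Atypical-C"],
    }


@dataclass
class FamilySpec:
    """Parameters of a synthetic MYB-census study population."""

    counts_per_class: Dict[str, int] = field(default_factory=_default_counts)
    repeat_consensus: str = MYB_REPEAT_CONSENSUS
    substitution_rate: float = 0.05
    background_length: Tuple[int, int] = (60, 160)
    inter_repeat_gap: Tuple[int, int] = (1, 12)
    n_chromosomes: int = 8
    chromosome_length: int = 2_000_000
    seed: int = 0
    # Group structure used for anchor-guided classification: members of a
    # class are partitioned into families sharing a common ancestor sequence.
    groups_per_class: Dict[str, int] = field(default_factory=_default_groups)
    anchors_per_group: int = 3
    # Per class, number of groups left without anchors; their members are the
    # ground-truth "species-specific" queries.
    unanchored_groups: Dict[str, int] = field(default_factory=lambda: {"1R": 2})

    def __post_init__(self) -> None:
        if not (50 <= len(self.repeat_consensus) <= 53):
            raise ValueError("repeat_consensus must be 50-53 residues long")
        if any(v < 0 for v in self.counts_per_class.values()):
            raise ValueError("counts_per_class must be non-negative")
        if sum(self.counts_per_class.values()) <= 0:
            raise ValueError("counts_per_class must sum to a positive total")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must lie in [0, 1]")
        unknown = set(self.counts_per_class) - set(CLASSES)
        if unknown:
            raise ValueError(f"unknown architecture classes: {sorted(unknown)}")
        lo, hi = self.background_length
        if not (2 <= lo <= hi):
            raise GenerationError("background_length range is infeasible")
        glo, ghi = self.inter_repeat_gap
        if not (0 <= glo <= ghi):
            raise GenerationError("inter_repeat_gap range is infeasible")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ValueError("need >=1 chromosome of positive length")


@dataclass
class ProteinTruth:
    id: str
    architecture: str                       # one of CLASSES
    repeats: List[Tuple[int, int]]          # 0-based half-open, ordered
    group: Optional[str]                    # phylogenetic group label
    family: int                             # shared-ancestor family index
    anchored: bool                          # family has labelled anchors


@dataclass
class GeneTruth:
    id: str
    chromosome: str
    strand: str
    exons: List[Tuple[int, int]]            # 1-based closed genomic intervals


@dataclass
class GroundTruth:
    proteins: Dict[str, ProteinTruth] = field(default_factory=dict)
    genes: Dict[str, GeneTruth] = field(default_factory=dict)
    folds: Dict[Tuple[str, str, int], float] = field(default_factory=dict)

    def class_counts(self) -> Dict[str, int]:
        out: Dict[str, int] = {}
        for t in self.proteins.values():
            out[t.architecture] = out.get(t.architecture, 0) + 1
        return out

    def to_json(self) -> str:
        doc = {
            "proteins": {
                k: dataclasses.asdict(v) for k, v in sorted(self.proteins.items())
            },
            "genes": {
                k: dataclasses.asdict(v) for k, v in sorted(self.genes.items())
            },
            "folds": [
                {"gene": g, "cultivar": c, "stage": s, "fold": f}
                for (g, c, s), f in sorted(self.folds.items())
            ],
        }
        return json.dumps(doc, indent=1, sort_keys=True)


@dataclass
class SyntheticBundle:
    """In-memory result of proteome generation (plus anchors)."""

    proteins: Dict[str, str]
    cds: Dict[str, str]
    truth: GroundTruth
    anchors: Dict[str, str]                 # anchor id -> sequence
    anchor_labels: Dict[str, Tuple[str, str]]  # anchor id -> (subfamily, group)


# ---------------------------------------------------------------------------
# Sequence-level generators
# ---------------------------------------------------------------------------

def _random_peptide(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[rng.integers(0, 20, size=n)])


def generate_repeat(consensus: str, substitution_rate: float,
                    rng: np.random.Generator) -> str:
    """Mutate *consensus* position-wise: each residue is replaced with
    probability ``substitution_rate`` by a uniform draw from the 19 others."""
    if not consensus:
        raise ValueError("consensus must be non-empty")
    if not 0.0 <= substitution_rate <= 1.0:
        raise ValueError("substitution_rate must lie in [0, 1]")
    out = list(consensus)
    hit = rng.random(len(out)) < substitution_rate
    for i in np.nonzero(hit)[0]:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[rng.integers(0, len(choices))]
    return "".join(out)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Whole-protein point substitution at the given per-site rate."""
    if rate <= 0.0:
        return seq
    return generate_repeat(seq, rate, rng)


def back_translate(protein: str) -> str:
    """Fixed-codon back-translation plus one stop codon (length = 3L + 3)."""
    try:
        return "".join(_CODON[a] for a in protein) + _STOP
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"cannot back-translate residue {exc}") from exc


def _build_ancestor(cls: str, spec: FamilySpec, rng: np.random.Generator
                    ) -> Tuple[str, List[Tuple[int, int]]]:
    """One family-ancestor protein for class *cls* with repeat coordinates."""
    w = len(spec.repeat_consensus)
    lo, hi = spec.background_length
    lead = int(rng.integers(lo // 2, hi // 2 + 1))
    trail = int(rng.integers(lo // 2, hi // 2 + 1))
    parts: List[str] = [_random_peptide(lead, rng)]
    coords: List[Tuple[int, int]] = []
    pos = lead
    if cls == "ATYPICAL":
        frac = rng.uniform(0.4, 0.6)
        partial = spec.repeat_consensus[: max(1, round(frac * w))]
        parts.append(partial)
        coords.append((pos, pos + len(partial)))
        pos += len(partial)
    elif cls != "NONE":
        n_rep = _N_REPEATS[cls]
        glo, ghi = spec.inter_repeat_gap
        for k in range(n_rep):
            if k > 0:
                gap = int(rng.integers(glo, ghi + 1))
                parts.append(_random_peptide(gap, rng))
                pos += gap
            parts.append(spec.repeat_consensus)
            coords.append((pos, pos + w))
            pos += w
    parts.append(_random_peptide(trail, rng))
    return "".join(parts), coords


def generate_proteome(spec: FamilySpec) -> SyntheticBundle:
    """Generate the synthetic proteome, its CDS set, anchors and ground truth.

    Members of each architecture class are partitioned into families sharing a
    common ancestor (planted repeats in random background); every member and
    anchor is an independently mutated copy of its family ancestor, so family
    membership is recoverable by phylogenetic clustering while the planted
    repeat coordinates remain exact.
    """
    rng = stream(spec.seed, "proteome")
    proteins: Dict[str, str] = {}
    cds: Dict[str, str] = {}
    truth = GroundTruth()
    anchors: Dict[str, str] = {}
    anchor_labels: Dict[str, Tuple[str, str]] = {}

    labels_pool = _default_group_labels()
    subfamily_name = {
        "1R": "MYB_RELATED", "2R3R": "R2R3", "3R": "R1R2R3",
        "4R": "FOUR_R", "ATYPICAL": "ATYPICAL",
    }

    idx = 0
    family_idx = 0
    for cls in CLASSES:
        count = spec.counts_per_class.get(cls, 0)
        if count == 0:
            continue
        if cls == "NONE":
            n_groups = count  # background proteins are unrelated singletons
        else:
            n_groups = min(spec.groups_per_class.get(cls, 1), count)
        n_unanchored = spec.unanchored_groups.get(cls, 0) if cls != "NONE" else n_groups
        sizes = [count // n_groups + (1 if g < count % n_groups else 0)
                 for g in range(n_groups)]
        for g, size in enumerate(sizes):
            ancestor, coords = _build_ancestor(cls, spec, rng)
            anchored = cls != "NONE" and g >= n_unanchored
            if cls == "NONE":
                group = None
            elif anchored:
                pool = labels_pool[cls]
                group = pool[(g - n_unanchored) % len(pool)]
            else:
                group = SPECIES_SPECIFIC
            for _ in range(size):
                pid = f"syn{idx:04d}"
                idx += 1
                seq = _mutate(ancestor, spec.substitution_rate, rng)
                proteins[pid] = seq
                cds[pid] = back_translate(seq)
                truth.proteins[pid] = ProteinTruth(
                    id=pid, architecture=cls, repeats=list(coords),
                    group=group, family=family_idx, anchored=anchored,
                )
            if anchored:
                for a in range(spec.anchors_per_group):
                    aid = f"anc{family_idx:03d}_{a}"
                    anchors[aid] = _mutate(ancestor, spec.substitution_rate, rng)
                    anchor_labels[aid] = (subfamily_name[cls], group)
            family_idx += 1

    return SyntheticBundle(proteins=proteins, cds=cds, truth=truth,
                           anchors=anchors, anchor_labels=anchor_labels)


def generate_seed_alignment(consensus: str = MYB_REPEAT_CONSENSUS,
                            n_seqs: int = 24, substitution_rate: float = 0.08,
                            seed: int = 0) -> List[Tuple[str, str]]:
    """Ungapped alignment of mutated consensus copies; profile-building input."""
    rng = stream(seed, "seed_alignment")
    return [(f"seed{i:02d}", generate_repeat(consensus, substitution_rate, rng))
            for i in range(n_seqs)]


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def generate_gene_models(spec: FamilySpec, truth: GroundTruth,
                         cds_lengths: Mapping[str, int],
                         exons_per_gene: Mapping[str, int],
                         intron_length: Tuple[int, int] = (60, 400)) -> str:
    """Place one gene per protein uniformly without overlap and emit GFF3.

    ``exons_per_gene`` maps gene id -> exon count (>= 1); exon spans sum to the
    CDS length.  Returns the GFF3 text (version 3, 1-based closed intervals)
    and records placements in ``truth.genes``.
    """
    for gid, e in exons_per_gene.items():
        if e < 1:
            raise ValueError(f"exons_per_gene must be >= 1 (gene {gid})")
    rng = stream(spec.seed, "gene_models")
    gene_ids = sorted(cds_lengths)
    chrom_of = {g: f"chr{int(rng.integers(1, spec.n_chromosomes + 1))}"
                for g in gene_ids}

    # exon/intron geometry per gene
    geometry: Dict[str, Tuple[List[int], List[int]]] = {}
    span: Dict[str, int] = {}
    for g in gene_ids:
        L = cds_lengths[g]
        n_ex = exons_per_gene.get(g, 1)
        if n_ex > L:
            raise GenerationError(f"gene {g}: more exons than CDS bases")
        cuts = sorted(rng.choice(np.arange(1, L), size=n_ex - 1, replace=False)) \
            if n_ex > 1 else []
        bounds = [0, *map(int, cuts), L]
        ex_lens = [bounds[i + 1] - bounds[i] for i in range(n_ex)]
        in_lens = [int(rng.integers(intron_length[0], intron_length[1] + 1))
                   for _ in range(n_ex - 1)]
        geometry[g] = (ex_lens, in_lens)
        span[g] = sum(ex_lens) + sum(in_lens)

    lines = ["##gff-version 3"]
    for c in range(1, spec.n_chromosomes + 1):
        lines.append(f"##sequence-region chr{c} 1 {spec.chromosome_length}")

    for c in range(1, spec.n_chromosomes + 1):
        chrom = f"chr{c}"
        members = [g for g in gene_ids if chrom_of[g] == chrom]
        total = sum(span[g] for g in members)
        free = spec.chromosome_length - total - len(members)
        if free < 0:
            raise GenerationError(f"chromosome capacity exceeded on {chrom}")
        # uniform non-overlapping placement: distribute free space as gaps
        gaps = np.diff(np.concatenate(
            ([0], np.sort(rng.integers(0, free + 1, size=len(members))))))
        pos = 1
        for g, gap in zip(members, gaps):
            start = pos + int(gap)
            ex_lens, in_lens = geometry[g]
            strand = "+" if rng.random() < 0.5 else "-"
            exons: List[Tuple[int, int]] = []
            p = start
            for i, el in enumerate(ex_lens):
                exons.append((p, p + el - 1))
                p += el
                if i < len(in_lens):
                    p += in_lens[i]
            end = exons[-1][1]
            pos = end + 1
            truth.genes[g] = GeneTruth(id=g, chromosome=chrom, strand=strand,
                                       exons=exons)
            lines.append("\t".join([chrom, "famcensus", "gene", str(start),
                                    str(end), ".", strand, ".", f"ID=gene:{g}"]))
            mid = f"mRNA:{g}.1"
            lines.append("\t".join([chrom, "famcensus", "mRNA", str(start),
                                    str(end), ".", strand, ".",
                                    f"ID={mid};Parent=gene:{g}"]))
            for k, (s, e) in enumerate(exons, 1):
                lines.append("\t".join([chrom, "famcensus", "exon", str(s),
                                        str(e), ".", strand, ".",
                                        f"ID={mid}.exon{k};Parent={mid}"]))
                lines.append("\t".join([chrom, "famcensus", "CDS", str(s),
                                        str(e), ".", strand, "0",
                                        f"ID={mid}.cds{k};Parent={mid}"]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

DEFAULT_STAGES = (51, 64, 75, 84, 93)   # days after full bloom
DEFAULT_CULTIVARS = ("ZX", "YJH")       # white- and red-fleshed cultivars


def generate_fold_patterns(genes: Sequence[str],
                           cultivars: Sequence[str] = DEFAULT_CULTIVARS,
                           stages: Sequence[int] = DEFAULT_STAGES,
                           seed: int = 0) -> Dict[Tuple[str, str, int], float]:
    """Planted fold-change map: per (gene, cultivar) a decreasing, increasing
    or patternless trajectory over stages, calibrated to 1 at the first stage."""
    rng = stream(seed, "qpcr")
    folds: Dict[Tuple[str, str, int], float] = {}
    for g in genes:
        for c in cultivars:
            kind = rng.choice(["decreasing", "increasing", "none"])
            f = 1.0
            for i, s in enumerate(stages):
                if i == 0:
                    f = 1.0
                elif kind == "decreasing":
                    f *= rng.uniform(0.35, 0.8)
                elif kind == "increasing":
                    f *= rng.uniform(1.25, 2.8)
                else:
                    f *= rng.uniform(0.5, 2.0)
                folds[(g, c, int(s))] = f
    return folds


def generate_qpcr_table(genes: Sequence[str],
                        stages: Sequence[int],
                        fold_changes: Mapping[Tuple[str, str, int], float],
                        reference_gene: str = "RPII",
                        ct_noise_sd: float = 0.0,
                        seed: int = 0,
                        cultivars: Sequence[str] = DEFAULT_CULTIVARS,
                        n_replicates: int = 3,
                        reference_ct: float = 20.0,
                        delta_ct_calibrator: float = 5.0) -> pd.DataFrame:
    """Run the 2^-ddCt model in reverse to produce a replicate-level Ct table.

    Ct_target = Ct_ref + dCt_calibrator - log2(fold) + Normal(0, ct_noise_sd)
    per replicate; the first stage is the calibrator and has fold 1 by
    construction.  Columns: gene, cultivar, stage_DAFB, replicate, Ct.
    """
    for key, f in fold_changes.items():
        if f <= 0:
            raise ValueError(f"fold change must be positive ({key} -> {f})")
    rng = stream(seed, "qpcr")
    rows = []
    stages = [int(s) for s in stages]
    cal = stages[0]
    for c in cultivars:
        for s in stages:
            for r in range(1, n_replicates + 1):
                rows.append((reference_gene, c, s, r, reference_ct))
                for g in genes:
                    fold = 1.0 if s == cal else float(fold_changes[(g, c, s)])
                    ct = (reference_ct + delta_ct_calibrator - np.log2(fold)
                          + (rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0))
                    rows.append((g, c, s, r, float(ct)))
    return pd.DataFrame(rows, columns=["gene", "cultivar", "stage_DAFB",
                                       "replicate", "Ct"])


# ---------------------------------------------------------------------------
# Bundle + I/O helpers
# ---------------------------------------------------------------------------

def write_fasta(records: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in records:
            fh.write(f">{name}\n")
            seq = records[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i: i + 60] + "\n")


def _default_exon_counts(truth: GroundTruth) -> Dict[str, int]:
    # Typical plant-MYB gene structures: most 2R genes carry 3 exons, 3R genes
    # many more, 1R genes 2, atypical/related singletons 1-2.
    per_class = {"NONE": 2, "1R": 2, "2R3R": 3, "3R": 6, "4R": 3, "ATYPICAL": 1}
    return {pid: per_class[t.architecture] for pid, t in truth.proteins.items()}


def generate_bundle(spec: FamilySpec, n_expression_genes: int = 12,
                    ct_noise_sd: float = 0.2) -> Dict[str, object]:
    """Generate the full synthetic input bundle for a pipeline run."""
    bundle = generate_proteome(spec)
    exon_counts = _default_exon_counts(bundle.truth)
    cds_lengths = {g: len(s) for g, s in bundle.cds.items()}
    gff3 = generate_gene_models(spec, bundle.truth, cds_lengths, exon_counts)
    seed_aln = generate_seed_alignment(spec.repeat_consensus, seed=spec.seed)
    expr_genes = sorted(bundle.truth.proteins)[:n_expression_genes]
    folds = generate_fold_patterns(expr_genes, seed=spec.seed)
    bundle.truth.folds.update(folds)
    ct = generate_qpcr_table(expr_genes, DEFAULT_STAGES, folds,
                             ct_noise_sd=ct_noise_sd, seed=spec.seed)
    return {
        "bundle": bundle,
        "gff3": gff3,
        "seed_alignment": seed_aln,
        "ct_table": ct,
    }
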