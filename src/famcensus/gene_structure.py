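"""GFF3 gene-model parsing, exon/intron structure derivation and chromosome
distribution summaries.

GFF3 coordinates (1-based closed) are preserved at I/O; conversion to internal
conventions is centralised here.  Each gene is represented by one mRNA - the
one with the longest summed CDS, ties broken by lexicographic mRNA id.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import gffutils

__all__ = [
    "GeneModel",
    "StructureRecord",
    "ChromosomeMap",
    "FormatError",
    "DataError",
    "parse_gff3",
    "exon_intron_structure",
    "chromosome_distribution",
]


class FormatError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass
class GeneModel:
    gene_id: str
    chromosome: str
    strand: str
    mrna_id: str
    exons: List[Tuple[int, int]]          # 1-based closed, genomic order
    cds: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class StructureRecord:
    gene_id: str
    n_exons: int
    n_introns: int
    exon_lengths: List[int]
    intron_lengths: List[int]
    introns: List[Tuple[int, int]]        # 1-based closed


@dataclass
class ChromosomeMap:
    chromosome_lengths: Dict[str, int]
    counts: Dict[str, int]
    midpoints: Dict[str, List[Tuple[str, float]]]   # chrom -> (gene, midpoint)
    terminal_fraction: float
    terminal_density: float


def _strip_prefix(fid: str) -> str:
    return fid.split(":", 1)[1] if ":" in fid else fid


def parse_gff3(path: str) -> Tuple[List[GeneModel], Dict[str, int]]:
    """Parse a GFF3 file into representative gene models.

    Returns (models, chromosome_lengths).  Chromosome lengths come from
    ``##sequence-region`` directives when present.  An exon/CDS naming an
    unknown Parent, or any feature with end < start, is a format error.
    """
    db = gffutils.create_db(path, dbfn=":memory:", force=True,
                            merge_strategy="create_unique",
                            keep_order=True)
    chrom_lengths: Dict[str, int] = {}
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            if len(parts) >= 4:
                chrom_lengths[parts[1]] = int(parts[3])

    known_ids = {f.id for f in db.all_features()}
    models: List[GeneModel] = []
    problems: List[str] = []
    for feat in db.all_features():
        if feat.end < feat.start:
            raise FormatError(f"feature {feat.id}: end < start")
        if feat.featuretype in ("exon", "CDS", "mRNA"):
            for parent in feat.attributes.get("Parent", []):
                if parent not in known_ids:
                    raise FormatError(
                        f"{feat.featuretype} {feat.id}: unknown Parent {parent}")

    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            problems.append(f"gene {gene.id} has no mRNA")
            continue

        def cds_span(m) -> int:
            return sum(c.end - c.start + 1
                       for c in db.children(m, featuretype="CDS"))

        rep = sorted(mrnas, key=lambda m: (-cds_span(m), m.id))[0]
        exons = sorted((e.start, e.end)
                       for e in db.children(rep, featuretype="exon"))
        cds = sorted((c.start, c.end)
                     for c in db.children(rep, featuretype="CDS"))
        if not exons:
            problems.append(f"mRNA {rep.id} has no exons")
            continue
        models.append(GeneModel(
            gene_id=_strip_prefix(gene.id), chromosome=gene.seqid,
            strand=gene.strand, mrna_id=_strip_prefix(rep.id),
            exons=exons, cds=cds))
    if problems:
        warnings.warn("malformed gene models skipped: " + "; ".join(problems))
    return models, chrom_lengths


def exon_intron_structure(model: GeneModel) -> StructureRecord:
    """Introns are the gaps between consecutive sorted exons."""
    if not model.exons:
        raise DataError(f"gene {model.gene_id} has no exons")
    exons = sorted(model.exons)
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1:
            raise DataError(f"gene {model.gene_id}: overlapping exons "
                            f"({s1},{e1}) and ({s2},{e2})")
    introns = [(e1 + 1, s2 - 1) for (_, e1), (s2, _) in zip(exons, exons[1:])]
    return StructureRecord(
        gene_id=model.gene_id,
        n_exons=len(exons),
        n_introns=len(introns),
        exon_lengths=[e - s + 1 for s, e in exons],
        intron_lengths=[e - s + 1 for s, e in introns],
        introns=introns,
    )


def chromosome_distribution(models: Sequence[GeneModel],
                            chromosome_lengths: Mapping[str, int],
                            terminal_fraction: float = 0.25) -> ChromosomeMap:
    """Per-chromosome gene counts and the terminal-density statistic: the
    fraction of genes whose midpoint lies within ``terminal_fraction`` of
    either chromosome end."""
    counts: Dict[str, int] = {c: 0 for c in chromosome_lengths}
    midpoints: Dict[str, List[Tuple[str, float]]] = {c: [] for c in chromosome_lengths}
    n_terminal = 0
    for m in models:
        if m.chromosome not in chromosome_lengths:
            raise DataError(f"unknown chromosome {m.chromosome!r} "
                            f"(gene {m.gene_id})")
        length = chromosome_lengths[m.chromosome]
        mid = 0.5 * (min(s for s, _ in m.exons) + max(e for _, e in m.exons))
        rel = mid / length
        counts[m.chromosome] += 1
        midpoints[m.chromosome].append((m.gene_id, mid))
        if rel <= terminal_fraction or rel >= 1.0 - terminal_fraction:
            n_terminal += 1
    density = n_terminal / len(models) if models else 0.0
    return ChromosomeMap(chromosome_lengths=dict(chromosome_lengths),
                         counts=counts, midpoints=midpoints,
                         terminal_fraction=terminal_fraction,
                         terminal_density=density)


def structure_table(records: Sequence[StructureRecord]) -> str:
    lines = ["# coordinates are 1-based closed",
             "gene\tn_exons\tn_introns\texon_lengths\tintron_lengths"]
    for r in sorted(records, key=lambda r: r.gene_id):
        lines.append(f"{r.gene_id}\t{r.n_exons}\t{r.n_introns}\t"
                     f"{','.join(map(str, r.exon_lengths))}\t"
                     f"{','.join(map(str, r.intron_lengths))}")
    return "\n".join(lines) + "\n"


def distribution_table(cmap: ChromosomeMap) -> str:
    lines = [f"# terminal_fraction={cmap.terminal_fraction:g} "
             f"terminal_density={cmap.terminal_density:.4f}",
             "chromosome\tlength\tn_genes"]
    for c in sorted(cmap.counts):
        lines.append(f"{c}\t{cmap.chromosome_lengths[c]}\t{cmap.counts[c]}")
    return "\n".join(lines) + "\n"


def chromosome_svg(cmap: ChromosomeMap) -> str:
    """Minimal linear chromosome ideogram: one bar per chromosome with a tick
    at each gene midpoint (stands in for a circular rendering)."""
    chroms = sorted(cmap.chromosome_lengths)
    width, row_h, pad = 800.0, 30, 40
    maxlen = max(cmap.chromosome_lengths.values())
    parts = [f'<svg xmlns="http://www.w3.org/2000/svg" width="{int(width + 2 * pad)}" '
             f'height="{len(chroms) * row_h + 2 * pad}">']
    for i, c in enumerate(chroms):
        y = pad + i * row_h
        w = width * cmap.chromosome_lengths[c] / maxlen
        parts.append(f'<text x="5" y="{y + 14}" font-size="12">{c}</text>')
        parts.append(f'<rect x="{pad}" y="{y + 5}" width="{w:.1f}" height="12" '
                     f'fill="#ddd" stroke="#555"/>')
        for _, mid in cmap.midpoints.get(c, []):
            x = pad + width * mid / maxlen
            parts.append(f'<line x1="{x:.1f}" y1="{y + 3}" x2="{x:.1f}" '
                         f'y2="{y + 19}" stroke="#c22" stroke-width="1"/>')
    parts.append("</svg>")
    return "\n".join(parts) + "\n"
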