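"""End-to-end census pipeline: synthetic inputs (or user-supplied files) ->
repeat scan -> two-stage phylogenetic grouping -> motifs -> gene structures ->
orthology -> physicochemical profiling -> expression, with a checksum manifest
for reproducibility.  Every stage writes its outputs before the next starts
and can be re-run standalone on the prior outputs.
"""

from __future__ import annotations

import configparser
import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from . import (expression, gene_structure, homology, motif_discovery,
               msa_phylo, protparam, repeat_scan, synthetic_data)

log = logging.getLogger("famcensus")

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]


@dataclass
class PipelineConfig:
    out_dir: str = "famcensus_out"
    seed: int = 42
    # synthetic-input generation (used when explicit inputs are not given)
    synth_total: int = 60
    substitution_rate: float = 0.05
    ct_noise_sd: float = 0.2
    # scan
    min_score: str | float = "auto"
    min_partial_score: str | float = "auto"
    max_adjacent_gap: int = 30
    # phylogeny
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    bootstrap_reps: int = 0
    specific_quantile: float = 0.9
    # motifs
    max_motifs: int = 5
    motif_width_grid: Tuple[int, ...] = (11, 21, 31, 41)
    motif_n_starts: int = 2
    # structure
    terminal_fraction: float = 0.25
    # homology
    homology_min_score: str | float = "auto"
    mcl_inflation: float = 2.0
    # expression
    reference_gene: str = "RPII"
    trend_tolerance: float = 0.05
    # optional explicit inputs (paths); synthetic inputs are generated when None
    proteome: Optional[str] = None
    cds: Optional[str] = None
    gff3: Optional[str] = None
    seed_alignment: Optional[str] = None
    anchors_fasta: Optional[str] = None
    anchors_tsv: Optional[str] = None
    ct_table: Optional[str] = None

    @classmethod
    def from_ini(cls, path: str) -> "PipelineConfig":
        """Flat key-value config with optional [sections]; keys match the
        dataclass field names."""
        cp = configparser.ConfigParser()
        cp.read(path)
        kwargs: Dict[str, object] = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for section in cp.sections():
            for key, val in cp.items(section):
                if key not in fields:
                    raise ValueError(f"unknown config key {key!r}")
                ftype = fields[key].type
                if val.lower() in ("none", ""):
                    kwargs[key] = None
                elif key == "motif_width_grid":
                    kwargs[key] = tuple(int(x) for x in val.split(","))
                elif "int" in str(ftype):
                    kwargs[key] = int(val)
                elif "float" in str(ftype) and val != "auto":
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = val
        return cls(**kwargs)


def _scaled_counts(total: int) -> Dict[str, int]:
    base = synthetic_data._default_counts()
    base_total = sum(base.values())
    counts = {k: max(1, round(v * total / base_total)) if v else 0
              for k, v in base.items()}
    counts["NONE"] += total - sum(counts.values())
    return counts


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _read_fasta(path: Path) -> Dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def _echo_params(cfg: PipelineConfig) -> None:
    for f in dataclasses.fields(cfg):
        log.info("param %s = %r", f.name, getattr(cfg, f.name))


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "inputs"
    out.mkdir(parents=True, exist_ok=True)
    spec = synthetic_data.FamilySpec(
        counts_per_class=_scaled_counts(cfg.synth_total),
        substitution_rate=cfg.substitution_rate, seed=cfg.seed)
    made = synthetic_data.generate_bundle(spec, ct_noise_sd=cfg.ct_noise_sd)
    bundle = made["bundle"]
    synthetic_data.write_fasta(bundle.proteins, out / "proteome.fasta")
    synthetic_data.write_fasta(bundle.cds, out / "cds.fasta")
    synthetic_data.write_fasta(bundle.anchors, out / "anchors.fasta")
    synthetic_data.write_fasta(dict(made["seed_alignment"]),
                               out / "seed_alignment.fasta")
    (out / "genes.gff3").write_text(made["gff3"])
    with open(out / "anchors.tsv", "w") as fh:
        fh.write("id\tsubfamily\tgroup\n")
        for aid in sorted(bundle.anchor_labels):
            sub, grp = bundle.anchor_labels[aid]
            fh.write(f"{aid}\t{sub}\t{grp}\n")
    made["ct_table"].to_csv(out / "ct.tsv", sep="\t", index=False,
                            float_format="%.6g")
    (out / "truth.json").write_text(bundle.truth.to_json())
    log.info("synth: %d proteins, %d anchors",
             len(bundle.proteins), len(bundle.anchors))


def _input_path(cfg: PipelineConfig, key: str, default_name: str) -> Path:
    explicit = getattr(cfg, key)
    if explicit:
        return Path(explicit)
    return Path(cfg.out_dir) / "inputs" / default_name


def stage_scan(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "scan"
    out.mkdir(parents=True, exist_ok=True)
    proteome = _read_fasta(_input_path(cfg, "proteome", "proteome.fasta"))
    seed_aln = _read_fasta(_input_path(cfg, "seed_alignment",
                                       "seed_alignment.fasta"))
    profile = repeat_scan.build_profile(list(seed_aln.values()))
    params = repeat_scan.ScanParams(
        min_score=cfg.min_score, min_partial_score=cfg.min_partial_score,
        max_adjacent_gap=cfg.max_adjacent_gap, seed=cfg.seed)
    cens, archs = repeat_scan.census(proteome, profile, params)
    (out / "architectures.tsv").write_text(
        repeat_scan.architecture_table(archs))
    (out / "census.json").write_text(json.dumps(
        {"counts": {k: len(v) for k, v in sorted(cens.members.items())},
         "total_myb": cens.total,
         "members": {k: sorted(v) for k, v in sorted(cens.members.items())}},
        indent=1, sort_keys=True))
    log.info("scan: %d MYB members of %d proteins", cens.total, len(proteome))


def _load_census(cfg: PipelineConfig) -> Dict[str, List[str]]:
    doc = json.loads((Path(cfg.out_dir) / "scan" / "census.json").read_text())
    return doc["members"]


def _load_anchors(cfg: PipelineConfig
                  ) -> Tuple[Dict[str, str], Dict[str, Tuple[str, str]]]:
    seqs = _read_fasta(_input_path(cfg, "anchors_fasta", "anchors.fasta"))
    labels: Dict[str, Tuple[str, str]] = {}
    path = _input_path(cfg, "anchors_tsv", "anchors.tsv")
    for line in path.read_text().splitlines()[1:]:
        aid, sub, grp = line.split("\t")
        labels[aid] = (sub, grp)
    return seqs, labels


def stage_classify(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "classify"
    out.mkdir(parents=True, exist_ok=True)
    proteome = _read_fasta(_input_path(cfg, "proteome", "proteome.fasta"))
    members = _load_census(cfg)
    candidates = {pid: proteome[pid]
                  for sub, ids in members.items() if sub != "NOT_MYB"
                  for pid in ids}
    anchor_seqs, anchor_labels = _load_anchors(cfg)
    a1 = {a: anchor_seqs[a] for a, (sub, _) in anchor_labels.items()
          if sub in ("R2R3", "R1R2R3")}
    l1 = {a: anchor_labels[a][1] for a in a1}
    a2 = {a: anchor_seqs[a] for a in anchor_seqs if a not in a1}
    l2 = {a: anchor_labels[a][1] for a in a2}
    params = msa_phylo.PhyloParams(
        matrix=cfg.matrix, gap_open=cfg.gap_open, gap_extend=cfg.gap_extend,
        bootstrap_reps=cfg.bootstrap_reps,
        specific_quantile=cfg.specific_quantile, seed=cfg.seed)
    result = msa_phylo.two_stage_classify(candidates, (a1, l1), (a2, l2),
                                          params)
    (out / "tree1.nwk").write_text(result.tree1.newick() + "\n")
    if result.tree2 is not None:
        (out / "tree2.nwk").write_text(result.tree2.newick() + "\n")
    (out / "assignments.tsv").write_text(
        msa_phylo.assignments_table(result))
    (out / "stages.json").write_text(json.dumps(
        {"stage1_labeled": result.stage1_labeled,
         "stage2_input": result.stage2_input,
         "total": len(candidates)}, indent=1, sort_keys=True))
    log.info("classify: %d candidates, %d labelled in stage 1, %d to stage 2",
             len(candidates), result.stage1_labeled, result.stage2_input)


def _load_assignments(cfg: PipelineConfig) -> pd.DataFrame:
    return pd.read_csv(Path(cfg.out_dir) / "classify" / "assignments.tsv",
                       sep="\t")


def stage_motifs(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "motifs"
    out.mkdir(parents=True, exist_ok=True)
    proteome = _read_fasta(_input_path(cfg, "proteome", "proteome.fasta"))
    members = _load_census(cfg)
    myb = {pid: proteome[pid]
           for sub, ids in members.items() if sub != "NOT_MYB"
           for pid in ids}
    models, occurrences = motif_discovery.discover_motifs(
        myb, max_motifs=cfg.max_motifs, width_grid=cfg.motif_width_grid,
        n_starts=cfg.motif_n_starts, seed=cfg.seed)
    (out / "motifs_meme.txt").write_text(
        motif_discovery.meme_minimal_text(models))
    with open(out / "occurrences.tsv", "w") as fh:
        fh.write("# start is 1-based\nprotein\tmotif\tstart\tposterior\n")
        for o in sorted(occurrences, key=lambda o: (o.protein_id, o.start)):
            fh.write(f"{o.protein_id}\t{o.motif_id}\t{o.start + 1}\t"
                     f"{o.posterior:.4f}\n")
    archs = motif_discovery.architecture_strings(occurrences)
    with open(out / "architectures.tsv", "w") as fh:
        fh.write("protein\tarchitecture\n")
        for pid in sorted(archs):
            fh.write(f"{pid}\t{archs[pid]}\n")
    assignments = _load_assignments(cfg)
    group_map = dict(zip(assignments["query"], assignments["group"]))
    cons = motif_discovery.architecture_conservation(
        archs, {p: g for p, g in group_map.items() if p in myb})
    with open(out / "conservation.tsv", "w") as fh:
        fh.write("group\tmodal_architecture\tconserved_fraction\tn\n")
        for grp, (modal, frac, n) in sorted(cons.items()):
            fh.write(f"{grp}\t{modal}\t{frac:.4f}\t{n}\n")
    for m in models:
        motif_discovery.logo_svg(m.theta, str(out / f"logo_m{m.motif_id}.svg"))
    log.info("motifs: %d motifs discovered", len(models))


def stage_structure(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "structure"
    out.mkdir(parents=True, exist_ok=True)
    models, chrom_lengths = gene_structure.parse_gff3(
        str(_input_path(cfg, "gff3", "genes.gff3")))
    members = _load_census(cfg)
    myb_ids = {pid for sub, ids in members.items() if sub != "NOT_MYB"
               for pid in ids}
    myb_models = [m for m in models if m.gene_id in myb_ids]
    records = [gene_structure.exon_intron_structure(m) for m in myb_models]
    (out / "structures.tsv").write_text(gene_structure.structure_table(records))
    cmap = gene_structure.chromosome_distribution(
        myb_models, chrom_lengths, cfg.terminal_fraction)
    (out / "distribution.tsv").write_text(gene_structure.distribution_table(cmap))
    (out / "chromosomes.svg").write_text(gene_structure.chromosome_svg(cmap))
    log.info("structure: %d MYB gene models", len(myb_models))


def stage_homology(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "homology"
    out.mkdir(parents=True, exist_ok=True)
    proteome = _read_fasta(_input_path(cfg, "proteome", "proteome.fasta"))
    members = _load_census(cfg)
    myb = {pid: proteome[pid]
           for sub, ids in members.items() if sub != "NOT_MYB"
           for pid in ids}
    anchor_seqs, _ = _load_anchors(cfg)
    species = {**{p: "query" for p in myb},
               **{a: "reference" for a in anchor_seqs}}
    pool = {**myb, **anchor_seqs}
    edges = homology.all_vs_all(pool, pool, matrix=cfg.matrix,
                                gap_open=cfg.gap_open,
                                gap_extend=cfg.gap_extend,
                                min_score=cfg.homology_min_score,
                                seed=cfg.seed)
    clusters = homology.mcl(sorted(pool), edges, inflation=cfg.mcl_inflation)
    orthologs, paralogs = homology.call_pairs(clusters, edges, species)
    (out / "orthologs.tsv").write_text(homology.pairs_table(orthologs, clusters))
    for sp, pairs in sorted(paralogs.items()):
        (out / f"paralogs_{sp}.tsv").write_text(
            homology.pairs_table(pairs, clusters))
    for sp in ("query", "reference"):
        p = out / f"paralogs_{sp}.tsv"
        if not p.exists():
            p.write_text(homology.pairs_table([], clusters))
    (out / "clusters.tsv").write_text(homology.clusters_table(clusters))
    log.info("homology: %d ortholog pairs, %d clusters",
             len(orthologs), len(clusters))


def stage_protparam(cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir) / "protparam"
    out.mkdir(parents=True, exist_ok=True)
    proteome = _read_fasta(_input_path(cfg, "proteome", "proteome.fasta"))
    members = _load_census(cfg)
    myb = {pid: proteome[pid]
           for sub, ids in members.items() if sub != "NOT_MYB"
           for pid in ids}
    profiles = protparam.profile_proteome(myb)
    (out / "physchem.tsv").write_text(protparam.profiles_table(profiles))
    (out / "summary.json").write_text(json.dumps(
        protparam.summary(profiles.values()), indent=1, sort_keys=True))
    log.info("protparam: %d proteins profiled", len(profiles))


def stage_expression(cfg: PipelineConfig) -> bool:
    out = Path(cfg.out_dir) / "expression"
    ct_path = _input_path(cfg, "ct_table", "ct.tsv")
    if not ct_path.exists():
        warnings.warn("Ct table missing; expression stage skipped")
        log.warning("expression: no Ct table at %s; skipped", ct_path)
        return False
    out.mkdir(parents=True, exist_ok=True)
    records = pd.read_csv(ct_path, sep="\t")
    dct = expression.delta_ct(records, cfg.reference_gene)
    results = expression.ddct_fold(dct)
    results.to_csv(out / "results.tsv", sep="\t", index=False,
                   float_format="%.6g")
    trends = expression.trends_by_gene(results, cfg.trend_tolerance)
    trends.to_csv(out / "trends.tsv", sep="\t", index=False)
    log.info("expression: %d conditions quantified", len(results))
    return True


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

STAGES = ("synth", "scan", "classify", "motifs", "structure", "homology",
          "protparam", "expression")


def run_pipeline(cfg: PipelineConfig) -> Dict[str, object]:
    """Run all stages in dependency order and write a checksum manifest.

    Re-running with the same config and seed reproduces identical manifests.
    A stage failure aborts with the failing stage named; outputs of completed
    stages are retained.
    """
    _echo_params(cfg)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    have_inputs = cfg.proteome is not None
    for name in STAGES:
        if name == "synth" and have_inputs:
            continue
        fn = globals()[f"stage_{name}"]
        log.info("=== stage %s ===", name)
        try:
            fn(cfg)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    artifacts: Dict[str, str] = {}
    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            artifacts[str(path.relative_to(out))] = _sha256(path)
    manifest = {"seed": cfg.seed, "artifacts": artifacts}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  sort_keys=True))
    return manifest


def validate_inputs(cfg: PipelineConfig) -> Dict[str, List[Dict[str, str]]]:
    """Report-only cross-checks of the configured inputs."""
    checks: List[Dict[str, str]] = []

    def add(name: str, status: str, detail: str = "") -> None:
        checks.append({"check": name, "status": status, "detail": detail})

    paths = {k: _input_path(cfg, k, d) for k, d in [
        ("proteome", "proteome.fasta"), ("gff3", "genes.gff3"),
        ("seed_alignment", "seed_alignment.fasta"),
        ("anchors_fasta", "anchors.fasta"), ("anchors_tsv", "anchors.tsv"),
        ("ct_table", "ct.tsv")]}
    for key, p in paths.items():
        add(f"exists:{key}", "pass" if p.exists() else
            ("warn" if key == "ct_table" else "fail"), str(p))
    if paths["proteome"].exists() and paths["gff3"].exists():
        prot = set(_read_fasta(paths["proteome"]))
        try:
            models, _ = gene_structure.parse_gff3(str(paths["gff3"]))
            genes = {m.gene_id for m in models}
            missing = sorted(prot - genes)
            add("proteome_gff3_agreement", "pass" if not missing else "warn",
                f"{len(missing)} proteome ids absent from GFF3"
                + (f": {missing[:5]}" if missing else ""))
        except Exception as exc:
            add("proteome_gff3_agreement", "fail", str(exc))
    if paths["anchors_fasta"].exists() and paths["anchors_tsv"].exists():
        seqs, labels = _load_anchors(cfg)
        unlabeled = sorted(set(seqs) - set(labels))
        add("anchor_label_coverage", "pass" if not unlabeled else "fail",
            f"{len(unlabeled)} anchors without labels")
        known_sub = set(repeat_scan.SUBFAMILIES)
        bad = sorted({s for s, _ in labels.values()} - known_sub)
        add("anchor_subfamilies_known", "pass" if not bad else "fail",
            f"unknown subfamilies: {bad}" if bad else "")
    if paths["ct_table"].exists():
        ct = pd.read_csv(paths["ct_table"], sep="\t")
        missing_cols = [c for c in expression.REQUIRED_COLUMNS
                        if c not in ct.columns]
        add("ct_columns", "pass" if not missing_cols else "fail",
            f"missing: {missing_cols}" if missing_cols else "")
        if not missing_cols:
            has_ref = cfg.reference_gene in set(ct["gene"])
            add("ct_reference_gene", "pass" if has_ref else "fail",
                cfg.reference_gene)
    return {"checks": checks}
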