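"""Orthology/paralogy calling: all-vs-all local alignment, reciprocal best
hits and Markov clustering (MCL), a desk-scale stand-in for the classic
BLAST + OrthoMCL workflow.

Local Smith-Waterman scores come from Biopython's C-implemented aligner; edge
weights are scores normalised by the geometric mean of the two self-scores, so
identical sequences get weight 1.  A gap of length k costs
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .synthetic_data import stream

__all__ = [
    "Edge",
    "HomologyGraph",
    "all_vs_all",
    "calibrate_min_score",
    "rbh",
    "mcl",
    "call_pairs",
]


@dataclass(frozen=True)
class Edge:
    a: str
    b: str
    weight: float
    score: float = 0.0

    def key(self) -> frozenset:
        return frozenset((self.a, self.b))


@dataclass
class HomologyGraph:
    species: Dict[str, str]                 # node -> species tag
    edges: List[Edge] = field(default_factory=list)


def _aligner(matrix: str, gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "local"
    al.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; with these settings a gap of
    # length k costs gap_open + k * gap_extend.
    al.open_gap_score = -(gap_open + gap_extend)
    al.extend_gap_score = -gap_extend
    return al


def local_score(a: str, b: str, matrix: str = "BLOSUM62",
                gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Smith-Waterman local alignment score."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    return float(_aligner(matrix, gap_open, gap_extend).score(a, b))


def calibrate_min_score(seqs: Mapping[str, str], matrix: str = "BLOSUM62",
                        gap_open: float = 10.0, gap_extend: float = 0.5,
                        n_pairs: int = 50, quantile: float = 0.99,
                        seed: int = 0) -> float:
    """Null score threshold: the given quantile of local scores between
    residue-shuffled sequence pairs (seeded)."""
    rng = stream(seed, "scan_null")
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    al = _aligner(matrix, gap_open, gap_extend)
    scores = []
    for _ in range(n_pairs):
        i, j = rng.choice(len(ids), size=2, replace=False)
        a = list(seqs[ids[i]])
        b = list(seqs[ids[j]])
        rng.shuffle(a)
        rng.shuffle(b)
        scores.append(float(al.score("".join(a), "".join(b))))
    return float(np.quantile(scores, quantile))


def all_vs_all(seqs_a: Mapping[str, str], seqs_b: Mapping[str, str],
               matrix: str = "BLOSUM62", gap_open: float = 10.0,
               gap_extend: float = 0.5,
               min_score: float | str = "auto",
               seed: int = 0) -> List[Edge]:
    """Weighted edge list over every cross pair scoring >= min_score.

    Weight = score / sqrt(self_a * self_b), in (0, 1] for positive scores.
    Passing the same mapping twice gives within-species edges (self pairs are
    skipped).  Result is sorted by (a, b) and invariant to input ordering.
    """
    if not seqs_a or not seqs_b:
        raise ValueError("sequence sets must be non-empty")
    al = _aligner(matrix, gap_open, gap_extend)
    if min_score == "auto":
        pool = dict(seqs_a)
        pool.update(seqs_b)
        min_score = calibrate_min_score(pool, matrix, gap_open, gap_extend,
                                        seed=seed)
    min_score = float(min_score)
    self_score: Dict[str, float] = {}
    for name, s in list(seqs_a.items()) + list(seqs_b.items()):
        if name not in self_score:
            self_score[name] = float(al.score(s, s))
    same = seqs_a is seqs_b or set(seqs_a) == set(seqs_b)
    edges: List[Edge] = []
    seen: Set[frozenset] = set()
    for na in sorted(seqs_a):
        for nb in sorted(seqs_b):
            if na == nb:
                continue
            key = frozenset((na, nb))
            if same and key in seen:
                continue
            seen.add(key)
            sc = float(al.score(seqs_a[na], seqs_b[nb]))
            if sc >= min_score:
                w = sc / np.sqrt(self_score[na] * self_score[nb])
                edges.append(Edge(min(na, nb), max(na, nb), float(w), sc))
    edges.sort(key=lambda e: (e.a, e.b))
    return edges


def rbh(edges: Sequence[Edge], species: Mapping[str, str]) -> List[Edge]:
    """Reciprocal best hits across the two species present in *species*.

    A pair is kept iff each member is the other's unique maximum-weight
    cross-species partner; ties yield no pair (conservative).
    """
    best: Dict[str, Tuple[float, List[str]]] = {}
    for e in edges:
        if species[e.a] == species[e.b]:
            continue
        for x, y in ((e.a, e.b), (e.b, e.a)):
            w, partners = best.get(x, (-np.inf, []))
            if e.weight > w:
                best[x] = (e.weight, [y])
            elif e.weight == w:
                partners.append(y)
    out = []
    for e in edges:
        if species[e.a] == species[e.b]:
            continue
        wa, pa = best.get(e.a, (None, []))
        wb, pb = best.get(e.b, (None, []))
        if pa == [e.b] and pb == [e.a]:
            out.append(e)
    return out


def mcl(nodes: Sequence[str], edges: Sequence[Edge], inflation: float = 2.0,
        max_iter: int = 200, prune_threshold: float = 1e-5,
        tol: float = 1e-6, contrast: float = 3.0) -> List[Set[str]]:
    """Markov clustering on the weighted undirected graph.

    Edge weights are raised to the ``contrast`` power when building the
    transition matrix: self-score-normalised similarities have a much more
    compressed dynamic range than the log-significance weights classic
    Markov-clustering orthology pipelines consume, and within-family vs
    between-family flow must differ enough for inflation to act on.  The
    column-stochastic matrix (self-loops equal to each node's maximum
    incident transformed weight) is then alternately expanded (squared) and
    inflated (element-wise power + renormalisation), pruning entries below
    ``prune_threshold``, until the change falls under ``tol``.  Clusters are
    the connected components of the limit matrix's support and always
    partition the node set.
    """
    nodes = sorted(set(nodes))
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for e in edges:
        i, j = index[e.a], index[e.b]
        M[i, j] = M[j, i] = max(M[i, j], e.weight ** contrast)
    loop = np.where(M.max(axis=0) > 0, M.max(axis=0), 1.0)
    M[np.diag_indices(n)] = loop
    M = M / M.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        new = M @ M
        new = np.power(new, inflation)
        new[new < prune_threshold] = 0.0
        colsum = new.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        new = new / colsum
        if np.abs(new - M).max() < tol:
            M = new
            converged = True
            break
        M = new
    if not converged:
        warnings.warn("MCL did not converge within max_iter; returning the "
                      "current partition")

    support = (M + M.T) > 0
    seen: Set[int] = set()
    clusters: List[Set[str]] = []
    for i in range(n):
        if i in seen:
            continue
        stack, comp = [i], set()
        while stack:
            k = stack.pop()
            if k in seen:
                continue
            seen.add(k)
            comp.add(nodes[k])
            stack.extend(np.nonzero(support[k])[0].tolist())
        clusters.append(comp)
    return clusters


def call_pairs(clusters: Sequence[Set[str]], edges: Sequence[Edge],
               species: Mapping[str, str],
               rbh_pairs: Optional[Sequence[Edge]] = None
               ) -> Tuple[List[Edge], Dict[str, List[Edge]]]:
    """Ortholog pairs (RBH pairs whose ends share a cluster) and per-species
    paralog pairs (within-cluster same-species edges whose weight reaches the
    cluster's mean cross-species weight; clusters without cross-species edges
    keep all their within-species edges)."""
    cluster_of: Dict[str, int] = {}
    for ci, cl in enumerate(clusters):
        for node in cl:
            cluster_of[node] = ci
    if rbh_pairs is None:
        rbh_pairs = rbh(edges, species)
    orthologs = [e for e in rbh_pairs
                 if cluster_of.get(e.a) == cluster_of.get(e.b)]

    cross_w: Dict[int, List[float]] = {}
    for e in edges:
        ci, cj = cluster_of.get(e.a), cluster_of.get(e.b)
        if ci is not None and ci == cj and species[e.a] != species[e.b]:
            cross_w.setdefault(ci, []).append(e.weight)
    thresholds = {ci: float(np.mean(ws)) for ci, ws in cross_w.items()}

    paralogs: Dict[str, List[Edge]] = {}
    for e in edges:
        if species[e.a] != species[e.b]:
            continue
        ci, cj = cluster_of.get(e.a), cluster_of.get(e.b)
        if ci is None or ci != cj:
            continue
        thr = thresholds.get(ci)
        if thr is None or e.weight >= thr:
            paralogs.setdefault(species[e.a], []).append(e)
    for sp in paralogs:
        paralogs[sp].sort(key=lambda e: (e.a, e.b))
    return orthologs, paralogs


def pairs_table(pairs: Sequence[Edge], clusters: Sequence[Set[str]]) -> str:
    cluster_of: Dict[str, int] = {}
    for ci, cl in enumerate(clusters):
        for node in cl:
            cluster_of[node] = ci
    lines = ["idA\tidB\tweight\tcluster"]
    for e in sorted(pairs, key=lambda e: (e.a, e.b)):
        lines.append(f"{e.a}\t{e.b}\t{e.weight:.4f}\t{cluster_of.get(e.a, -1)}")
    return "\n".join(lines) + "\n"


def clusters_table(clusters: Sequence[Set[str]]) -> str:
    lines = ["cluster\tmembers"]
    for ci, cl in enumerate(clusters):
        lines.append(f"{ci}\t{','.join(sorted(cl))}")
    return "\n".join(lines) + "\n"
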