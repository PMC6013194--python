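"""Progressive multiple alignment, neighbour-joining trees with bootstrap, and
anchor-guided group classification.

The alignment engine is a Gotoh affine-gap dynamic programme over residue
profiles (a sequence is a one-hot profile), used both for pairwise alignment
and for the profile-profile merges of the progressive strategy (guide tree:
3-mer distance + UPGMA).  Distances are p-distances with pairwise gap
deletion; trees are built with the Saitou-Nei neighbour-joining algorithm and
supported by column-resampling bootstrap.  Queries are labelled by the
smallest edge-bounded subtree that contains them together with at least one
labelled anchor; queries too far from every anchor (beyond a quantile of the
within-group anchor-anchor patristic distances) are called species-specific.
A gap of length k costs ``gap_open + k * gap_extend``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .synthetic_data import AMINO_ACIDS, SPECIES_SPECIFIC, stream

__all__ = [
    "Alignment",
    "DistanceMatrix",
    "Tree",
    "TreeNode",
    "GroupAssignment",
    "TwoStageResult",
    "PhyloParams",
    "pairwise_align",
    "progressive_msa",
    "distance_matrix",
    "nj_tree",
    "bootstrap_supports",
    "assign_groups",
    "two_stage_classify",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG_INF = -1e30


def _load_matrix(name: str) -> np.ndarray:
    m = substitution_matrices.load(name)
    S = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            S[i, j] = m[a, b]
    return S


# ---------------------------------------------------------------------------
# Alignment containers
# ---------------------------------------------------------------------------

@dataclass
class Alignment:
    records: List[Tuple[str, str]]          # (id, gapped sequence)

    def __post_init__(self) -> None:
        if self.records:
            w = len(self.records[0][1])
            if any(len(s) != w for _, s in self.records):
                raise ValueError("alignment rows have unequal length")

    @property
    def ids(self) -> List[str]:
        return [i for i, _ in self.records]

    @property
    def width(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def encoded(self) -> np.ndarray:
        """n x width integer matrix; gaps/unknowns are -1."""
        return np.array(
            [[_AA_INDEX.get(c, -1) for c in s] for _, s in self.records],
            dtype=np.int64)

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.width, size=self.width)
        return Alignment([(i, "".join(s[c] for c in cols))
                          for i, s in self.records])


@dataclass
class DistanceMatrix:
    labels: List[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = self.matrix
        if m.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if np.any(m < 0) or not np.allclose(m, m.T):
            raise ValueError("matrix must be symmetric and non-negative")


# ---------------------------------------------------------------------------
# Gotoh affine alignment over profiles
# ---------------------------------------------------------------------------

def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    L = len(rows[0])
    C = np.zeros((L, 20))
    for s in rows:
        for j, c in enumerate(s):
            k = _AA_INDEX.get(c, -1)
            if k >= 0:
                C[j, k] += 1
    return C


def _gotoh(score: np.ndarray, gap_open: float, gap_extend: float
           ) -> Tuple[float, List[Tuple[int, int]]]:
    """Global affine-gap DP on a precomputed (La x Lb) column-score matrix.

    Returns the optimal score and the traceback as a list of (da, db) steps,
    each (1,1) match, (0,1) gap in A, or (1,0) gap in B.  Tie-break on
    traceback prefers match, then gap-in-A, then gap-in-B.
    """
    La, Lb = score.shape
    go, ge = gap_open, gap_extend
    M = np.full((La + 1, Lb + 1), _NEG_INF)
    Ix = np.full((La + 1, Lb + 1), _NEG_INF)   # gap in A (consumes B)
    Iy = np.full((La + 1, Lb + 1), _NEG_INF)   # gap in B (consumes A)
    M[0, 0] = 0.0
    j = np.arange(1, Lb + 1)
    Ix[0, 1:] = -(go + j * ge)
    i = np.arange(1, La + 1)
    Iy[1:, 0] = -(go + i * ge)

    jj = np.arange(Lb + 1)
    for r in range(1, La + 1):
        prev_best = np.maximum(np.maximum(M[r - 1], Ix[r - 1]), Iy[r - 1])
        M[r, 1:] = score[r - 1] + prev_best[:-1]
        Iy[r, 1:] = np.maximum(M[r - 1, 1:] - go - ge, Iy[r - 1, 1:] - ge)
        # within-row horizontal scan via running maximum
        run = np.maximum.accumulate(M[r] + jj * ge)
        Ix[r, 1:] = run[:-1] - go - jj[1:] * ge

    end = max((M[La, Lb], 0), (Ix[La, Lb], 1), (Iy[La, Lb], 2),
              key=lambda t: (t[0], -t[1]))
    best, state = end
    steps: List[Tuple[int, int]] = []
    r, c = La, Lb
    eps = 1e-9
    while r > 0 or c > 0:
        if state == 0:
            steps.append((1, 1))
            target = M[r, c] - score[r - 1, c - 1]
            r, c = r - 1, c - 1
            for s, v in ((0, M[r, c]), (1, Ix[r, c]), (2, Iy[r, c])):
                if abs(v - target) < eps:
                    state = s
                    break
        elif state == 1:
            steps.append((0, 1))
            target = Ix[r, c]
            c = c - 1
            if abs(M[r, c] - go - ge - target) < eps:
                state = 0
            else:
                state = 1
        else:
            steps.append((1, 0))
            target = Iy[r, c]
            r = r - 1
            if abs(M[r, c] - go - ge - target) < eps:
                state = 0
            else:
                state = 2
        if r == 0 and c > 0:
            state = 1
        elif c == 0 and r > 0:
            state = 2
    steps.reverse()
    return float(best), steps


def pairwise_align(a: str, b: str, matrix: str = "BLOSUM62",
                   gap_open: float = 10.0, gap_extend: float = 0.5
                   ) -> Tuple[float, Tuple[str, str]]:
    """Global affine-gap pairwise alignment maximising the summed
    substitution score minus gap costs (gap of length k costs
    gap_open + k * gap_extend)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    S = _load_matrix(matrix)
    ia = np.array([_AA_INDEX[c] for c in a])
    ib = np.array([_AA_INDEX[c] for c in b])
    score = S[ia][:, ib]
    best, steps = _gotoh(score, gap_open, gap_extend)
    out_a, out_b = [], []
    pa = pb = 0
    for da, db in steps:
        out_a.append(a[pa] if da else "-")
        out_b.append(b[pb] if db else "-")
        pa += da
        pb += db
    return best, ("".join(out_a), "".join(out_b))


def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    if len(a) < k or len(b) < k:
        return 1.0
    ka = {a[i: i + k] for i in range(len(a) - k + 1)}
    kb = {b[i: i + k] for i in range(len(b) - k + 1)}
    denom = min(len(a), len(b)) - k + 1
    return 1.0 - len(ka & kb) / denom


@dataclass
class PhyloParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    min_support: float = 0.0
    specific_quantile: float = 0.9
    bootstrap_reps: int = 0
    seed: int = 0


def progressive_msa(seqs: Mapping[str, str] | Sequence[Tuple[str, str]],
                    params: Optional[PhyloParams] = None) -> Alignment:
    """Progressive multiple alignment: 3-mer distance + UPGMA guide tree,
    profiles merged leaf-to-root by profile-profile affine alignment.  Columns
    are preserved once formed (no realignment)."""
    params = params or PhyloParams()
    items = list(seqs.items()) if isinstance(seqs, Mapping) else list(seqs)
    if len(items) < 2:
        raise ValueError("need >= 2 sequences")
    ids = [i for i, _ in items]
    raw = {i: s for i, s in items}
    S = _load_matrix(params.matrix)
    n = len(ids)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = _kmer_distance(raw[ids[i]], raw[ids[j]])
    Z = hierarchy.linkage(squareform(D, checks=False), method="average")

    # cluster index -> list of (id, gapped string)
    profiles: Dict[int, List[Tuple[str, str]]] = {
        i: [(ids[i], raw[ids[i]])] for i in range(n)}
    for step, (ia, ib, _, _) in enumerate(Z):
        pa = profiles.pop(int(ia))
        pb = profiles.pop(int(ib))
        Ca = _profile_counts([s for _, s in pa])
        Cb = _profile_counts([s for _, s in pb])
        na, nb = len(pa), len(pb)
        score = (Ca @ S @ Cb.T) / (na * nb)
        _, steps = _gotoh(score, params.gap_open, params.gap_extend)
        new_a = {idx: [] for idx in range(na)}
        new_b = {idx: [] for idx in range(nb)}
        qa = qb = 0
        for da, db in steps:
            for idx, (_, s) in enumerate(pa):
                new_a[idx].append(s[qa] if da else "-")
            for idx, (_, s) in enumerate(pb):
                new_b[idx].append(s[qb] if db else "-")
            qa += da
            qb += db
        merged = [(pa[idx][0], "".join(new_a[idx])) for idx in range(na)]
        merged += [(pb[idx][0], "".join(new_b[idx])) for idx in range(nb)]
        profiles[n + step] = merged
    final = profiles.popitem()[1]
    order = {i: k for k, i in enumerate(ids)}
    final.sort(key=lambda rec: order[rec[0]])
    return Alignment(final)


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

class DataError(ValueError):
    pass


def distance_matrix(alignment: Alignment) -> DistanceMatrix:
    """p-distance with pairwise gap deletion: mismatches / compared sites over
    positions where neither row has a gap."""
    if len(alignment.records) < 2:
        raise ValueError("need >= 2 rows")
    A = alignment.encoded()
    n = A.shape[0]
    D = np.zeros((n, n))
    valid = A >= 0
    for i, j in itertools.combinations(range(n), 2):
        both = valid[i] & valid[j]
        comp = int(both.sum())
        if comp == 0:
            raise DataError(f"no comparable sites between "
                            f"{alignment.ids[i]!r} and {alignment.ids[j]!r}")
        mism = int(((A[i] != A[j]) & both).sum())
        D[i, j] = D[j, i] = mism / comp
    return DistanceMatrix(labels=list(alignment.ids), matrix=D)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: Optional[str] = None              # leaf name; None for internal
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)
    support: Optional[float] = None         # % on the edge above this node

    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf():
            return [self.name]
        out: List[str] = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out


@dataclass
class Tree:
    root: TreeNode                          # trifurcating for unrooted trees

    def leaves(self) -> List[str]:
        return self.root.leaves()

    def newick(self) -> str:
        def fmt(node: TreeNode, length: Optional[float]) -> str:
            if node.is_leaf():
                body = node.name
            else:
                inner = ",".join(fmt(c, bl) for c, bl in node.children)
                label = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){label}"
            return body if length is None else f"{body}:{length:.10g}"
        return fmt(self.root, None) + ";"

    # -- structural queries -------------------------------------------------

    def _edges(self) -> List[Tuple[TreeNode, TreeNode, float]]:
        out = []

        def walk(node: TreeNode) -> None:
            for c, bl in node.children:
                out.append((node, c, bl))
                walk(c)
        walk(self.root)
        return out

    def bipartitions(self) -> Dict[frozenset, TreeNode]:
        """Internal-edge bipartitions keyed canonically by the side that does
        not contain the alphabetically first leaf."""
        all_leaves = set(self.leaves())
        ref = min(all_leaves)
        out: Dict[frozenset, TreeNode] = {}
        for _, child, _ in self._edges():
            side = frozenset(child.leaves())
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            key = side if ref not in side else frozenset(all_leaves - side)
            out[key] = child
        return out

    def patristic_distances(self) -> Tuple[List[str], np.ndarray]:
        leaves = sorted(self.leaves())
        index = {l: i for i, l in enumerate(leaves)}
        n = len(leaves)
        D = np.zeros((n, n))
        # adjacency over all nodes
        adj: Dict[int, List[Tuple[int, float]]] = {}
        nodes: List[TreeNode] = []

        def reg(node: TreeNode) -> int:
            nodes.append(node)
            return len(nodes) - 1

        idx_of: Dict[int, int] = {}

        def walk(node: TreeNode) -> int:
            ni = reg(node)
            idx_of[id(node)] = ni
            adj.setdefault(ni, [])
            for c, bl in node.children:
                ci = walk(c)
                adj[ni].append((ci, bl))
                adj[ci].append((ni, bl))
            return ni
        walk(self.root)
        leaf_node = {nodes[i].name: i for i in range(len(nodes))
                     if nodes[i].is_leaf()}
        for name, start in leaf_node.items():
            dist = {start: 0.0}
            stack = [start]
            while stack:
                u = stack.pop()
                for v, bl in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + bl
                        stack.append(v)
            for other, oi in leaf_node.items():
                D[index[name], index[other]] = dist[oi]
        return leaves, D


def nj_tree(D: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbour joining.

    Iteratively joins the pair minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j;
    ties are broken on the label-sorted pair (cluster label = smallest leaf
    name below it).  Negative branch lengths are clamped to zero with the
    deficit moved to the sibling branch, preserving the pair's summed length.
    """
    n = len(D.labels)
    if n < 3:
        raise ValueError("neighbour joining needs >= 3 taxa")
    mat = D.matrix.copy()
    nodes: List[TreeNode] = [TreeNode(name=l) for l in D.labels]
    labels: List[str] = list(D.labels)     # cluster label = min leaf below

    def clamp(li: float, lj: float) -> Tuple[float, float]:
        if li < 0:
            lj = max(lj + li, 0.0)
            li = 0.0
        if lj < 0:
            li = max(li + lj, 0.0)
            lj = 0.0
        return li, lj

    while len(nodes) > 3:
        m = len(nodes)
        r = mat.sum(axis=1)
        Q = (m - 2) * mat - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        cand = np.argwhere(Q <= qmin + 1e-12)
        pairs = sorted(
            (tuple(sorted((labels[i], labels[j]))), (i, j))
            for i, j in cand if i < j)
        (i, j) = pairs[0][1]
        dij = mat[i, j]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        li, lj = clamp(li, lj)
        parent = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        new_d = 0.5 * (mat[i] + mat[j] - dij)
        keep = [k for k in range(m) if k not in (i, j)]
        new_mat = np.zeros((len(keep) + 1, len(keep) + 1))
        new_mat[:-1, :-1] = mat[np.ix_(keep, keep)]
        new_mat[-1, :-1] = new_mat[:-1, -1] = new_d[keep]
        mat = new_mat
        nodes = [nodes[k] for k in keep] + [parent]
        labels = [labels[k] for k in keep] + [min(labels[i], labels[j])]

    # resolve the final three around an unrooted centre
    d01, d02, d12 = mat[0, 1], mat[0, 2], mat[1, 2]
    l0 = max(0.5 * (d01 + d02 - d12), 0.0)
    l1 = max(0.5 * (d01 + d12 - d02), 0.0)
    l2 = max(0.5 * (d02 + d12 - d01), 0.0)
    centre = TreeNode(children=[(nodes[0], l0), (nodes[1], l1),
                                (nodes[2], l2)])
    return Tree(root=centre)


def bootstrap_supports(alignment: Alignment, n_reps: int = 100, seed: int = 0,
                       treebuilder: Optional[Callable[[Alignment], Tree]] = None
                       ) -> Tuple[Tree, Dict[frozenset, float]]:
    """Column-resampling bootstrap.

    Builds the reference tree on the full alignment, then ``n_reps`` trees on
    column-resampled replicates; the support of each internal edge is the
    percentage of replicate trees containing the same bipartition.  Returns
    the reference tree with supports attached plus the support map.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if alignment.width == 0:
        raise ValueError("alignment width is zero")
    build = treebuilder or (lambda a: nj_tree(distance_matrix(a)))
    rng = stream(seed, "pipeline")
    ref = build(alignment)
    target = ref.bipartitions()
    counts = {k: 0 for k in target}
    for _ in range(n_reps):
        rep = build(alignment.resample_columns(rng))
        found = set(rep.bipartitions())
        for k in counts:
            if k in found:
                counts[k] += 1
    supports = {k: 100.0 * v / n_reps for k, v in counts.items()}
    for k, node in target.items():
        node.support = supports[k]
    return ref, supports


# ---------------------------------------------------------------------------
# Anchor-guided group assignment
# ---------------------------------------------------------------------------

@dataclass
class GroupAssignment:
    query: str
    group: str
    stage: int
    nearest_anchor: Optional[str]
    nearest_distance: float
    support: Optional[float] = None
    clade_anchors: List[str] = field(default_factory=list)


def assign_groups(tree: Tree, anchors: Mapping[str, str],
                  min_support: float = 0.0,
                  specific_quantile: float = 0.9,
                  stage: int = 1) -> Dict[str, GroupAssignment]:
    """Label every non-anchor leaf of *tree*.

    Each query takes the majority anchor label of the smallest edge-bounded
    subtree containing the query and at least one anchor (label ties broken by
    nearest patristic anchor, then lexicographically).  Queries whose nearest
    anchor lies beyond the ``specific_quantile`` quantile of within-group
    anchor-anchor patristic distances are called species-specific.
    """
    if not anchors:
        raise ValueError("anchor map must be non-empty")
    leaves, D = tree.patristic_distances()
    index = {l: i for i, l in enumerate(leaves)}
    anchor_names = [a for a in anchors if a in index]
    if not anchor_names:
        raise ValueError("tree contains no anchor leaves")
    queries = [l for l in leaves if l not in anchors]

    within: List[float] = []
    by_label: Dict[str, List[str]] = {}
    for a in anchor_names:
        by_label.setdefault(anchors[a], []).append(a)
    for label, members in by_label.items():
        for x, y in itertools.combinations(members, 2):
            within.append(D[index[x], index[y]])
    threshold = float(np.quantile(within, specific_quantile)) if within else np.inf

    all_leaves = set(leaves)
    edge_sides: List[Tuple[frozenset, Optional[float]]] = []
    for _, child, _ in tree._edges():
        side = frozenset(child.leaves())
        edge_sides.append((side, child.support))

    out: Dict[str, GroupAssignment] = {}
    for q in queries:
        qi = index[q]
        adist = {a: D[qi, index[a]] for a in anchor_names}
        nearest = min(adist, key=lambda a: (adist[a], a))
        if adist[nearest] > threshold:
            out[q] = GroupAssignment(q, SPECIES_SPECIFIC, stage, nearest,
                                     float(adist[nearest]))
            continue
        best: Optional[Tuple[int, Tuple[str, ...], frozenset, Optional[float]]] = None
        for side, support in edge_sides:
            qside = side if q in side else frozenset(all_leaves - side)
            inside = [a for a in anchor_names if a in qside]
            if not inside:
                continue
            if min_support > 0 and support is not None and support < min_support:
                continue
            key = (len(qside), tuple(sorted(qside)), qside, support)
            if best is None or key[:2] < best[:2]:
                best = key
        assert best is not None
        _, _, clade, support = best
        clade_anchors = [a for a in anchor_names if a in clade]
        tally: Dict[str, int] = {}
        for a in clade_anchors:
            tally[anchors[a]] = tally.get(anchors[a], 0) + 1
        top = max(tally.values())
        tied = sorted(l for l, c in tally.items() if c == top)
        if len(tied) > 1:
            tied.sort(key=lambda l: (min(adist[a] for a in clade_anchors
                                         if anchors[a] == l), l))
        out[q] = GroupAssignment(q, tied[0], stage, nearest,
                                 float(adist[nearest]), support,
                                 sorted(clade_anchors))
    return out


def _classify_stage(queries: Mapping[str, str], anchor_seqs: Mapping[str, str],
                    anchor_labels: Mapping[str, str], params: PhyloParams,
                    stage: int) -> Tuple[Dict[str, GroupAssignment], Tree]:
    aln = progressive_msa({**dict(queries), **dict(anchor_seqs)}, params)
    if params.bootstrap_reps > 0:
        tree, _ = bootstrap_supports(aln, params.bootstrap_reps, params.seed)
    else:
        tree = nj_tree(distance_matrix(aln))
    assigned = assign_groups(tree, anchor_labels, params.min_support,
                             params.specific_quantile, stage=stage)
    return assigned, tree


@dataclass
class TwoStageResult:
    assignments: Dict[str, GroupAssignment]
    stage1_labeled: int
    stage2_input: int
    tree1: Tree
    tree2: Optional[Tree]


def two_stage_classify(candidates: Mapping[str, str],
                       anchors_r2r3_3r: Tuple[Mapping[str, str], Mapping[str, str]],
                       anchors_other: Tuple[Mapping[str, str], Mapping[str, str]],
                       params: Optional[PhyloParams] = None) -> TwoStageResult:
    """Two-tree classification strategy.

    Stage 1 places all candidates on a tree with the 2R/3R anchors and labels
    the queries falling into anchored clades; the remainder joins the 1R / 4R
    / atypical anchors in a second tree.  The union of labels covers every
    candidate; queries anchored in neither stage stay species-specific.
    """
    params = params or PhyloParams()
    seqs1, labels1 = anchors_r2r3_3r
    seqs2, labels2 = anchors_other
    if set(seqs1) & set(seqs2):
        raise ValueError("anchor sets must be disjoint")
    if not candidates:
        raise ValueError("no candidates to classify")

    stage1, tree1 = _classify_stage(candidates, seqs1, labels1, params, stage=1)
    labeled = {q: a for q, a in stage1.items() if a.group != SPECIES_SPECIFIC}
    remainder = {q: candidates[q] for q in candidates if q not in labeled}

    tree2 = None
    final = dict(labeled)
    if remainder and seqs2:
        stage2, tree2 = _classify_stage(remainder, seqs2, labels2, params,
                                        stage=2)
        final.update(stage2)
    else:
        for q in remainder:
            final[q] = stage1[q]
    return TwoStageResult(assignments=final, stage1_labeled=len(labeled),
                          stage2_input=len(remainder), tree1=tree1,
                          tree2=tree2)


def assignments_table(result: TwoStageResult) -> str:
    lines = ["query\tstage\tgroup\tsupport\tnearest_anchor\tnearest_distance"]
    for q in sorted(result.assignments):
        a = result.assignments[q]
        sup = "" if a.support is None else f"{a.support:.1f}"
        lines.append(f"{q}\t{a.stage}\t{a.group}\t{sup}\t"
                     f"{a.nearest_anchor or ''}\t{a.nearest_distance:.4f}")
    return "\n".join(lines) + "\n"
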