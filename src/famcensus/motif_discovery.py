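"""ZOOPS-EM motif discovery, information-content logos, and per-protein
motif-architecture strings.

The ZOOPS (zero-or-one occurrence per sequence) model: each sequence carries
at most one occurrence of a width-W motif, with occurrence prior lambda and a
uniform positional prior.  Expectation-maximisation alternates occurrence
posteriors (E) with position-frequency-matrix and lambda updates (M);
the observed-data log likelihood is non-decreasing across iterations.
Discovery iterates EM over a width grid, masks found occurrences with
background-sampled residues, and repeats up to ``max_motifs`` times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .synthetic_data import AMINO_ACIDS, stream

__all__ = [
    "MotifModel",
    "MotifOccurrence",
    "zoops_em",
    "discover_motifs",
    "information_content",
    "letter_heights",
    "consensus",
    "architecture_strings",
    "architecture_conservation",
    "meme_minimal_text",
]

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


@dataclass
class MotifModel:
    width: int
    theta: np.ndarray               # W x 20, row-stochastic
    background: np.ndarray          # 20-vector
    occurrence_prior: float         # lambda, in [0, 1]
    motif_id: int = 1
    log_likelihood: float = float("-inf")
    ll_trace: List[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.theta.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("theta rows must sum to 1")
        if not 0.0 <= self.occurrence_prior <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")

    @property
    def relative_entropy_per_column(self) -> float:
        t = np.clip(self.theta, 1e-12, 1.0)
        re = (t * np.log2(t / self.background[None, :])).sum(axis=1)
        return float(re.mean())

    @property
    def penalized_information(self) -> float:
        """Total relative entropy minus one bit per column; scores a motif's
        information content against its parameter cost, so a fully conserved
        wide motif beats any of its sub-windows while padding a motif with
        uninformative background columns is penalised."""
        t = np.clip(self.theta, 1e-12, 1.0)
        re = (t * np.log2(t / self.background[None, :])).sum(axis=1)
        return float(re.sum() - self.width)


@dataclass
class MotifOccurrence:
    protein_id: str
    motif_id: int
    start: int                      # 0-based
    posterior: float


def _encode(seqs: Mapping[str, str]) -> Dict[str, np.ndarray]:
    return {k: np.array([_AA_INDEX[c] for c in v], dtype=np.int64)
            for k, v in seqs.items()}


def _background(encoded: Mapping[str, np.ndarray]) -> np.ndarray:
    counts = np.ones(20)  # +1 smoothing
    for arr in encoded.values():
        counts += np.bincount(arr, minlength=20)
    return counts / counts.sum()


def _window_loglik(arr: np.ndarray, log_ratio: np.ndarray) -> np.ndarray:
    """log(P_motif/P_bg) for every window start in one sequence."""
    W = log_ratio.shape[0]
    m = arr.size - W + 1
    gather = arr[np.arange(m)[:, None] + np.arange(W)[None, :]]
    return log_ratio[np.arange(W)[None, :], gather].sum(axis=1)


def _theta_from_window(arr: np.ndarray, p: int, width: int,
                       bg: np.ndarray) -> np.ndarray:
    theta = np.tile(bg, (width, 1)) * 0.3
    theta[np.arange(width), arr[p: p + width]] += 0.7
    return theta / theta.sum(axis=1, keepdims=True)


def zoops_em(seqs: Mapping[str, str], width: int, n_starts: int = 3,
             max_iter: int = 200, tol: float = 1e-6, seed: int = 0,
             background: Optional[np.ndarray] = None,
             pseudocount_frac: float = 0.01, init_candidates: int = 30
             ) -> Tuple[MotifModel, List[MotifOccurrence]]:
    """Fit the ZOOPS model at a fixed width.

    Initial position-frequency matrices are derived from observed windows:
    ``init_candidates`` seeded sample windows are ranked by one-E-step log
    likelihood and the best ``n_starts`` are run to convergence; the winner by
    final log likelihood is returned.  Occurrences are reported for sequences
    whose total occurrence posterior exceeds 0.5, at the maximum-posterior
    start position.
    """
    if width < 2:
        raise ValueError("width must be >= 2")
    ids = sorted(seqs)
    short = [k for k in ids if len(seqs[k]) < width]
    if short:
        raise ValueError(f"sequences shorter than the motif width: {short}")
    encoded = _encode(seqs)
    bg = _background(encoded) if background is None else np.asarray(background)
    log_bg = np.log(bg)
    rng = stream(seed, "pipeline")
    gathers = {}
    for k in ids:
        arr = encoded[k]
        m = arr.size - width + 1
        gathers[k] = arr[np.arange(m)[:, None] + np.arange(width)[None, :]]

    def e_step(theta: np.ndarray, lam: float
               ) -> Tuple[float, Dict[str, np.ndarray], float]:
        log_ratio = np.log(np.clip(theta, 1e-12, None)) - log_bg[None, :]
        ll = 0.0
        z_store: Dict[str, np.ndarray] = {}
        z_total = 0.0
        for k in ids:
            arr = encoded[k]
            m = arr.size - width + 1
            llr = log_ratio[np.arange(width)[None, :], gathers[k]].sum(axis=1)
            mx = max(float(llr.max()), 0.0)
            w_pos = (lam / m) * np.exp(llr - mx)
            denom = (1.0 - lam) * np.exp(-mx) + w_pos.sum()
            ll += float(np.log(denom) + mx + log_bg[arr].sum())
            z = w_pos / denom
            z_store[k] = z
            z_total += float(z.sum())
        return ll, z_store, z_total

    def run_em(theta: np.ndarray
               ) -> Tuple[MotifModel, List[MotifOccurrence]]:
        lam = 0.5
        ll_trace: List[float] = []
        z_store: Dict[str, np.ndarray] = {}
        for _ in range(max_iter):
            ll, z_store, z_total = e_step(theta, lam)
            ll_trace.append(ll)
            if len(ll_trace) > 1 and abs(ll_trace[-1] - ll_trace[-2]) < tol:
                break
            counts = np.zeros((width, 20))
            for k in ids:
                z = z_store[k]
                if z.sum() > 0:
                    for j in range(width):
                        np.add.at(counts[j], gathers[k][:, j], z)
            pc = pseudocount_frac * bg
            theta = counts + pc[None, :]
            theta /= theta.sum(axis=1, keepdims=True)
            lam = min(max(z_total / len(ids), 1e-6), 1.0 - 1e-6)
        occurrences = []
        for k in ids:
            z = z_store[k]
            tot = float(z.sum())
            if tot > 0.5:
                occurrences.append(MotifOccurrence(k, 1, int(z.argmax()), tot))
        model = MotifModel(width=width, theta=theta, background=bg,
                           occurrence_prior=float(lam),
                           log_likelihood=ll_trace[-1], ll_trace=ll_trace)
        return model, occurrences

    def shift_refine(model: MotifModel, occurrences: List[MotifOccurrence]
                     ) -> Tuple[MotifModel, List[MotifOccurrence]]:
        """Phase-shift correction: EM can converge a few columns out of
        register with the planted site; re-seed from shifted occurrence
        windows and keep any shift that raises the likelihood."""
        pc = pseudocount_frac * bg
        for _ in range(6):
            best_shift = None
            for s in (-3, -2, -1, 1, 2, 3):
                counts = np.zeros((width, 20))
                n_used = 0
                for o in occurrences:
                    arr = encoded[o.protein_id]
                    p = o.start + s
                    if 0 <= p <= arr.size - width:
                        counts[np.arange(width), arr[p: p + width]] += o.posterior
                        n_used += 1
                if n_used == 0:
                    continue
                theta_s = counts + pc[None, :]
                theta_s /= theta_s.sum(axis=1, keepdims=True)
                ll_s, _, _ = e_step(theta_s, model.occurrence_prior)
                if ll_s > model.log_likelihood + tol and (
                        best_shift is None or ll_s > best_shift[0]):
                    best_shift = (ll_s, theta_s)
            if best_shift is None:
                break
            model, occurrences = run_em(best_shift[1])
        return model, occurrences

    # rank candidate seed windows by one-E-step likelihood
    scored: List[Tuple[float, np.ndarray]] = []
    for _ in range(init_candidates):
        sid = ids[int(rng.integers(0, len(ids)))]
        arr = encoded[sid]
        p = int(rng.integers(0, arr.size - width + 1))
        theta0 = _theta_from_window(arr, p, width, bg)
        ll0, _, _ = e_step(theta0, 0.5)
        scored.append((ll0, theta0))
    scored.sort(key=lambda t: -t[0])

    best: Optional[Tuple[float, MotifModel, List[MotifOccurrence]]] = None
    for _, theta0 in scored[:max(1, n_starts)]:
        model, occurrences = run_em(theta0)
        model, occurrences = shift_refine(model, occurrences)
        if best is None or model.log_likelihood > best[0]:
            best = (model.log_likelihood, model, occurrences)
    assert best is not None
    return best[1], best[2]


def discover_motifs(seqs: Mapping[str, str], max_motifs: int = 15,
                    width_range: Tuple[int, int] = (2, 250),
                    width_grid: Optional[Sequence[int]] = None,
                    n_starts: int = 2, min_re_per_col: float = 0.3,
                    seed: int = 0, max_iter: int = 100
                    ) -> Tuple[List[MotifModel], List[MotifOccurrence]]:
    """Iterative ZOOPS discovery with masking.

    At each round, EM runs at every width of a practical grid (default
    6,8,...,50, clipped to ``width_range`` and the shortest sequence) and the
    width with the best penalized information (total relative entropy minus
    one bit per column) wins; its occurrences are masked by
    background-sampled residues before the next round.  Motifs are numbered
    by discovery order.  Stops early when the best motif falls under
    ``min_re_per_col`` bits/column.
    """
    if not seqs:
        raise ValueError("empty sequence set")
    rng = stream(seed, "pipeline")
    work = {k: v for k, v in seqs.items()}
    min_len = min(len(v) for v in work.values())
    if width_grid is None:
        width_grid = list(range(6, 51, 2))
    grid = [w for w in width_grid
            if width_range[0] <= w <= min(width_range[1], min_len)]
    if not grid:
        raise ValueError("no feasible motif width for these sequences")

    models: List[MotifModel] = []
    occurrences: List[MotifOccurrence] = []
    bg = _background(_encode(work))
    aa = np.array(list(AMINO_ACIDS))
    for motif_id in range(1, max_motifs + 1):
        best_model: Optional[MotifModel] = None
        best_occ: List[MotifOccurrence] = []
        for w in grid:
            model, occ = zoops_em(work, w, n_starts=n_starts,
                                  max_iter=max_iter,
                                  seed=seed * 1000 + motif_id * 10 + w % 10,
                                  background=bg)
            if (best_model is None or model.penalized_information
                    > best_model.penalized_information):
                best_model, best_occ = model, occ
        assert best_model is not None
        if best_model.relative_entropy_per_column < min_re_per_col:
            break
        best_model.motif_id = motif_id
        for o in best_occ:
            o.motif_id = motif_id
        models.append(best_model)
        occurrences.extend(best_occ)
        # mask found occurrences with background-sampled residues
        for o in best_occ:
            s = list(work[o.protein_id])
            repl = aa[rng.choice(20, size=best_model.width, p=bg)]
            s[o.start: o.start + best_model.width] = list(repl)
            work[o.protein_id] = "".join(s)
    return models, occurrences


def information_content(theta: np.ndarray,
                        background: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-column information content IC_j = log2(20) - H(theta_j) in bits."""
    theta = np.asarray(theta, dtype=float)
    if not np.allclose(theta.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("theta rows must sum to 1")
    t = np.where(theta > 0, theta, 1.0)
    H = -(theta * np.log2(t)).sum(axis=1)
    return np.log2(20.0) - H


def letter_heights(theta: np.ndarray,
                   background: Optional[np.ndarray] = None) -> np.ndarray:
    """Logo stack heights: frequency x column IC; columns sum to the IC."""
    ic = information_content(theta, background)
    return np.asarray(theta) * ic[:, None]


def consensus(theta: np.ndarray) -> str:
    return "".join(AMINO_ACIDS[i] for i in np.asarray(theta).argmax(axis=1))


def logo_svg(theta: np.ndarray, path: str) -> None:
    """Small sequence-logo rendering (letters scaled by frequency x IC)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    matplotlib.rcParams["svg.hashsalt"] = "famcensus"  # reproducible SVG ids

    heights = letter_heights(theta)
    W = heights.shape[0]
    fig, ax = plt.subplots(figsize=(max(2.0, W * 0.28), 2.2))
    for j in range(W):
        order = np.argsort(heights[j])
        y = 0.0
        for k in order:
            h = heights[j, k]
            if h < 0.01:
                continue
            ax.text(j + 0.5, y + h / 2, AMINO_ACIDS[k], ha="center",
                    va="center", fontsize=9, stretch="condensed",
                    transform=ax.transData)
            y += h
    ax.set_xlim(0, W)
    ax.set_ylim(0, np.log2(20))
    ax.set_ylabel("bits")
    ax.set_xticks(np.arange(W) + 0.5,
                  [str(j + 1) for j in range(W)], fontsize=6)
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def architecture_strings(occurrences: Sequence[MotifOccurrence]
                         ) -> Dict[str, str]:
    """Per-protein ordered motif-id string, e.g. "3-4-1-2"."""
    per: Dict[str, List[Tuple[int, int]]] = {}
    for o in occurrences:
        per.setdefault(o.protein_id, []).append((o.start, o.motif_id))
    return {pid: "-".join(str(m) for _, m in sorted(v))
            for pid, v in per.items()}


def architecture_conservation(architectures: Mapping[str, str],
                              group_map: Mapping[str, str]
                              ) -> Dict[str, Tuple[str, float, int]]:
    """Per group: (modal architecture string, conserved fraction, n members)."""
    import warnings
    groups: Dict[str, List[str]] = {}
    for pid, grp in group_map.items():
        groups.setdefault(grp, []).append(architectures.get(pid, ""))
    out: Dict[str, Tuple[str, float, int]] = {}
    for grp, archs in sorted(groups.items()):
        archs = [a for a in archs]
        if not archs:
            warnings.warn(f"group {grp} is empty; skipped")
            continue
        tally: Dict[str, int] = {}
        for a in archs:
            tally[a] = tally.get(a, 0) + 1
        modal = sorted(tally, key=lambda a: (-tally[a], a))[0]
        out[grp] = (modal, tally[modal] / len(archs), len(archs))
    return out


def meme_minimal_text(models: Sequence[MotifModel]) -> str:
    """MEME minimal motif format (letter-probability matrices)."""
    lines = ["MEME version 4", "", f"ALPHABET= {AMINO_ACIDS}", ""]
    if models:
        bg = models[0].background
        lines += ["Background letter frequencies",
                  " ".join(f"{a} {f:.5f}" for a, f in zip(AMINO_ACIDS, bg)), ""]
    for m in models:
        lines.append(f"MOTIF m{m.motif_id}")
        lines.append(f"letter-probability matrix: alength= 20 w= {m.width} "
                     f"nsites= 1 E= 0")
        for row in m.theta:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
    return "\n".join(lines) + "\n"
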