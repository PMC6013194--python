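"""Physicochemical profiling: molecular weight, theoretical pI, GRAVY and the
Guruprasad instability index, following the ProtParam conventions (average
residue masses, Kyte-Doolittle hydropathy, DIWV dipeptide weights, proteins
with an instability index above 40 called unstable)."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from Bio.Data.IUPACData import protein_weights as _AVG_AA_WEIGHTS
from Bio.SeqUtils.ProtParamData import DIWV as _DIWV
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

from .synthetic_data import AMINO_ACIDS

__all__ = [
    "PhysChemProfile",
    "PKaSet",
    "EMBOSS_PKA",
    "EXPASY_PKA",
    "molecular_weight",
    "isoelectric_point",
    "gravy",
    "instability_index",
    "profile_protein",
    "profile_proteome",
    "summary",
]

WATER = 18.01524  # average mass of one water molecule, Da

# Average residue masses (residue = amino acid minus water).
RESIDUE_MASS = {a: _AVG_AA_WEIGHTS[a] - WATER for a in AMINO_ACIDS}


@dataclass(frozen=True)
class PKaSet:
    """Ionizable-group pKa values; positive groups gain, negative lose a proton."""
    name: str
    positive: Mapping[str, float]   # includes "Nterm"
    negative: Mapping[str, float]   # includes "Cterm"


# EMBOSS iep defaults.
EMBOSS_PKA = PKaSet(
    name="EMBOSS",
    positive={"Nterm": 8.6, "K": 10.8, "R": 12.5, "H": 6.5},
    negative={"Cterm": 3.6, "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
)

# Bjellqvist-style values as used by the ExPASy ProtParam service.
EXPASY_PKA = PKaSet(
    name="ExPASy",
    positive={"Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98},
    negative={"Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
)


@dataclass
class PhysChemProfile:
    protein_id: str
    length: int
    molecular_weight: float
    pI: float
    gravy: float
    instability_index: float
    unstable: bool


class NonStandardResidueError(ValueError):
    pass


def _clean(seq: str, tolerate_nonstandard: bool) -> str:
    bad = [c for c in seq if c not in RESIDUE_MASS]
    if not bad:
        return seq
    if tolerate_nonstandard:
        warnings.warn(f"skipping {len(bad)} non-standard residue(s): "
                      f"{sorted(set(bad))}")
        return "".join(c for c in seq if c in RESIDUE_MASS)
    raise NonStandardResidueError(
        f"non-standard residues {sorted(set(bad))}; pass "
        f"tolerate_nonstandard=True to skip them")


def molecular_weight(seq: str, tolerate_nonstandard: bool = False) -> float:
    """Sum of average residue masses plus one water, in daltons."""
    seq = _clean(seq, tolerate_nonstandard)
    if not seq:
        raise ValueError("empty sequence")
    return sum(RESIDUE_MASS[a] for a in seq) + WATER


def _net_charge(seq: str, pH: float, pka: PKaSet) -> float:
    counts: Dict[str, int] = {}
    for a in seq:
        counts[a] = counts.get(a, 0) + 1
    pos = sum(n / (1.0 + 10.0 ** (pH - pka.positive[g]))
              for g, n in [("Nterm", 1)] +
              [(a, counts.get(a, 0)) for a in ("K", "R", "H")])
    neg = sum(n / (1.0 + 10.0 ** (pka.negative[g] - pH))
              for g, n in [("Cterm", 1)] +
              [(a, counts.get(a, 0)) for a in ("D", "E", "C", "Y")])
    return pos - neg


def isoelectric_point(seq: str, pka_table: PKaSet = EXPASY_PKA,
                      tolerate_nonstandard: bool = False,
                      tol: float = 1e-4) -> float:
    """pH at which the modelled net charge is zero, by bisection on [0, 14].

    The net charge is strictly decreasing in pH, so the root is unique.
    """
    seq = _clean(seq, tolerate_nonstandard)
    if not seq:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    # converge on the interval, not on the charge: near the root the charge
    # curve can be flat enough that a |charge| stop leaves the pH off by
    # several hundredths while the charge criterion is already met
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if _net_charge(seq, mid, pka_table) > 0:
            lo = mid
        else:
            hi = mid
    mid = 0.5 * (lo + hi)
    assert abs(_net_charge(seq, mid, pka_table)) < tol
    return mid


def gravy(seq: str, tolerate_nonstandard: bool = False) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    seq = _clean(seq, tolerate_nonstandard)
    if not seq:
        raise ValueError("empty sequence")
    return sum(_KYTE_DOOLITTLE[a] for a in seq) / len(seq)


def instability_index(seq: str, tolerate_nonstandard: bool = False) -> float:
    """Guruprasad dipeptide statistic: II = (10/L) * sum of DIWV weights over
    the L-1 dipeptides; values above 40 conventionally mean unstable."""
    seq = _clean(seq, tolerate_nonstandard)
    if len(seq) < 2:
        raise ValueError("need at least 2 residues")
    total = sum(_DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def dipeptide_weight(x: str, y: str) -> float:
    """DIWV weight of the dipeptide x followed by y."""
    return _DIWV[x][y]


def profile_protein(protein_id: str, seq: str, pka_table: PKaSet = EXPASY_PKA,
                    tolerate_nonstandard: bool = False) -> PhysChemProfile:
    ii = instability_index(seq, tolerate_nonstandard)
    return PhysChemProfile(
        protein_id=protein_id,
        length=len(seq),
        molecular_weight=molecular_weight(seq, tolerate_nonstandard),
        pI=isoelectric_point(seq, pka_table, tolerate_nonstandard),
        gravy=gravy(seq, tolerate_nonstandard),
        instability_index=ii,
        unstable=ii > 40.0,
    )


def profile_proteome(proteins: Mapping[str, str],
                     pka_table: PKaSet = EXPASY_PKA,
                     tolerate_nonstandard: bool = False
                     ) -> Dict[str, PhysChemProfile]:
    return {pid: profile_protein(pid, proteins[pid], pka_table,
                                 tolerate_nonstandard)
            for pid in sorted(proteins)}


def summary(profiles: Iterable[PhysChemProfile]) -> Dict[str, Dict[str, float]]:
    """min/mean/max per measure over a proteome (exact arithmetic)."""
    profiles = list(profiles)
    out: Dict[str, Dict[str, float]] = {}
    for measure in ("molecular_weight", "pI", "gravy", "instability_index"):
        vals = np.array([getattr(p, measure) for p in profiles], dtype=float)
        out[measure] = {"min": float(vals.min()), "mean": float(vals.mean()),
                        "max": float(vals.max())}
    return out


def profiles_table(profiles: Mapping[str, PhysChemProfile]) -> str:
    lines = ["id\tlength\tMW_Da\tpI\tGRAVY\tinstability_index\tstability"]
    for pid in sorted(profiles):
        p = profiles[pid]
        lines.append(f"{pid}\t{p.length}\t{p.molecular_weight:.2f}\t"
                     f"{p.pI:.2f}\t{p.gravy:.3f}\t{p.instability_index:.2f}\t"
                     f"{'unstable' if p.unstable else 'stable'}")
    return "\n".join(lines) + "\n"
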