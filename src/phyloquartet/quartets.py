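"""Four-point arithmetic on distance matrices: splits diagrams and the
quartet score.

For four taxa ``i, j, k, l`` with reference pairing ``ij|kl`` and a distance
matrix ``D``, the three pair sums are

    s1 = D(i,j) + D(k,l)      (the reference pairing)
    s2 = D(i,k) + D(j,l)
    s3 = D(i,l) + D(j,k)

Split decomposition draws these as a box ("splits diagram") with sides

    e = (s3 - s2) / 2         f = (min(s2, s3) - s1) / 2

``f`` is the isolation index of the reference split — its support in the
quartet's split decomposition — and equals the internal-edge length when
``D`` is a perfect tree metric, in which case ``e = 0`` and the box
degenerates to a line.  The diagram label says which two splits the metric
supports: ``S`` (reference supported, e >= 0), ``S'`` (reference supported
with the opposite skew, e' = -e > 0), or ``S''`` (the reference pairing has
the strictly largest pair sum and cannot be recovered by shrinking either
box side).

A quartet counts as *correct* when its diagram is S or S' and the reference
split strictly dominates the conflicting signal, ``|e| < f``.  The quartet
score of a distance matrix against a reference tree is the fraction of the
tree's quartets that are correct; an additive metric of the tree itself
scores exactly 1, an all-zero (collapsed) matrix scores 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterator, NamedTuple, Union

import numpy as np
import pandas as pd

__all__ = [
    "Diagram",
    "QuartetSplit",
    "QuartetTable",
    "QuartetGeometry",
    "quartet_edges",
    "classify_diagram",
    "quartet_score",
    "quartet_report",
]


class Diagram(str, Enum):
    S = "S"
    S_PRIME = "S'"
    S_DOUBLE_PRIME = "S''"


class QuartetSplit(NamedTuple):
    """Canonical quartet split ij|kl with i<j, k<l, i<k."""

    i: int
    j: int
    k: int
    l: int  # noqa: E741


@dataclass(frozen=True)
class QuartetTable:
    """The quartet splits of a reference tree, one row per 4-subset.

    ``ijkl`` is an (m, 4) integer array of canonical splits ij|kl.
    """

    ijkl: np.ndarray
    n_taxa: int

    def __post_init__(self):
        a = np.asarray(self.ijkl, dtype=np.int64).reshape(-1, 4)
        object.__setattr__(self, "ijkl", a)
        if len(a):
            i, j, k, l = a.T
            ok = (i < j) & (k < l) & (i < k)
            if not ok.all():
                raise ValueError("quartet splits must be canonical (i<j, k<l, i<k)")
            if a.max() >= self.n_taxa or a.min() < 0:
                raise ValueError("taxon index out of range")

    def __len__(self) -> int:
        return len(self.ijkl)

    def __iter__(self) -> Iterator[QuartetSplit]:
        for row in self.ijkl:
            yield QuartetSplit(*map(int, row))


@dataclass(frozen=True)
class QuartetGeometry:
    """Splits-diagram geometry of one quartet under one distance matrix."""

    split: QuartetSplit
    s1: float
    s2: float
    s3: float
    e: float
    f: float
    diagram: Diagram
    correct: bool


def _values(D) -> np.ndarray:
    return D.values if hasattr(D, "values") else np.asarray(D, dtype=float)


def _pair_sums(V: np.ndarray, ijkl: np.ndarray):
    i, j, k, l = ijkl.T
    s1 = V[i, j] + V[k, l]
    s2 = V[i, k] + V[j, l]
    s3 = V[i, l] + V[j, k]
    return s1, s2, s3


def _classify(s1, s2, s3) -> np.ndarray:
    """Vectorized diagram labels; ties resolved toward S over S', S/S' over S''."""
    s1, s2, s3 = np.atleast_1d(s1, s2, s3)
    out = np.empty(s1.shape, dtype=object)
    unrecoverable = s1 > np.minimum(s2, s3)
    out[unrecoverable] = Diagram.S_DOUBLE_PRIME
    out[~unrecoverable & (s2 <= s3)] = Diagram.S
    out[~unrecoverable & (s3 < s2)] = Diagram.S_PRIME
    return out


def classify_diagram(g: QuartetGeometry) -> Diagram:
    """Diagram label of a quartet geometry (S, S' or S'')."""
    return _classify(g.s1, g.s2, g.s3)[0]


def quartet_edges(D, split: QuartetSplit) -> QuartetGeometry:
    """Splits-diagram sides e and f of one quartet, via the closed form
    ``e = (D(i,l) + D(j,k) - D(i,k) - D(j,l)) / 2``.
    """
    V = _values(D)
    row = np.asarray([split], dtype=np.int64)
    s1, s2, s3 = (float(x[0]) for x in _pair_sums(V, row))
    e = 0.5 * (s3 - s2)
    f = 0.5 * (min(s2, s3) - s1)
    diagram = _classify(s1, s2, s3)[0]
    correct = diagram is not Diagram.S_DOUBLE_PRIME and abs(e) < f
    return QuartetGeometry(QuartetSplit(*split), s1, s2, s3, e, f, diagram, correct)


def _correct_mask(V: np.ndarray, table: QuartetTable) -> np.ndarray:
    s1, s2, s3 = _pair_sums(V, table.ijkl)
    e = 0.5 * (s3 - s2)
    f = 0.5 * (np.minimum(s2, s3) - s1)
    # s1 <= min(s2,s3) excludes S''; |e| < f is the strict dominance rule.
    # Comparisons are exact on purpose: near collapse an epsilon would
    # silently inflate the score.
    return (s1 <= np.minimum(s2, s3)) & (np.abs(e) < f)


def quartet_score(D, table: QuartetTable) -> float:
    """Fraction of reference quartets in diagram S or S' with |e| < f."""
    if len(table) == 0:
        raise ValueError("empty quartet table")
    V = _values(D)
    if hasattr(D, "taxa") and D.taxa and len(D.taxa) != table.n_taxa:
        raise ValueError("distance matrix and quartet table disagree on n_taxa")
    return float(_correct_mask(V, table).mean())


def quartet_report(D, table: QuartetTable) -> pd.DataFrame:
    """Per-quartet TSV-ready report: indices, pair sums, e, f, diagram, correct."""
    V = _values(D)
    s1, s2, s3 = _pair_sums(V, table.ijkl)
    e = 0.5 * (s3 - s2)
    f = 0.5 * (np.minimum(s2, s3) - s1)
    diagram = [d.value for d in _classify(s1, s2, s3)]
    correct = _correct_mask(V, table)
    i, j, k, l = table.ijkl.T
    return pd.DataFrame(
        {
            "i": i,
            "j": j,
            "k": k,
            "l": l,
            "s1": s1,
            "s2": s2,
            "s3": s3,
            "e": e,
            "f": f,
            "diagram": diagram,
            "correct": correct,
        }
    )
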