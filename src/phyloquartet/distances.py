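"""Symmetric taxon-by-taxon distance matrices and their file formats.

The same container holds patristic distances from a reference tree and
Euclidean distances between latent feature vectors.  Writers cover relaxed
PHYLIP (square) and NEXUS with a DISTANCES block (triangle=both), the format
SplitsTree loads for NeighborNet drawing.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DistanceMatrix",
    "write_phylip",
    "read_phylip",
    "write_nexus",
]

_SYM_TOL = 1e-8


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distance matrix over an ordered taxon set."""

    values: np.ndarray
    taxa: tuple[str, ...] = field(default=())

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError(f"matrix must be square, got shape {v.shape}")
        if self.taxa and len(self.taxa) != v.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa for a {v.shape[0]}x{v.shape[0]} matrix"
            )
        if not np.allclose(v, v.T, atol=_SYM_TOL):
            raise ValueError("matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=_SYM_TOL):
            raise ValueError("diagonal must be zero")
        if v.min() < -_SYM_TOL:
            raise ValueError("distances must be nonnegative")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, key):
        return self.values[key]


def _sanitize_taxa(taxa) -> tuple[list[str], dict[str, str]]:
    """Replace characters unsafe for PHYLIP/NEXUS dialects; warn on changes."""
    clean, mapping, seen = [], {}, set()
    for label in taxa:
        safe = re.sub(r"[\s(),:;\[\]']+", "_", label)
        base = safe
        k = 1
        while safe in seen:
            k += 1
            safe = f"{base}_{k}"
        seen.add(safe)
        clean.append(safe)
        if safe != label:
            mapping[label] = safe
    if mapping:
        warnings.warn(
            f"taxon labels sanitized for export: {mapping}", stacklevel=3
        )
    return clean, mapping


def write_phylip(D: DistanceMatrix, path) -> dict[str, str]:
    """Write a relaxed square PHYLIP matrix; returns the sanitization map."""
    taxa, mapping = _sanitize_taxa(D.taxa or [f"T{i}" for i in range(D.n)])
    width = max(len(t) for t in taxa)
    with open(path, "w") as fh:
        fh.write(f"{D.n}\n")
        for i, t in enumerate(taxa):
            row = " ".join(f"{x:.6f}" for x in D.values[i])
            fh.write(f"{t:<{width}}  {row}\n")
    return mapping


def read_phylip(path) -> DistanceMatrix:
    """Read a relaxed square PHYLIP distance matrix."""
    with open(path) as fh:
        tokens = fh.read().split()
    n = int(tokens[0])
    taxa, rows = [], []
    pos = 1
    for _ in range(n):
        taxa.append(tokens[pos])
        rows.append([float(x) for x in tokens[pos + 1 : pos + 1 + n]])
        pos += 1 + n
    return DistanceMatrix(np.array(rows), tuple(taxa))


def write_nexus(D: DistanceMatrix, path) -> dict[str, str]:
    """Write a NEXUS file with TAXA and DISTANCES blocks (triangle=both).

    The layout follows what SplitsTree expects for NeighborNet drawing.
    """
    taxa, mapping = _sanitize_taxa(D.taxa or [f"T{i}" for i in range(D.n)])
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\n")
        fh.write("BEGIN TAXA;\n")
        fh.write(f"    DIMENSIONS NTAX={D.n};\n")
        fh.write("    TAXLABELS\n")
        for t in taxa:
            fh.write(f"        {t}\n")
        fh.write("    ;\nEND;\n\n")
        fh.write("BEGIN DISTANCES;\n")
        fh.write(f"    DIMENSIONS NTAX={D.n};\n")
        fh.write("    FORMAT TRIANGLE=BOTH DIAGONAL LABELS;\n")
        fh.write("    MATRIX\n")
        width = max(len(t) for t in taxa)
        for i, t in enumerate(taxa):
            row = " ".join(f"{x:.6f}" for x in D.values[i])
            fh.write(f"        {t:<{width}}  {row}\n")
        fh.write("    ;\nEND;\n")
    return mapping
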