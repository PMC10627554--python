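"""Two-population joint site-frequency spectra.

A :class:`JointSFS` is an ``(n1+1) x (n2+1)`` matrix whose entry (i, j)
counts (or weights) loci with i alternate-allele copies in population 1 and
j in population 2.  The two monomorphic corners carry no information about
divergence and are always masked; folding maps each cell to its
minor-allele mirror, ``min((i, j), (n1-i, n2-j))`` by pooled count (ties
broken lexicographically), as appropriate for unpolarized SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


@dataclass
class JointSFS:
    data: np.ndarray            # (n1+1, n2+1) counts or weights
    pop_names: tuple[str, str] = ("pop1", "pop2")
    folded: bool = False
    mask: np.ndarray = field(default=None)  # True = excluded from likelihood

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("joint SFS must be a 2-D matrix")
        if (self.data < 0).any():
            raise ValueError("SFS entries must be non-negative")
        if self.mask is None:
            self.mask = np.zeros(self.data.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        # monomorphic corners are never informative
        self.mask[0, 0] = True
        self.mask[-1, -1] = True
        if self.folded:
            self.mask |= ~_folded_canonical(self.n1, self.n2)

    @property
    def n1(self) -> int:
        return self.data.shape[0] - 1

    @property
    def n2(self) -> int:
        return self.data.shape[1] - 1

    @property
    def included(self) -> np.ndarray:
        return ~self.mask

    def total(self) -> float:
        """Total weight over included entries (= polymorphic locus count)."""
        return float(self.data[self.included].sum())

    def fold(self) -> "JointSFS":
        """Fold onto pooled minor-allele classes; idempotent."""
        if self.folded:
            return self
        n1, n2 = self.n1, self.n2
        out = np.zeros_like(self.data)
        for i in range(n1 + 1):
            for j in range(n2 + 1):
                fi, fj = fold_cell(i, j, n1, n2)
                out[fi, fj] += self.data[i, j]
        return JointSFS(out, self.pop_names, folded=True)

    def normalized(self) -> np.ndarray:
        """Probability over included entries (masked cells -> 0)."""
        p = np.where(self.included, self.data, 0.0)
        s = p.sum()
        if s <= 0:
            raise ValueError("joint SFS has no included mass")
        return p / s

    # -- text serialization (dadi/fastsimcoal-style single matrix) ---------

    def write(self, path) -> None:
        with open(Path(path), "w") as fh:
            fh.write(f"{self.n1 + 1} {self.n2 + 1} "
                     f"{'folded' if self.folded else 'unfolded'} "
                     f"{self.pop_names[0]} {self.pop_names[1]}\n")
            for row in self.data:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")

    @classmethod
    def read(cls, path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().split()
            d1, d2 = int(header[0]), int(header[1])
            folded = header[2] == "folded"
            names = tuple(header[3:5]) if len(header) >= 5 else ("pop1",
                                                                 "pop2")
            data = np.loadtxt(fh, ndmin=2)
        if data.shape != (d1, d2):
            raise ValueError("SFS matrix does not match its header")
        return cls(data, names, folded=folded)


def fold_cell(i: int, j: int, n1: int, n2: int) -> tuple[int, int]:
    """Canonical folded representative of cell (i, j)."""
    mi, mj = n1 - i, n2 - j
    if (i + j, i, j) <= (mi + mj, mi, mj):
        return i, j
    return mi, mj


def _folded_canonical(n1: int, n2: int) -> np.ndarray:
    keep = np.zeros((n1 + 1, n2 + 1), dtype=bool)
    for i in range(n1 + 1):
        for j in range(n2 + 1):
            keep[i, j] = fold_cell(i, j, n1, n2) == (i, j)
    return keep
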