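"""Summary statistics for ABC over unlinked biallelic SNP panels.

The fixed summary vector (layout version 1) concatenates, in canonical
population order:

* per population — proportion of monomorphic loci, mean unbiased expected
  heterozygosity (gene diversity) over loci;
* per unordered population pair — multi-locus Weir–Cockerham FST
  (ratio of summed variance components) and Nei's (1972) standard genetic
  distance.

For a 5-population design this gives 5*2 + C(5,2)*2 = 30 summaries.
Undefined components (e.g. Nei distance with zero joint identity, FST with
no polymorphism in a pair) are imputed to 0 and flagged so reference tables
stay rectangular.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeSnpMatrix

logger = logging.getLogger(__name__)

LAYOUT_VERSION = 1

__all__ = [
    "SummaryVector",
    "expected_heterozygosity",
    "pairwise_fst",
    "nei_distance",
    "compute_summary_vector",
    "summary_names",
]


@dataclass
class SummaryVector:
    """Fixed-order named summary statistics of one SNP dataset."""

    names: list[str]
    values: np.ndarray
    layout_version: int = LAYOUT_VERSION
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.shape[0]:
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _pop_counts(matrix: GenotypeSnpMatrix, pop: str):
    """(alt copies, called copies, het individuals) per locus for one pop."""
    cols = matrix.columns_for(pop)
    g = matrix.genotypes[:, cols]
    called = (g >= 0)
    n = 2 * called.sum(axis=1)
    alt = np.where(called, g, 0).sum(axis=1)
    het = (g == 1).sum(axis=1)
    return alt.astype(float), n.astype(float), het.astype(float)


def expected_heterozygosity(alt: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Per-locus unbiased gene diversity h = n/(n-1) * (1 - sum p^2).

    ``alt``/``n`` are alternate and total gene-copy counts; loci with fewer
    than two called copies are returned as NaN (undefined denominator).
    """
    alt = np.asarray(alt, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = alt / n
        h = (n / (n - 1.0)) * 2.0 * p * (1.0 - p)
    return np.where(n >= 2, h, np.nan)


def _wc_components(a1, n1, h1, a2, n2, h2):
    """Two-population Weir–Cockerham (1984) variance components per locus.

    Inputs are per-locus alt-copy counts, copy totals and heterozygote
    counts; sample sizes below are in diploid individuals.  Returns
    (a, b, c) arrays; loci with a population entirely missing give NaN.
    """
    r = 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ni = np.stack([n1 / 2.0, n2 / 2.0])          # diploid sample sizes
        pi = np.stack([a1 / n1, a2 / n2])
        hi = np.stack([h1 / (n1 / 2.0), h2 / (n2 / 2.0)])
        nbar = ni.mean(axis=0)
        nc = (r * nbar - (ni**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (ni * pi).sum(axis=0) / (r * nbar)
        s2 = (ni * (pi - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (ni * hi).sum(axis=0) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    return a, b, c


def pairwise_fst(matrix: GenotypeSnpMatrix, pop_a: str, pop_b: str) -> float:
    """Multi-locus Weir–Cockerham theta: sum(a) / sum(a + b + c) over loci.

    Returns 0 (with a warning) when every locus is monomorphic in the pair.
    """
    a1, n1, h1 = _pop_counts(matrix, pop_a)
    a2, n2, h2 = _pop_counts(matrix, pop_b)
    a, b, c = _wc_components(a1, n1, h1, a2, n2, h2)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        warnings.warn(
            f"all loci monomorphic in pair ({pop_a}, {pop_b}); FST set to 0",
            stacklevel=2,
        )
        return 0.0
    return float(a[ok].sum() / denom)


def nei_distance(matrix: GenotypeSnpMatrix, pop_a: str, pop_b: str) -> float:
    """Nei (1972) standard genetic distance D = -ln(Jxy / sqrt(Jx * Jy)).

    J terms are means over loci of allele-frequency products.  A zero joint
    identity yields +inf (flagged by the caller).
    """
    aa, na, _ = _pop_counts(matrix, pop_a)
    ab, nb, _ = _pop_counts(matrix, pop_b)
    ok = (na >= 1) & (nb >= 1)
    pa, pb = aa[ok] / na[ok], ab[ok] / nb[ok]
    jx = np.mean(pa**2 + (1 - pa) ** 2)
    jy = np.mean(pb**2 + (1 - pb) ** 2)
    jxy = np.mean(pa * pb + (1 - pa) * (1 - pb))
    if jxy <= 0:
        return float("inf")
    return float(-np.log(jxy / np.sqrt(jx * jy)))


def summary_names(pop_names: list[str]) -> list[str]:
    names = []
    for p in pop_names:
        names += [f"pmono_{p}", f"het_{p}"]
    for a, b in itertools.combinations(pop_names, 2):
        names += [f"fst_{a}_{b}", f"neiD_{a}_{b}"]
    return names


def compute_summary_vector(matrix: GenotypeSnpMatrix,
                           pop_names: list[str] | None = None
                           ) -> SummaryVector:
    """Compute the full fixed-layout summary vector of one dataset.

    Population order defaults to first appearance in the matrix; pass
    ``pop_names`` to pin the canonical order across datasets.  Undefined
    components are imputed to 0 and listed in ``flags``.
    """
    if matrix.n_loci == 0:
        raise ValueError("empty genotype matrix")
    pops = pop_names or matrix.population_names
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    values: list[float] = []
    flags: list[str] = []
    per_pop = {p: _pop_counts(matrix, p) for p in pops}
    for p in pops:
        alt, n, _ = per_pop[p]
        ok = n >= 2
        if not ok.any():
            values += [0.0, 0.0]
            flags.append(f"pop {p}: no loci with >=2 called copies")
            continue
        mono = ((alt[ok] == 0) | (alt[ok] == n[ok])).mean()
        h = expected_heterozygosity(alt[ok], n[ok])
        values += [float(mono), float(np.nanmean(h))]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for a, b in itertools.combinations(pops, 2):
            fst = pairwise_fst(matrix, a, b)
            d = nei_distance(matrix, a, b)
            if not np.isfinite(d):
                flags.append(f"pair ({a},{b}): infinite Nei distance")
                d = 0.0
            values += [fst, d]
    for f in flags:
        logger.debug("summary imputation: %s", f)
    return SummaryVector(summary_names(pops), np.array(values), flags=flags)
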