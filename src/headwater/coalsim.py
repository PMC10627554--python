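"""Backward-in-time coalescent simulation of unlinked SNP loci.

Genealogies follow the standard continuous-time coalescent with
piecewise-constant diploid population sizes and instantaneous population
merges: within an epoch, j lineages in a population of size N coalesce at
rate j(j-1)/(4N) per generation; at a merge event every lineage of the
source population moves to the destination.

Each locus carries exactly one mutation, placed uniformly along the total
branch length, so every simulated locus is polymorphic in the pooled sample
— the natural model for a panel of unlinked GBS SNPs, and one that leaves
the mutation rate out of the scenario-choice path entirely.  Because
observing a SNP is more likely on a longer genealogy, dataset simulation
weights genealogies by total branch length (low-mutation-rate
conditioning), which reproduces the classical SFS expectations such as the
1/i unfolded shape; see :func:`headwater._kernels.simulate_snp_batch`.

Two code paths produce identical statistics: a readable pure-Python path
(:func:`simulate_genealogy`, :func:`place_single_mutation`) for API-level
use and small-scale verification, and numba batch kernels
(:func:`simulate_snp_dataset`, :func:`expected_joint_sfs`) for the
reference-table and likelihood workloads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .demography import (
    CompiledDemography,
    ParameterDraw,
    ScenarioModel,
    compile_demography,
)
from .genotypes import GenotypeSnpMatrix
from .sfs import JointSFS

__all__ = [
    "Genealogy",
    "simulate_genealogy",
    "place_single_mutation",
    "simulate_snp_dataset",
    "expected_joint_sfs",
    "sample_joint_sfs",
    "kernel_seed",
]

_SEED_MOD = 2**31 - 1


def kernel_seed(seed: int | np.random.Generator) -> int:
    """Derive a 31-bit kernel seed from an integer seed or a Generator."""
    if isinstance(seed, np.random.Generator):
        return int(seed.integers(_SEED_MOD))
    return int(np.random.SeedSequence(seed).generate_state(1)[0] % _SEED_MOD)


def _as_compiled(model, draw=None) -> CompiledDemography:
    if isinstance(model, CompiledDemography):
        return model
    if isinstance(model, ScenarioModel):
        if not isinstance(draw, ParameterDraw):
            raise TypeError("a ScenarioModel needs a ParameterDraw")
        return compile_demography(model, draw)
    raise TypeError(f"cannot interpret {type(model).__name__} as a demography")


@dataclass
class Genealogy:
    """One coalescent tree over the sampled gene copies.

    Nodes ``0..n-1`` are tips at time 0; internal nodes are numbered in
    coalescence order, so a parent always has a larger id than its children.
    """

    node_time: np.ndarray
    parent: np.ndarray
    left: np.ndarray
    right: np.ndarray
    root: int
    sample_pops: np.ndarray       # population index per tip
    pop_names: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return self.sample_pops.shape[0]

    @property
    def tmrca(self) -> float:
        return float(self.node_time[self.root])

    def branch_lengths(self) -> np.ndarray:
        """Length of the branch above each node (0 for the root)."""
        out = np.zeros_like(self.node_time)
        for v in range(self.node_time.shape[0]):
            if v != self.root:
                out[v] = self.node_time[self.parent[v]] - self.node_time[v]
        return out

    @property
    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def tip_info(self, tip: int) -> tuple[str, int, int]:
        """(population, diploid individual, chromosome copy) of a tip."""
        return (self.pop_names[self.sample_pops[tip]], tip // 2, tip % 2)

    def leaves_below(self, node: int) -> np.ndarray:
        mark = np.zeros(self.n_leaves, dtype=bool)
        stack = [node]
        while stack:
            v = stack.pop()
            if v < self.n_leaves:
                mark[v] = True
            else:
                stack.append(int(self.left[v]))
                stack.append(int(self.right[v]))
        return mark


def simulate_genealogy(model, draw=None, seed=0) -> Genealogy:
    """Simulate one genealogy under a scenario instantiation.

    ``model`` may be a :class:`ScenarioModel` (with ``draw``) or an
    already-compiled :class:`CompiledDemography`.
    """
    dem = _as_compiled(model, draw)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sample_pops = np.repeat(
        np.arange(dem.sample_copies.shape[0]), dem.sample_copies
    )
    n = sample_pops.shape[0]
    if n < 2:
        raise ValueError("need at least two sampled gene copies")
    tot = 2 * n - 1
    node_time = np.zeros(tot)
    parent = np.full(tot, -1, dtype=np.int64)
    left = np.full(tot, -1, dtype=np.int64)
    right = np.full(tot, -1, dtype=np.int64)

    sizes = dem.init_sizes.copy()
    act = list(range(n))
    act_pop = list(sample_pops)
    t = 0.0
    iev = 0
    next_id = n
    while len(act) > 1:
        npop = sizes.shape[0]
        counts = np.bincount(act_pop, minlength=npop)
        rates = counts * (counts - 1) / (4.0 * sizes)
        total = rates.sum()
        w = rng.exponential(1.0 / total) if total > 0 else np.inf
        if iev < dem.event_times.shape[0] and t + w >= dem.event_times[iev]:
            t = dem.event_times[iev]
            if dem.event_kinds[iev] == 0:
                sizes[dem.event_pop_a[iev]] = dem.event_sizes[iev]
            else:
                a, b = dem.event_pop_a[iev], dem.event_pop_b[iev]
                act_pop = [b if p == a else p for p in act_pop]
            iev += 1
            continue
        t += w
        p = int(rng.choice(npop, p=rates / total))
        slots = [i for i, q in enumerate(act_pop) if q == p]
        s1, s2 = rng.choice(len(slots), size=2, replace=False)
        s1, s2 = slots[s1], slots[s2]
        c1, c2 = act[s1], act[s2]
        node_time[next_id] = t
        left[next_id], right[next_id] = c1, c2
        parent[c1] = parent[c2] = next_id
        act[s1] = next_id
        del act[s2]
        del act_pop[s2]
        next_id += 1
    return Genealogy(node_time, parent, left, right, root=next_id - 1,
                     sample_pops=sample_pops, pop_names=dem.pop_names)


def place_single_mutation(g: Genealogy, seed=0) -> np.ndarray:
    """Place one mutation uniformly along the genealogy's branches.

    Returns the diploid genotype column (alternate-allele counts 0/1/2 per
    individual, gene copies 2k and 2k+1 belonging to individual k).
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lens = g.branch_lengths()
    total = lens.sum()
    if total <= 0:
        raise ValueError("genealogy has zero total branch length")
    u = rng.uniform(0, total)
    node = int(np.searchsorted(np.cumsum(lens), u))
    derived = g.leaves_below(node)
    return derived.astype(np.int8).reshape(-1, 2).sum(axis=1)


def simulate_snp_dataset(model, draw=None, n_loci: int = 1000,
                         seed=0) -> GenotypeSnpMatrix:
    """Simulate ``n_loci`` unlinked polymorphic SNP loci and return the
    diploid genotype matrix (genealogies length-weighted, one uniformly
    placed mutation per locus)."""
    if n_loci < 1:
        raise ValueError("n_loci must be >= 1")
    dem = _as_compiled(model, draw)
    sample_pops = np.repeat(
        np.arange(dem.sample_copies.shape[0]), dem.sample_copies
    )
    geno = _kernels.simulate_snp_batch(
        sample_pops, dem.init_sizes, dem.event_times, dem.event_kinds,
        dem.event_pop_a, dem.event_pop_b, dem.event_sizes,
        int(n_loci), kernel_seed(seed),
    )
    samples, populations = [], []
    counter: dict[str, int] = {}
    for p in sample_pops.reshape(-1, 2)[:, 0]:
        name = dem.pop_names[p]
        counter[name] = counter.get(name, 0) + 1
        samples.append(f"{name}_{counter[name]:02d}")
        populations.append(name)
    return GenotypeSnpMatrix(geno, samples, populations)


def expected_joint_sfs(model, draw=None, n_sims: int = 10_000, seed=0,
                       fold: bool = False) -> JointSFS:
    """Monte-Carlo expected joint SFS of a polymorphic SNP locus for a
    two-population demography.

    Entry (i, j) is proportional to the mean branch length subtending
    exactly i copies in population 1 and j in population 2, normalized over
    polymorphic entries; the monomorphic corners are masked.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    dem = _as_compiled(model, draw)
    if dem.sample_copies.shape[0] != 2:
        raise ValueError("expected_joint_sfs needs exactly 2 populations")
    n1, n2 = int(dem.sample_copies[0]), int(dem.sample_copies[1])
    sample_pops = np.repeat(np.arange(2), dem.sample_copies)
    W = _kernels.expected_joint_sfs_branch(
        sample_pops, dem.init_sizes, dem.event_times, dem.event_kinds,
        dem.event_pop_a, dem.event_pop_b, dem.event_sizes,
        n1, n2, int(n_sims), kernel_seed(seed),
    )
    sfs = JointSFS(W, pop_names=(dem.pop_names[0], dem.pop_names[1]))
    if fold:
        sfs = sfs.fold()
    p = sfs.normalized()
    return JointSFS(p, sfs.pop_names, folded=sfs.folded)


def sample_joint_sfs(model, draw=None, n_loci: int = 5000,
                     n_sims: int = 20_000, seed=0,
                     fold: bool = True) -> JointSFS:
    """Draw a multinomial joint SFS of ``n_loci`` polymorphic loci from the
    expected locus distribution of a two-population demography."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    exp = expected_joint_sfs(model, draw, n_sims=n_sims,
                             seed=kernel_seed(rng), fold=fold)
    p = exp.normalized()
    counts = rng.multinomial(n_loci, p.ravel()).reshape(p.shape)
    return JointSFS(counts.astype(float), exp.pop_names, folded=exp.folded)
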