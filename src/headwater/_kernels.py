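"""Numba-compiled coalescent kernels.

These back the batch operations (SNP dataset simulation, expected joint SFS)
where per-locus Python overhead would dominate.  The readable reference
implementation of the same process lives in :mod:`headwater.coalsim`; tests
check the two agree and both match an independent simulator.

All kernels take a flat event encoding (see
:class:`headwater.demography.CompiledDemography`) and an explicit 32-bit
seed; they are single-threaded and bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _sim_tree(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b, ev_s,
              node_time, parent, left, right):
    """Simulate one coalescent genealogy in place.

    sample_pops : int64[n] population index of each sampled gene copy.
    Output arrays have length 2n-1; leaves are nodes 0..n-1 at time 0.
    Returns the root node id.
    """
    n = sample_pops.shape[0]
    npop = init_sizes.shape[0]
    sizes = init_sizes.copy()
    # active lineage node ids and their populations
    act = np.empty(n, dtype=np.int64)
    act_pop = np.empty(n, dtype=np.int64)
    for i in range(n):
        act[i] = i
        act_pop[i] = sample_pops[i]
        node_time[i] = 0.0
        parent[i] = -1
        left[i] = -1
        right[i] = -1
    n_act = n
    next_id = n
    t = 0.0
    iev = 0
    nev = ev_t.shape[0]
    counts = np.zeros(npop, dtype=np.int64)
    for i in range(n_act):
        counts[act_pop[i]] += 1
    rates = np.empty(npop, dtype=np.float64)
    while n_act > 1:
        total = 0.0
        for p in range(npop):
            k = counts[p]
            r = k * (k - 1) / (4.0 * sizes[p]) if k > 1 else 0.0
            rates[p] = r
            total += r
        if total > 0.0:
            w = np.random.exponential(1.0 / total)
        else:
            w = np.inf
        if iev < nev and t + w >= ev_t[iev]:
            t = ev_t[iev]
            if ev_k[iev] == 0:
                sizes[ev_a[iev]] = ev_s[iev]
            else:
                a = ev_a[iev]
                b = ev_b[iev]
                for i in range(n_act):
                    if act_pop[i] == a:
                        act_pop[i] = b
                counts[b] += counts[a]
                counts[a] = 0
            iev += 1
            continue
        t += w
        # choose population proportional to rate
        u = np.random.random() * total
        p = 0
        acc = rates[0]
        while acc < u and p < npop - 1:
            p += 1
            acc += rates[p]
        # choose an unordered pair of active lineages in population p
        k = counts[p]
        i1 = np.random.randint(k)
        i2 = np.random.randint(k - 1)
        if i2 >= i1:
            i2 += 1
        # map within-pop indices to active-slot indices
        seen = 0
        s1 = -1
        s2 = -1
        for i in range(n_act):
            if act_pop[i] == p:
                if seen == i1:
                    s1 = i
                if seen == i2:
                    s2 = i
                seen += 1
        c1 = act[s1]
        c2 = act[s2]
        node_time[next_id] = t
        parent[next_id] = -1
        left[next_id] = c1
        right[next_id] = c2
        parent[c1] = next_id
        parent[c2] = next_id
        act[s1] = next_id
        # remove slot s2 (swap with last)
        act[s2] = act[n_act - 1]
        act_pop[s2] = act_pop[n_act - 1]
        counts[p] -= 1
        n_act -= 1
        next_id += 1
    return next_id - 1


@njit(cache=True)
def _mark_descendants(node, left, right, n_leaves, out):
    """Set out[leaf] = 1 for every leaf below `node` (inclusive)."""
    stack = np.empty(2 * n_leaves, dtype=np.int64)
    top = 0
    stack[top] = node
    top += 1
    while top > 0:
        top -= 1
        v = stack[top]
        if v < n_leaves:
            out[v] = 1
        else:
            stack[top] = left[v]
            top += 1
            stack[top] = right[v]
            top += 1


@njit(cache=True, inline="always")
def _tree_seed(seed, i):
    return (seed + (i + 1) * 2654435761) & 0x7FFFFFFF


@njit(cache=True)
def simulate_snp_batch(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b, ev_s,
                       n_loci, seed):
    """Simulate `n_loci` unlinked polymorphic SNP loci.

    A SNP locus is a locus that happens to carry exactly one mutation; in
    the low-mutation-rate limit that conditioning weights genealogies by
    their total branch length.  The batch therefore simulates genealogies
    twice with per-tree seeds: a first pass records each tree's total
    length, loci are multinomially assigned to trees proportionally to
    length, and a second pass replays only the hit trees and drops each
    assigned mutation uniformly along the branches.  This reproduces the
    standard SFS expectations (e.g. the 1/i unfolded shape under
    panmixia) exactly rather than the slightly singleton-biased spectrum
    of per-tree conditioning.

    Returns genotypes (n_loci, n_individuals) int8 with codes 0/1/2 =
    copies of the derived allele; gene copies 2k and 2k+1 belong to
    individual k.  Every locus is polymorphic in the pooled sample by
    construction (mutations never land above the root).
    """
    n = sample_pops.shape[0]
    nind = n // 2
    tot = 2 * n - 1
    node_time = np.empty(tot, dtype=np.float64)
    parent = np.empty(tot, dtype=np.int64)
    left = np.empty(tot, dtype=np.int64)
    right = np.empty(tot, dtype=np.int64)
    derived = np.empty(n, dtype=np.int8)
    geno = np.empty((n_loci, nind), dtype=np.int8)
    # pass 1: total branch length of each candidate genealogy
    lengths = np.empty(n_loci, dtype=np.float64)
    for i in range(n_loci):
        np.random.seed(_tree_seed(seed, i))
        root = _sim_tree(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b,
                         ev_s, node_time, parent, left, right)
        total_len = 0.0
        for v in range(tot):
            if v != root:
                total_len += node_time[parent[v]] - node_time[v]
        lengths[i] = total_len
    # length-weighted multinomial assignment of loci to genealogies
    np.random.seed(seed)
    remaining = n_loci
    w_rest = lengths.sum()
    hits = np.zeros(n_loci, dtype=np.int64)
    for i in range(n_loci):
        if remaining == 0:
            break
        if w_rest <= lengths[i]:
            hits[i] = remaining
            remaining = 0
            break
        k = np.random.binomial(remaining, lengths[i] / w_rest)
        hits[i] = k
        remaining -= k
        w_rest -= lengths[i]
    # pass 2: replay hit genealogies, place the assigned mutations
    locus = 0
    for i in range(n_loci):
        if hits[i] == 0:
            continue
        np.random.seed(_tree_seed(seed, i))
        root = _sim_tree(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b,
                         ev_s, node_time, parent, left, right)
        for _ in range(hits[i]):
            u = np.random.random() * lengths[i]
            acc = 0.0
            hit = -1
            for v in range(tot):
                if v != root:
                    acc += node_time[parent[v]] - node_time[v]
                    if acc >= u:
                        hit = v
                        break
            if hit < 0:
                hit = root - 1 if root > 0 else 0
            for q in range(n):
                derived[q] = 0
            _mark_descendants(hit, left, right, n, derived)
            for kk in range(nind):
                geno[locus, kk] = derived[2 * kk] + derived[2 * kk + 1]
            locus += 1
    return geno


@njit(cache=True)
def expected_joint_sfs_branch(sample_pops, init_sizes, ev_t, ev_k, ev_a,
                              ev_b, ev_s, n1, n2, n_sims, seed):
    """Monte-Carlo expected unfolded joint SFS for a two-population sample.

    Entry (i, j) accumulates, over `n_sims` genealogies, the branch length
    subtending exactly i copies in population 0 and j in population 1; under
    the one-mutation-per-locus SNP model the normalized matrix is the
    expected distribution of a polymorphic locus over frequency classes.
    """
    np.random.seed(seed)
    n = sample_pops.shape[0]
    tot = 2 * n - 1
    node_time = np.empty(tot, dtype=np.float64)
    parent = np.empty(tot, dtype=np.int64)
    left = np.empty(tot, dtype=np.int64)
    right = np.empty(tot, dtype=np.int64)
    cnt1 = np.empty(tot, dtype=np.int64)
    cnt2 = np.empty(tot, dtype=np.int64)
    W = np.zeros((n1 + 1, n2 + 1), dtype=np.float64)
    for _ in range(n_sims):
        root = _sim_tree(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b,
                         ev_s, node_time, parent, left, right)
        for v in range(tot):
            if v < n:
                if sample_pops[v] == 0:
                    cnt1[v] = 1
                    cnt2[v] = 0
                else:
                    cnt1[v] = 0
                    cnt2[v] = 1
            else:
                cnt1[v] = cnt1[left[v]] + cnt1[right[v]]
                cnt2[v] = cnt2[left[v]] + cnt2[right[v]]
        for v in range(tot):
            if v != root:
                W[cnt1[v], cnt2[v]] += node_time[parent[v]] - node_time[v]
    return W


@njit(cache=True)
def tmrca_and_length_batch(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b,
                           ev_s, n_reps, seed):
    """(TMRCA, total branch length) over replicate genealogies."""
    np.random.seed(seed)
    n = sample_pops.shape[0]
    tot = 2 * n - 1
    node_time = np.empty(tot, dtype=np.float64)
    parent = np.empty(tot, dtype=np.int64)
    left = np.empty(tot, dtype=np.int64)
    right = np.empty(tot, dtype=np.int64)
    out = np.empty((n_reps, 2), dtype=np.float64)
    for r in range(n_reps):
        root = _sim_tree(sample_pops, init_sizes, ev_t, ev_k, ev_a, ev_b,
                         ev_s, node_time, parent, left, right)
        total_len = 0.0
        for v in range(tot):
            if v != root:
                total_len += node_time[parent[v]] - node_time[v]
        out[r, 0] = node_time[root]
        out[r, 1] = total_len
    return out
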