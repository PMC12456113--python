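"""Numba kernels for the structured-coalescent SNP simulator.

Everything here operates on flat arrays so the hot loop compiles; the
user-facing API (Scenario objects, GenotypeMatrix) lives in ``coalsim``.

Event encoding (rows sorted by time ascending, ties by original order):
    kind 0  divergence     all lineages of pop_a move to pop_b
    kind 1  pulse          each lineage of pop_a moves to pop_b w.p. param
    kind 2  admixture      each lineage of pop_a moves to pop_b w.p. param,
                           else to pop_c
    kind 3  ne_change      diploid Ne of pop_a set to param

Status codes returned by the tree kernel: 0 ok, 1 stranded lineages
(no common ancestor reachable), 2 zero total branch length at mutation.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_STRANDED = 1
STATUS_ZERO_LENGTH = 2
STATUS_MAF_EXHAUSTED = 3


@njit(cache=False)
def _seed_rng(seed):
    np.random.seed(seed)


@njit(cache=False)
def _simulate_tree(lineage_pop0, n_pops, ne0,
                   ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
                   parent, node_time, node_pop):
    """One coalescent genealogy under the encoded event schedule.

    ``lineage_pop0``: initial population index per leaf (leaves are nodes
    0..n-1).  Output arrays are sized 2n-1; returns (status, n_nodes).
    Uses numba's thread-local RNG — seed beforehand with ``_seed_rng``.
    """
    n = lineage_pop0.shape[0]
    n_nodes_max = 2 * n - 1
    for i in range(n_nodes_max):
        parent[i] = -1
        node_time[i] = 0.0
        node_pop[i] = -1

    ne = ne0.copy()
    # active lineage node ids and their populations
    active = np.empty(n, dtype=np.int64)
    active_pop = np.empty(n, dtype=np.int64)
    for i in range(n):
        active[i] = i
        active_pop[i] = lineage_pop0[i]
        node_pop[i] = lineage_pop0[i]
    n_active = n
    counts = np.zeros(n_pops, dtype=np.int64)
    for i in range(n):
        counts[lineage_pop0[i]] += 1

    t = 0.0
    next_node = n
    n_events = ev_time.shape[0]
    ev_i = 0
    while n_active > 1:
        # total coalescence rate under current sizes
        total_rate = 0.0
        for p in range(n_pops):
            k = counts[p]
            if k > 1:
                total_rate += k * (k - 1) / (4.0 * ne[p])
        t_event = ev_time[ev_i] if ev_i < n_events else np.inf
        if total_rate > 0.0:
            wait = np.random.exponential(1.0 / total_rate)
        else:
            wait = np.inf
        if t + wait < t_event:
            t = t + wait
            # choose population proportional to its rate
            u = np.random.random() * total_rate
            acc = 0.0
            pop = -1
            for p in range(n_pops):
                k = counts[p]
                if k > 1:
                    acc += k * (k - 1) / (4.0 * ne[p])
                    if u < acc:
                        pop = p
                        break
            if pop < 0:
                pop = n_pops - 1
            # choose an ordered random pair among lineages in pop
            k = counts[pop]
            i1 = np.random.randint(k)
            i2 = np.random.randint(k - 1)
            if i2 >= i1:
                i2 += 1
            # locate the i1-th and i2-th active lineages of pop
            a_idx = -1
            b_idx = -1
            seen = 0
            for j in range(n_active):
                if active_pop[j] == pop:
                    if seen == i1:
                        a_idx = j
                    if seen == i2:
                        b_idx = j
                    seen += 1
                    if a_idx >= 0 and b_idx >= 0:
                        break
            node = next_node
            next_node += 1
            node_time[node] = t
            node_pop[node] = pop
            parent[active[a_idx]] = node
            parent[active[b_idx]] = node
            # replace a with the new node, remove b (swap with last)
            active[a_idx] = node
            lo = b_idx
            active[lo] = active[n_active - 1]
            active_pop[lo] = active_pop[n_active - 1]
            n_active -= 1
            counts[pop] -= 1
        elif ev_i < n_events:
            t = t_event
            kind = ev_kind[ev_i]
            a = ev_a[ev_i]
            b = ev_b[ev_i]
            c = ev_c[ev_i]
            param = ev_param[ev_i]
            if kind == 0:  # divergence: all a -> b
                for j in range(n_active):
                    if active_pop[j] == a:
                        active_pop[j] = b
                counts[b] += counts[a]
                counts[a] = 0
            elif kind == 1:  # pulse: a -> b w.p. param
                for j in range(n_active):
                    if active_pop[j] == a and np.random.random() < param:
                        active_pop[j] = b
                        counts[a] -= 1
                        counts[b] += 1
            elif kind == 2:  # admixture: a -> b w.p. param else c
                for j in range(n_active):
                    if active_pop[j] == a:
                        if np.random.random() < param:
                            active_pop[j] = b
                            counts[b] += 1
                        else:
                            active_pop[j] = c
                            counts[c] += 1
                        counts[a] -= 1
            else:  # ne_change
                ne[a] = param
            ev_i += 1
        else:
            return STATUS_STRANDED, next_node
    return STATUS_OK, next_node


@njit(cache=False)
def _drop_mutation(parent, node_time, n_leaves, n_nodes, derived):
    """Place one mutation on a branch chosen proportional to its length.

    Marks ``derived[leaf]`` for leaves below the branch.  Placements deriving
    all leaves are impossible on a rooted binary genealogy (only the root has
    no branch), so every branch is admissible.
    """
    total = 0.0
    for i in range(n_nodes):
        if parent[i] >= 0:
            total += node_time[parent[i]] - node_time[i]
    if total <= 0.0:
        return STATUS_ZERO_LENGTH
    u = np.random.random() * total
    acc = 0.0
    chosen = -1
    for i in range(n_nodes):
        if parent[i] >= 0:
            acc += node_time[parent[i]] - node_time[i]
            if u < acc:
                chosen = i
                break
    if chosen < 0:
        chosen = n_nodes - 2
    # propagate derived state top-down (parent id always > child id)
    state = np.zeros(n_nodes, dtype=np.bool_)
    state[chosen] = True
    for i in range(n_nodes - 1, -1, -1):
        if parent[i] >= 0 and state[parent[i]]:
            state[i] = True
    for i in range(n_leaves):
        derived[i] = state[i]
    return STATUS_OK


@njit(cache=False)
def _simulate_dataset(lineage_pop0, n_pops, ne0,
                      ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
                      n_loci, maf, missing_rate, seed,
                      genotypes):
    """Simulate ``n_loci`` unlinked SNP loci into ``genotypes`` (n_ind x loci).

    Each locus: fresh genealogy, one conditioned mutation, per-genotype
    missingness (coded -1), pooled-sample MAF ascertainment by full redraw.
    """
    np.random.seed(seed)
    n_leaves = lineage_pop0.shape[0]
    n_ind = n_leaves // 2
    n_nodes_max = 2 * n_leaves - 1
    parent = np.empty(n_nodes_max, dtype=np.int64)
    node_time = np.empty(n_nodes_max, dtype=np.float64)
    node_pop = np.empty(n_nodes_max, dtype=np.int64)
    derived = np.zeros(n_leaves, dtype=np.bool_)
    locus = 0
    rejections = 0
    while locus < n_loci:
        status, n_nodes = _simulate_tree(
            lineage_pop0, n_pops, ne0,
            ev_time, ev_kind, ev_a, ev_b, ev_c, ev_param,
            parent, node_time, node_pop)
        if status != STATUS_OK:
            return status
        status = _drop_mutation(parent, node_time, n_leaves, n_nodes, derived)
        if status != STATUS_OK:
            return status
        # genotypes with missingness
        n_called = 0
        n_derived = 0
        for ind in range(n_ind):
            if missing_rate > 0.0 and np.random.random() < missing_rate:
                genotypes[ind, locus] = -1
            else:
                g = 0
                if derived[2 * ind]:
                    g += 1
                if derived[2 * ind + 1]:
                    g += 1
                genotypes[ind, locus] = g
                n_called += 2
                n_derived += g
        if n_called == 0:
            rejections += 1
            if rejections > 10_000:
                return STATUS_MAF_EXHAUSTED
            continue
        freq = n_derived / n_called
        minor = freq if freq <= 0.5 else 1.0 - freq
        if minor < maf:
            rejections += 1
            if rejections > 10_000:
                return STATUS_MAF_EXHAUSTED
            continue
        rejections = 0
        locus += 1
    return STATUS_OK
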