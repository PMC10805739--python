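"""Numba kernels for the structured coalescent.

All kernels operate on the flat-array form produced by
``DemographicModel.compile``.  Rates follow the standard structured
coalescent: within deme ``d`` holding ``k`` lineages, pairs coalesce at rate
``k (k-1) / (4 N_d)`` per generation; a lineage in recipient deme ``r``
migrates (backward in time) to source deme ``s`` at rate
``2Nm[s, r] / (2 N_r)``.

Per-replicate RNG streams are derived deterministically from the base seed
and the replicate index, so results are reproducible regardless of batching.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MASK31 = 0x7FFFFFFF


@njit(cache=False)
def _child_seed(base: np.int64, idx: np.int64) -> np.int64:
    # SplitMix-style mix, folded to 31 bits for np.random.seed.
    z = (base + np.int64(0x9E3779B9) * (idx + np.int64(1))) & np.int64(0xFFFFFFFFFFFF)
    z = (z ^ (z >> np.int64(15))) * np.int64(0x85EBCA6B)
    z = (z ^ (z >> np.int64(13))) * np.int64(0xC2B2AE35)
    return (z ^ (z >> np.int64(16))) & np.int64(_MASK31)


@njit(cache=False)
def _pick_in_deme(lin_deme, k, target_deme, which):
    """Index of the ``which``-th active lineage lying in ``target_deme``."""
    c = -1
    for i in range(k):
        if lin_deme[i] == target_deme:
            c += 1
            if c == which:
                return i
    return -1  # unreachable for consistent rates


@njit(cache=False)
def _simulate_one(
    seed_rep,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
    accumulate,
    sfs_out,
    # tree recording buffers (always filled)
    node_time,
    left_child,
    right_child,
    lin_deme,
    lin_c1,
    lin_c2,
    lin_node,
):
    """Simulate one genealogy; returns (total_branch_length, root_node) or
    (-1.0, -1) if the time ceiling is hit."""

    np.random.seed(seed_rep)
    nd = start_sizes.shape[0]
    sizes = start_sizes.copy()
    mig = start_mig.copy()

    n_total = 0
    k = 0
    for d in range(nd):
        for _ in range(samp_sizes[d]):
            lin_deme[k] = d
            lin_c1[k] = 1 if d == 0 else 0
            lin_c2[k] = 1 if d == 1 else 0
            lin_node[k] = k
            node_time[k] = 0.0
            left_child[k] = -1
            right_child[k] = -1
            k += 1
    n_total = k
    next_node = n_total

    t = 0.0
    iev = 0
    n_ev = ev_time.shape[0]
    total_len = 0.0

    while k > 1:
        if t > ceiling:
            return -1.0, -1
        # per-deme counts
        k0 = 0
        k1 = 0
        for i in range(k):
            if lin_deme[i] == 0:
                k0 += 1
            else:
                k1 += 1
        rate = 0.0
        c_rate0 = k0 * (k0 - 1) / (4.0 * sizes[0])
        rate += c_rate0
        c_rate1 = 0.0
        m_r0 = 0.0
        m_r1 = 0.0
        if nd > 1:
            c_rate1 = k1 * (k1 - 1) / (4.0 * sizes[1])
            rate += c_rate1
            # backward migration: lineage in r jumps to s at 2Nm[s,r]/(2 N_r)
            m_r0 = k0 * mig[1, 0] / (2.0 * sizes[0])  # deme0 lineages -> deme1
            m_r1 = k1 * mig[0, 1] / (2.0 * sizes[1])  # deme1 lineages -> deme0
            rate += m_r0 + m_r1

        if rate > 0.0:
            dt = np.random.exponential(1.0 / rate)
        else:
            if iev >= n_ev:
                return -1.0, -1  # nothing can ever coalesce
            dt = ceiling + 1.0

        t_event = t + dt
        if iev < n_ev and t_event >= ev_time[iev]:
            # advance to the model event, no genealogical event
            dt_adv = ev_time[iev] - t
            if dt_adv > 0.0:
                total_len += k * dt_adv
                if accumulate:
                    for i in range(k):
                        sfs_out[lin_c1[i], lin_c2[i]] += dt_adv
            t = ev_time[iev]
            # apply every event scheduled at this time
            while iev < n_ev and ev_time[iev] <= t:
                kind = ev_kind[iev]
                if kind == 0:  # resize
                    sizes[ev_a[iev]] = ev_val[iev]
                elif kind == 1:  # join: move all lineages from a into b
                    src = ev_a[iev]
                    dst = ev_b[iev]
                    for i in range(k):
                        if lin_deme[i] == src:
                            lin_deme[i] = dst
                    for d in range(nd):
                        mig[src, d] = 0.0
                        mig[d, src] = 0.0
                else:  # set_migration: 2Nm[source, dest]
                    mig[ev_a[iev], ev_b[iev]] = ev_val[iev]
                iev += 1
            continue

        # genealogical event at t + dt
        total_len += k * dt
        if accumulate:
            for i in range(k):
                sfs_out[lin_c1[i], lin_c2[i]] += dt
        t = t_event

        u = np.random.random() * rate
        if u < c_rate0:
            ed = 0
            kd = k0
            coal = True
        elif u < c_rate0 + c_rate1:
            ed = 1
            kd = k1
            coal = True
        elif u < c_rate0 + c_rate1 + m_r0:
            ed = 0
            kd = k0
            coal = False
            dest = 1
        else:
            ed = 1
            kd = k1
            coal = False
            dest = 0

        if coal:
            w1 = np.random.randint(0, kd)
            w2 = np.random.randint(0, kd - 1)
            if w2 >= w1:
                w2 += 1
            i1 = _pick_in_deme(lin_deme, k, ed, w1)
            i2 = _pick_in_deme(lin_deme, k, ed, w2)
            if i2 < i1:
                tmp = i1
                i1 = i2
                i2 = tmp
            v = next_node
            next_node += 1
            node_time[v] = t
            left_child[v] = lin_node[i1]
            right_child[v] = lin_node[i2]
            lin_node[i1] = v
            lin_c1[i1] += lin_c1[i2]
            lin_c2[i1] += lin_c2[i2]
            # deme stays ed
            k -= 1
            lin_deme[i2] = lin_deme[k]
            lin_c1[i2] = lin_c1[k]
            lin_c2[i2] = lin_c2[k]
            lin_node[i2] = lin_node[k]
        else:
            w = np.random.randint(0, kd)
            i1 = _pick_in_deme(lin_deme, k, ed, w)
            lin_deme[i1] = dest

    return total_len, lin_node[0]


@njit(cache=False)
def accumulate_expected_sfs(
    seed,
    n_reps,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
):
    """Sum, over replicates, of branch length subtending (i, j) samples.

    Returns ``(sfs, total_length_sum, n_failed)`` where ``sfs[i, j]`` is the
    summed branch length subtending exactly ``i`` deme-0 and ``j`` deme-1
    samples.
    """
    n1 = samp_sizes[0]
    n2 = samp_sizes[1] if samp_sizes.shape[0] > 1 else 0
    n = n1 + n2
    sfs = np.zeros((n1 + 1, n2 + 1))
    node_time = np.empty(2 * n - 1)
    left_child = np.empty(2 * n - 1, dtype=np.int64)
    right_child = np.empty(2 * n - 1, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    lin_c1 = np.empty(n, dtype=np.int64)
    lin_c2 = np.empty(n, dtype=np.int64)
    lin_node = np.empty(n, dtype=np.int64)
    total = 0.0
    n_failed = 0
    for rep in range(n_reps):
        tl, _root = _simulate_one(
            _child_seed(seed, rep),
            samp_sizes,
            start_sizes,
            start_mig,
            ev_time,
            ev_kind,
            ev_a,
            ev_b,
            ev_val,
            ceiling,
            True,
            sfs,
            node_time,
            left_child,
            right_child,
            lin_deme,
            lin_c1,
            lin_c2,
            lin_node,
        )
        if tl < 0.0:
            n_failed += 1
        else:
            total += tl
    return sfs, total, n_failed


@njit(cache=False)
def accumulate_expected_sfs_fast(
    seed,
    n_reps,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
):
    """Fast path for the optimizer: identical contract to
    ``accumulate_expected_sfs`` but O(1) work per event.

    Exploits that a lineage's (i, j) descendant configuration never changes
    between its creation and its coalescence, so its whole lifetime is added
    to one SFS cell at death.  Lineage records are kept partitioned by deme
    so event sampling needs no scans.  Seeded once per call (replicate
    streams are consecutive).
    """
    nd = start_sizes.shape[0]
    n1 = samp_sizes[0]
    n2 = samp_sizes[1] if nd > 1 else 0
    n = n1 + n2
    w2 = n2 + 1
    sfs = np.zeros((n1 + 1) * w2)
    # per-deme partitioned lineage records
    c1 = np.empty((2, n), dtype=np.int64)
    c2 = np.empty((2, n), dtype=np.int64)
    birth = np.empty((2, n))
    total = 0.0
    n_failed = 0
    # inline xorshift128+ (cheap, high-quality enough for event sampling);
    # state seeded by splitmix64 from the caller's seed
    z = np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s0 = z ^ (z >> np.uint64(31))
    z = s0 + np.uint64(0x9E3779B97F4A7C15)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    s1 = z ^ (z >> np.uint64(31))
    if s0 == np.uint64(0) and s1 == np.uint64(0):
        s1 = np.uint64(1)
    inv53 = 1.0 / 9007199254740992.0  # 2^-53
    for _rep in range(n_reps):
        sizes0 = start_sizes[0]
        sizes1 = start_sizes[1] if nd > 1 else 1.0
        m01 = start_mig[0, 1] if nd > 1 else 0.0  # 2Nm[source=0, dest=1]
        m10 = start_mig[1, 0] if nd > 1 else 0.0
        k0 = int(samp_sizes[0])
        k1 = int(samp_sizes[1]) if nd > 1 else 0
        for i in range(k0):
            c1[0, i] = 1
            c2[0, i] = 0
            birth[0, i] = 0.0
        for i in range(k1):
            c1[1, i] = 0
            c2[1, i] = 1
            birth[1, i] = 0.0
        t = 0.0
        iev = 0
        n_ev = ev_time.shape[0]
        failed = False
        while k0 + k1 > 1:
            if t > ceiling:
                failed = True
                break
            cr0 = k0 * (k0 - 1) / (4.0 * sizes0)
            cr1 = k1 * (k1 - 1) / (4.0 * sizes1)
            mr0 = k0 * m10 / (2.0 * sizes0)  # lineages in deme0 jump to deme1
            mr1 = k1 * m01 / (2.0 * sizes1)
            rate = cr0 + cr1 + mr0 + mr1
            if rate > 0.0:
                x = s0
                y = s1
                s0 = y
                x ^= x << np.uint64(23)
                s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
                uu = float((s1 + y) >> np.uint64(11)) * inv53
                dt = -math.log(1.0 - uu) / rate
            else:
                if iev >= n_ev:
                    failed = True
                    break
                dt = ceiling + 1.0
            te = t + dt
            if iev < n_ev and te >= ev_time[iev]:
                t = ev_time[iev]
                while iev < n_ev and ev_time[iev] <= t:
                    kind = ev_kind[iev]
                    if kind == 0:
                        if ev_a[iev] == 0:
                            sizes0 = ev_val[iev]
                        else:
                            sizes1 = ev_val[iev]
                    elif kind == 1:
                        src = ev_a[iev]
                        dst = ev_b[iev]
                        ks = k1 if src == 1 else k0
                        kd = k0 if src == 1 else k1
                        for i in range(ks):
                            c1[dst, kd + i] = c1[src, i]
                            c2[dst, kd + i] = c2[src, i]
                            birth[dst, kd + i] = birth[src, i]
                        if src == 1:
                            k0 += k1
                            k1 = 0
                        else:
                            k1 += k0
                            k0 = 0
                        m01 = 0.0
                        m10 = 0.0
                    else:
                        if ev_a[iev] == 0:
                            m01 = ev_val[iev]
                        else:
                            m10 = ev_val[iev]
                    iev += 1
                continue
            t = te
            x = s0
            y = s1
            s0 = y
            x ^= x << np.uint64(23)
            s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
            u = float((s1 + y) >> np.uint64(11)) * inv53 * rate
            if u < cr0 + cr1:
                d = 0 if u < cr0 else 1
                kd = k0 if d == 0 else k1
                x = s0
                y = s1
                s0 = y
                x ^= x << np.uint64(23)
                s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
                i1 = int(float((s1 + y) >> np.uint64(11)) * inv53 * kd)
                x = s0
                y = s1
                s0 = y
                x ^= x << np.uint64(23)
                s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
                i2 = int(float((s1 + y) >> np.uint64(11)) * inv53 * (kd - 1))
                if i2 >= i1:
                    i2 += 1
                # flush both lifetimes
                idx1 = c1[d, i1] * w2 + c2[d, i1]
                idx2 = c1[d, i2] * w2 + c2[d, i2]
                dl1 = t - birth[d, i1]
                dl2 = t - birth[d, i2]
                sfs[idx1] += dl1
                sfs[idx2] += dl2
                total += dl1 + dl2
                c1[d, i1] += c1[d, i2]
                c2[d, i1] += c2[d, i2]
                birth[d, i1] = t
                kd -= 1
                c1[d, i2] = c1[d, kd]
                c2[d, i2] = c2[d, kd]
                birth[d, i2] = birth[d, kd]
                if d == 0:
                    k0 = kd
                else:
                    k1 = kd
            else:
                # migration: deme r lineage jumps to the other deme
                r = 0 if u < cr0 + cr1 + mr0 else 1
                s = 1 - r
                kr = k0 if r == 0 else k1
                ks = k0 if s == 0 else k1
                x = s0
                y = s1
                s0 = y
                x ^= x << np.uint64(23)
                s1 = x ^ y ^ (x >> np.uint64(17)) ^ (y >> np.uint64(26))
                i1 = int(float((s1 + y) >> np.uint64(11)) * inv53 * kr)
                c1[s, ks] = c1[r, i1]
                c2[s, ks] = c2[r, i1]
                birth[s, ks] = birth[r, i1]
                kr -= 1
                c1[r, i1] = c1[r, kr]
                c2[r, i1] = c2[r, kr]
                birth[r, i1] = birth[r, kr]
                if r == 0:
                    k0 = kr
                    k1 = ks + 1
                else:
                    k1 = kr
                    k0 = ks + 1
        if failed:
            n_failed += 1
    return sfs.reshape((n1 + 1, w2)), total, n_failed


@njit(cache=False)
def _mark_descendants(v, left_child, right_child, out_row, stack):
    sp = 0
    stack[sp] = v
    sp += 1
    while sp > 0:
        sp -= 1
        node = stack[sp]
        lc = left_child[node]
        if lc < 0:
            out_row[node] = 1
        else:
            stack[sp] = lc
            sp += 1
            stack[sp] = right_child[node]
            sp += 1


@njit(cache=False)
def simulate_snp_haplotypes(
    seed,
    n_snps,
    pool_factor,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
):
    """Conditioned-segregating mode.

    Under infinite sites, a site conditioned on segregating falls on a
    genealogy with probability proportional to that genealogy's *total*
    length (length-biased sampling), and then on a branch proportional to
    branch length.  A pool of ``n_snps`` independent genealogies is
    simulated; the ``n_snps`` mutations are allocated across the pool by a
    multinomial on total lengths, and genealogies receiving mutations are
    re-simulated (identical per-index seed) to place them.  Marginally each
    SNP follows the exact conditioned-segregating distribution
    E[l_class] / E[l_total].  A pool of ``pool_factor * n_snps`` genealogies
    keeps repeat draws of the same genealogy (which would correlate SNPs)
    rare.

    Returns (haplotypes[n_snps, n], ok).
    """
    n1 = samp_sizes[0]
    n2 = samp_sizes[1] if samp_sizes.shape[0] > 1 else 0
    n = n1 + n2
    n_nodes = 2 * n - 1
    haps = np.zeros((n_snps, n), dtype=np.int8)
    node_time = np.empty(n_nodes)
    left_child = np.empty(n_nodes, dtype=np.int64)
    right_child = np.empty(n_nodes, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    lin_c1 = np.empty(n, dtype=np.int64)
    lin_c2 = np.empty(n, dtype=np.int64)
    lin_node = np.empty(n, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)
    bl = np.empty(n_nodes)
    n_pool = n_snps * pool_factor
    lens = np.empty(n_pool)
    # pass 1: total lengths of the genealogy pool
    for g in range(n_pool):
        tl, _root = _simulate_one(
            _child_seed(seed, g),
            samp_sizes,
            start_sizes,
            start_mig,
            ev_time,
            ev_kind,
            ev_a,
            ev_b,
            ev_val,
            ceiling,
            False,
            np.zeros((1, 1)),
            node_time,
            left_child,
            right_child,
            lin_deme,
            lin_c1,
            lin_c2,
            lin_node,
        )
        if tl < 0.0:
            return haps, False
        lens[g] = tl
    # length-biased multinomial allocation of mutations to genealogies
    np.random.seed(_child_seed(seed, np.int64(n_pool) + 7))
    counts = np.random.multinomial(n_snps, lens / lens.sum())
    s = 0
    for g in range(n_pool):
        m_g = counts[g]
        if m_g == 0:
            continue
        tl, root = _simulate_one(
            _child_seed(seed, g),
            samp_sizes,
            start_sizes,
            start_mig,
            ev_time,
            ev_kind,
            ev_a,
            ev_b,
            ev_val,
            ceiling,
            False,
            np.zeros((1, 1)),
            node_time,
            left_child,
            right_child,
            lin_deme,
            lin_c1,
            lin_c2,
            lin_node,
        )
        for v in range(n_nodes):
            bl[v] = 0.0
        for v in range(n, 2 * n - 1):
            tv = node_time[v]
            bl[left_child[v]] = tv - node_time[left_child[v]]
            bl[right_child[v]] = tv - node_time[right_child[v]]
        for _ in range(m_g):
            u = np.random.random() * tl
            acc = 0.0
            target = root
            for v in range(n_nodes):
                if v == root:
                    continue
                acc += bl[v]
                if acc >= u:
                    target = v
                    break
            _mark_descendants(target, left_child, right_child, haps[s], stack)
            s += 1
    return haps, True


@njit(cache=False)
def simulate_tag_haplotypes(
    seed,
    n_tags,
    theta_per_tag_half,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
):
    """Absolute mode: one genealogy per tag, Poisson(mu*L_tag*total_length)
    mutations.  ``theta_per_tag_half`` = mu * L_tag (per-generation rate per
    lineage).  Returns (haplotypes, tag_of_snp, n_snps_found, ok)."""
    n1 = samp_sizes[0]
    n2 = samp_sizes[1] if samp_sizes.shape[0] > 1 else 0
    n = n1 + n2
    n_nodes = 2 * n - 1
    cap = max(64, int(4 * n_tags))
    haps = np.zeros((cap, n), dtype=np.int8)
    tag_of = np.empty(cap, dtype=np.int64)
    node_time = np.empty(n_nodes)
    left_child = np.empty(n_nodes, dtype=np.int64)
    right_child = np.empty(n_nodes, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    lin_c1 = np.empty(n, dtype=np.int64)
    lin_c2 = np.empty(n, dtype=np.int64)
    lin_node = np.empty(n, dtype=np.int64)
    stack = np.empty(n_nodes, dtype=np.int64)
    bl = np.empty(n_nodes)
    m = 0
    for tg in range(n_tags):
        tl, root = _simulate_one(
            _child_seed(seed, tg),
            samp_sizes,
            start_sizes,
            start_mig,
            ev_time,
            ev_kind,
            ev_a,
            ev_b,
            ev_val,
            ceiling,
            False,
            np.zeros((1, 1)),
            node_time,
            left_child,
            right_child,
            lin_deme,
            lin_c1,
            lin_c2,
            lin_node,
        )
        if tl < 0.0:
            return haps, tag_of, m, False
        n_mut = np.random.poisson(theta_per_tag_half * tl)
        if n_mut == 0:
            continue
        for v in range(n_nodes):
            bl[v] = 0.0
        for v in range(n, 2 * n - 1):
            tv = node_time[v]
            bl[left_child[v]] = tv - node_time[left_child[v]]
            bl[right_child[v]] = tv - node_time[right_child[v]]
        for _ in range(n_mut):
            if m >= cap:
                new_cap = cap * 2
                new_haps = np.zeros((new_cap, n), dtype=np.int8)
                new_tag = np.empty(new_cap, dtype=np.int64)
                new_haps[:cap] = haps
                new_tag[:cap] = tag_of
                haps = new_haps
                tag_of = new_tag
                cap = new_cap
            u = np.random.random() * tl
            acc = 0.0
            target = root
            for v in range(n_nodes):
                if v == root:
                    continue
                acc += bl[v]
                if acc >= u:
                    target = v
                    break
            _mark_descendants(target, left_child, right_child, haps[m], stack)
            tag_of[m] = tg
            m += 1
    return haps, tag_of, m, True


@njit(cache=False)
def simulate_tree(
    seed,
    samp_sizes,
    start_sizes,
    start_mig,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_val,
    ceiling,
):
    """One genealogy: returns (node_time, left_child, right_child,
    total_length, root); root = -1 on ceiling failure."""
    n1 = samp_sizes[0]
    n2 = samp_sizes[1] if samp_sizes.shape[0] > 1 else 0
    n = n1 + n2
    n_nodes = 2 * n - 1
    node_time = np.zeros(n_nodes)
    left_child = np.full(n_nodes, -1, dtype=np.int64)
    right_child = np.full(n_nodes, -1, dtype=np.int64)
    lin_deme = np.empty(n, dtype=np.int64)
    lin_c1 = np.empty(n, dtype=np.int64)
    lin_c2 = np.empty(n, dtype=np.int64)
    lin_node = np.empty(n, dtype=np.int64)
    tl, root = _simulate_one(
        seed,
        samp_sizes,
        start_sizes,
        start_mig,
        ev_time,
        ev_kind,
        ev_a,
        ev_b,
        ev_val,
        ceiling,
        False,
        np.zeros((1, 1)),
        node_time,
        left_child,
        right_child,
        lin_deme,
        lin_c1,
        lin_c2,
        lin_node,
    )
    return node_time, left_child, right_child, tl, root
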