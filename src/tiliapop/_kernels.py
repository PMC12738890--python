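"""Hot per-locus coalescent/mutation kernel.

One function simulates a single microsatellite locus backward in time
through an arbitrary schedule of demographic events (lineage movements,
admixture splits, size changes) and then drops generalized-stepwise
mutations plus single-nucleotide indels on the resulting tree. It is
compiled with numba when available (pure-Python fallback otherwise) because
ABC reference tables need hundreds of thousands of locus simulations.

Event encoding (arrays sorted by time, stable within ties):
  kind 0  move every lineage of deme ``a`` to deme ``b`` (population merge)
  kind 1  admixture: each lineage of ``a`` moves to ``b`` with probability
          ``p``, else to ``c``
  kind 2  resize deme ``a`` to ``p`` (used for the ancestral size change)
"""

from __future__ import annotations

import numpy as np


def _simulate_locus_py(
    seed,
    deme0,
    sizes_init,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_c,
    ev_p,
    mu,
    gsm_p,
    sni,
    rep_lo,
    rep_hi,
    root_rep,
):
    """Simulate one locus; returns (leaf repeat counts, leaf SNI offsets, tmrca).

    Coalescence within a deme of (diploid) size N occurs at rate 1/(2N) per
    lineage pair, i.e. total rate k(k-1)/(4N); continuous-time exponential
    waiting times (exact in the N >> k regime of the priors). Mutations per
    branch are Poisson(mu * branch length); each changes the repeat count by
    a geometrically distributed step (P(|step|=m) = (1-gsm_p) gsm_p^(m-1)),
    sign symmetric; steps leaving [rep_lo, rep_hi] are redrawn. SNI events
    are Poisson(sni * branch) and shift the allele by +-1 nucleotide.
    """
    np.random.seed(seed)
    n_leaves = deme0.shape[0]
    n_nodes = 2 * n_leaves - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes, np.float64)
    act = np.arange(n_leaves).astype(np.int64)
    ademe = deme0.astype(np.int64).copy()
    sizes = sizes_init.astype(np.float64).copy()
    n_demes = sizes.shape[0]
    n_events = ev_time.shape[0]
    counts = np.zeros(n_demes, np.int64)
    rates = np.zeros(n_demes, np.float64)

    k = n_leaves
    t = 0.0
    ei = 0
    nxt = n_leaves
    while k > 1:
        for d in range(n_demes):
            counts[d] = 0
        for i in range(k):
            counts[ademe[i]] += 1
        tot = 0.0
        for d in range(n_demes):
            c = counts[d]
            if c >= 2 and sizes[d] > 0.0:
                rates[d] = c * (c - 1) / (4.0 * sizes[d])
            else:
                rates[d] = 0.0
            tot += rates[d]
        t_event = ev_time[ei] if ei < n_events else 1.0e300
        if tot <= 0.0:
            if ei >= n_events:
                break  # cannot coalesce further; caller validates scenarios
            t = t_event
        else:
            wait = np.random.exponential(1.0 / tot)
            if t + wait >= t_event:
                t = t_event
            else:
                t = t + wait
                # coalescence: pick deme weighted by rate
                u = np.random.random() * tot
                d = 0
                acc = rates[0]
                while acc < u and d < n_demes - 1:
                    d += 1
                    acc += rates[d]
                c = counts[d]
                i1 = np.random.randint(0, c)
                i2 = np.random.randint(0, c - 1)
                if i2 >= i1:
                    i2 += 1
                pos1 = -1
                pos2 = -1
                seen = 0
                for i in range(k):
                    if ademe[i] == d:
                        if seen == i1:
                            pos1 = i
                        if seen == i2:
                            pos2 = i
                        seen += 1
                if pos1 > pos2:
                    tmp = pos1
                    pos1 = pos2
                    pos2 = tmp
                node = nxt
                nxt += 1
                node_time[node] = t
                parent[act[pos1]] = node
                parent[act[pos2]] = node
                act[pos1] = node
                ademe[pos1] = d
                act[pos2] = act[k - 1]
                ademe[pos2] = ademe[k - 1]
                k -= 1
                continue
        # apply the demographic event at time t
        kind = ev_kind[ei]
        a = ev_a[ei]
        if kind == 0:
            b = ev_b[ei]
            for i in range(k):
                if ademe[i] == a:
                    ademe[i] = b
        elif kind == 1:
            b = ev_b[ei]
            c2 = ev_c[ei]
            p = ev_p[ei]
            for i in range(k):
                if ademe[i] == a:
                    if np.random.random() < p:
                        ademe[i] = b
                    else:
                        ademe[i] = c2
        else:
            sizes[a] = ev_p[ei]
        ei += 1

    root = nxt - 1
    rep = np.zeros(n_nodes, np.int64)
    off = np.zeros(n_nodes, np.int64)
    rep[root] = root_rep
    off[root] = 0
    for i in range(root - 1, -1, -1):
        pa = parent[i]
        br = node_time[pa] - node_time[i]
        r = rep[pa]
        n_mut = np.random.poisson(mu * br)
        for _ in range(n_mut):
            for _try in range(100):
                step = 1
                while np.random.random() < gsm_p:
                    step += 1
                if np.random.random() < 0.5:
                    step = -step
                r_new = r + step
                if rep_lo <= r_new <= rep_hi:
                    r = r_new
                    break
        rep[i] = r
        o = off[pa]
        n_sni = np.random.poisson(sni * br)
        for _ in range(n_sni):
            if np.random.random() < 0.5:
                o += 1
            else:
                o -= 1
        off[i] = o
    return rep[:n_leaves], off[:n_leaves], node_time[root]


def _summary_stats_py(sizes, gstart, motif):
    """ABC summary statistics from a haploid allele-size matrix.

    ``sizes`` is (n_loci, n_haploids) in nucleotides with missing < 0;
    columns are grouped (group g = columns gstart[g]:gstart[g+1]) and the
    two haploids of a diploid individual are adjacent. Returns a flat
    vector: A per group, H per group, V per group, M per group, then FST,
    DAS and (delta mu)^2 for each group pair (a < b).
    """
    n_loci = sizes.shape[0]
    n_groups = gstart.shape[0] - 1
    n_pairs = n_groups * (n_groups - 1) // 2
    max_sz = 0
    for g in range(n_groups):
        if gstart[g + 1] - gstart[g] > max_sz:
            max_sz = gstart[g + 1] - gstart[g]

    sorted_vals = np.zeros((n_groups, n_loci, max_sz), np.int64)
    cnt = np.zeros((n_groups, n_loci), np.int64)
    mean_nt = np.zeros((n_groups, n_loci))
    ok = np.zeros((n_groups, n_loci), np.bool_)

    a_sum = np.zeros(n_groups)
    h_sum = np.zeros(n_groups)
    v_sum = np.zeros(n_groups)
    m_sum = np.zeros(n_groups)
    n_ok = np.zeros(n_groups)

    for g in range(n_groups):
        lo, hi = gstart[g], gstart[g + 1]
        for j in range(n_loci):
            c = 0
            for i in range(lo, hi):
                v = sizes[j, i]
                if v >= 0:
                    sorted_vals[g, j, c] = v
                    c += 1
            if c == 0:
                continue
            b = np.sort(sorted_vals[g, j, :c])
            sorted_vals[g, j, :c] = b
            cnt[g, j] = c
            ok[g, j] = True
            mean = 0.0
            for i in range(c):
                mean += b[i]
            mean /= c
            mean_nt[g, j] = mean
            var = 0.0
            for i in range(c):
                d = (b[i] - mean) / motif
                var += d * d
            var = var / (c - 1) if c > 1 else 0.0
            ndist = 1
            ss = 0.0
            run = 1
            for i in range(1, c):
                if b[i] == b[i - 1]:
                    run += 1
                else:
                    ss += (run / c) ** 2
                    run = 1
                    ndist += 1
            ss += (run / c) ** 2
            rng_rep = int(np.rint((b[c - 1] - b[0]) / motif))
            n_ok[g] += 1
            a_sum[g] += ndist
            h_sum[g] += 1.0 - ss
            v_sum[g] += var
            m_sum[g] += ndist / (rng_rep + 1)

    out = np.full(4 * n_groups + 3 * n_pairs, np.nan)
    for g in range(n_groups):
        if n_ok[g] > 0:
            out[g] = a_sum[g] / n_ok[g]
            out[n_groups + g] = h_sum[g] / n_ok[g]
            out[2 * n_groups + g] = v_sum[g] / n_ok[g]
            out[3 * n_groups + g] = m_sum[g] / n_ok[g]

    pi = 0
    for a in range(n_groups):
        for bb in range(a + 1, n_groups):
            ht_sum = 0.0
            hs_sum = 0.0
            das_sum = 0.0
            dm2_sum = 0.0
            n_shared = 0
            for j in range(n_loci):
                if not (ok[a, j] and ok[bb, j]):
                    continue
                n_shared += 1
                ca_, cb_ = cnt[a, j], cnt[bb, j]
                xa = sorted_vals[a, j]
                xb = sorted_vals[bb, j]
                ia = 0
                ib = 0
                ssa = 0.0
                ssb = 0.0
                sab = 0.0
                while ia < ca_ or ib < cb_:
                    if ib >= cb_ or (ia < ca_ and xa[ia] <= xb[ib]):
                        s = xa[ia]
                    else:
                        s = xb[ib]
                    ra = 0
                    while ia < ca_ and xa[ia] == s:
                        ra += 1
                        ia += 1
                    rb = 0
                    while ib < cb_ and xb[ib] == s:
                        rb += 1
                        ib += 1
                    fa = ra / ca_
                    fb = rb / cb_
                    ssa += fa * fa
                    ssb += fb * fb
                    sab += fa * fb
                hs_sum += 0.5 * ((1.0 - ssa) + (1.0 - ssb))
                ht_sum += 1.0 - 0.25 * (ssa + 2.0 * sab + ssb)
                # DAS over cross-group diploid genotype pairs
                tot = 0
                npr = 0
                lo_a, lo_b = gstart[a], gstart[bb]
                nd_a = (gstart[a + 1] - lo_a) // 2
                nd_b = (gstart[bb + 1] - lo_b) // 2
                for i in range(nd_a):
                    x1 = sizes[j, lo_a + 2 * i]
                    x2 = sizes[j, lo_a + 2 * i + 1]
                    if x1 < 0 or x2 < 0:
                        continue
                    for k2 in range(nd_b):
                        y1 = sizes[j, lo_b + 2 * k2]
                        y2 = sizes[j, lo_b + 2 * k2 + 1]
                        if y1 < 0 or y2 < 0:
                            continue
                        sh = 0
                        used1 = False
                        used2 = False
                        if x1 == y1:
                            sh += 1
                            used1 = True
                        elif x1 == y2:
                            sh += 1
                            used2 = True
                        if x2 == y2 and not used2:
                            sh += 1
                        elif x2 == y1 and not used1:
                            sh += 1
                        tot += sh
                        npr += 1
                if npr > 0:
                    das_sum += 1.0 - tot / (2.0 * npr)
                dm = (mean_nt[a, j] - mean_nt[bb, j]) / motif
                dm2_sum += dm * dm
            base = 4 * n_groups
            if n_shared > 0:
                ht_bar = ht_sum / n_shared
                hs_bar = hs_sum / n_shared
                out[base + pi] = (ht_bar - hs_bar) / ht_bar if ht_bar > 0 else 0.0
                out[base + n_pairs + pi] = das_sum / n_shared
                out[base + 2 * n_pairs + pi] = dm2_sum / n_shared
            pi += 1
    return out


def _compile(func):
    try:
        from numba import njit

        return njit(cache=True)(func)
    except Exception:  # pragma: no cover - numba is normally available
        return func


simulate_locus = _compile(_simulate_locus_py)
summary_stats_kernel = _compile(_summary_stats_py)
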