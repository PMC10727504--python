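"""Compiled numerical kernels for the MCMC inner loop.

These mirror the reference implementations in :mod:`mscintro.likelihood`
(`locus_loglik` and `coalescent_stats`) on flat arrays; the test suite
checks they agree.  Gene trees are (parent, ages) arrays; the species
model is a flat event table compiled by :func:`event_arrays`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .popmodel import PopModel

__all__ = ["prune_jc69", "coal_sweep", "event_arrays", "stats_logdensity"]


@njit(cache=True)
def _tree_order(parent, n_tips):
    n = parent.shape[0]
    child0 = np.full(n, -1, np.int64)
    child1 = np.full(n, -1, np.int64)
    root = -1
    for i in range(n):
        p = parent[i]
        if p < 0:
            root = i
        elif child0[p] < 0:
            child0[p] = i
        else:
            child1[p] = i
    # postorder via iterative stack
    post = np.empty(n, np.int64)
    stack = np.empty(2 * n, np.int64)
    state = np.empty(2 * n, np.int64)
    top = 0
    stack[0] = root
    state[0] = 0
    k = 0
    while top >= 0:
        node = stack[top]
        st = state[top]
        top -= 1
        if st == 1 or node < n_tips:
            post[k] = node
            k += 1
        else:
            top += 1
            stack[top] = node
            state[top] = 1
            top += 1
            stack[top] = child0[node]
            state[top] = 0
            top += 1
            stack[top] = child1[node]
            state[top] = 0
    return child0, child1, root, post


@njit(cache=True)
def prune_jc69(parent, ages, n_tips, tip_partials, counts):
    """Pruning log-likelihood under JC69.

    tip_partials: (n_tips, npat, 4); counts: (npat,).
    """
    n = parent.shape[0]
    npat = tip_partials.shape[1]
    child0, child1, root, post = _tree_order(parent, n_tips)
    partial = np.empty((n, npat, 4))
    for i in range(n_tips):
        partial[i] = tip_partials[i]
    logscale = 0.0
    for oi in range(n):
        node = post[oi]
        if node < n_tips:
            continue
        mx = 0.0
        for pat in range(npat):
            for a in range(4):
                acc = 1.0
                for ci in range(2):
                    c = child0[node] if ci == 0 else child1[node]
                    t = ages[node] - ages[c]
                    same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
                    diff = (1.0 - same) / 3.0
                    v = partial[c]
                    tot = v[pat, 0] + v[pat, 1] + v[pat, 2] + v[pat, 3]
                    acc *= (same - diff) * v[pat, a] + diff * tot
                partial[node, pat, a] = acc
                if acc > mx:
                    mx = acc
        if mx <= 0.0:
            return -np.inf
        logscale += np.log(mx)
        for pat in range(npat):
            for a in range(4):
                partial[node, pat, a] /= mx
    total = 0.0
    csum = 0.0
    for pat in range(npat):
        site = 0.25 * (
            partial[root, pat, 0]
            + partial[root, pat, 1]
            + partial[root, pat, 2]
            + partial[root, pat, 3]
        )
        if site <= 0.0:
            return -np.inf
        total += counts[pat] * np.log(site)
        csum += counts[pat]
    return total + logscale * csum


def event_arrays(model: PopModel):
    """Flatten the event list: hybridization pairs become two single-side
    entries at the same time (safe: a side's target populations are never
    another side's source)."""
    times, kinds, a, b, c, d, phis = [], [], [], [], [], [], []
    hyb_labels: list[str] = []
    for ev in model.events:
        if ev.kind == "div":
            srcs = list(ev.sources)
            times.append(ev.time)
            kinds.append(0)
            a.append(srcs[0])
            b.append(srcs[1] if len(srcs) > 1 else -1)
            c.append(ev.target)
            d.append(-1)
            phis.append(0.0)
        else:
            for src, main, donor, label, phi in ev.sides:
                if label not in hyb_labels:
                    hyb_labels.append(label)
                times.append(ev.time)
                kinds.append(1)
                a.append(src)
                b.append(main)
                c.append(donor)
                d.append(hyb_labels.index(label))
                phis.append(phi)
    return (
        np.asarray(times, dtype=np.float64),
        np.asarray(kinds, dtype=np.int64),
        np.asarray(a, dtype=np.int64),
        np.asarray(b, dtype=np.int64),
        np.asarray(c, dtype=np.int64),
        np.asarray(d, dtype=np.int64),
        hyb_labels,
    )


@njit(cache=True)
def coal_sweep(
    parent,
    ages,
    n_tips,
    tip_pop,
    ind,
    n_pops,
    n_hyb,
    ev_time,
    ev_kind,
    ev_a,
    ev_b,
    ev_c,
    ev_d,
):
    """Sweep a gene tree through the population structure.

    Returns (feasible, coal_count[n_pops], wait_sum[n_pops],
    donor[n_hyb], ancestral[n_hyb], crossings[(m, 3)]) where crossings
    rows are (lineage, hybrid index, indicator).
    """
    n = parent.shape[0]
    child0, child1, root, post = _tree_order(parent, n_tips)
    coal_count = np.zeros(n_pops, np.int64)
    wait_sum = np.zeros(n_pops)
    donor = np.zeros(n_hyb, np.int64)
    anc = np.zeros(n_hyb, np.int64)
    crossings = np.empty((n * max(n_hyb, 1), 3), np.int64)
    n_cross = 0

    lineage_pop = np.full(n, -1, np.int64)
    counts = np.zeros(n_pops, np.int64)
    for i in range(n_tips):
        p = tip_pop[i]
        lineage_pop[i] = p
        counts[p] += 1

    internal = np.argsort(ages[n_tips:]) + n_tips
    n_int = internal.shape[0]
    n_ev = ev_time.shape[0]
    ii = 0
    ei = 0
    t = 0.0
    while ii < n_int or ei < n_ev:
        if ii < n_int and (ei >= n_ev or ages[internal[ii]] <= ev_time[ei]):
            when = ages[internal[ii]]
            is_coal = True
        else:
            when = ev_time[ei]
            is_coal = False
        dt = when - t
        if dt > 0:
            for p in range(n_pops):
                k = counts[p]
                if k > 1:
                    wait_sum[p] += k * (k - 1) * dt
        t = when
        if is_coal:
            node = internal[ii]
            ii += 1
            ca = child0[node]
            cb = child1[node]
            pa = lineage_pop[ca]
            pb = lineage_pop[cb]
            if pa != pb:
                return False, coal_count, wait_sum, donor, anc, crossings[:0]
            coal_count[pa] += 1
            lineage_pop[ca] = -1
            lineage_pop[cb] = -1
            lineage_pop[node] = pa
            counts[pa] -= 1
        else:
            kind = ev_kind[ei]
            if kind == 0:
                sa = ev_a[ei]
                sb = ev_b[ei]
                tgt = ev_c[ei]
                for lin in range(n):
                    p = lineage_pop[lin]
                    if p == sa or p == sb:
                        lineage_pop[lin] = tgt
                        counts[p] -= 1
                        counts[tgt] += 1
            else:
                src = ev_a[ei]
                main = ev_b[ei]
                don = ev_c[ei]
                h = ev_d[ei]
                for lin in range(n):
                    if lineage_pop[lin] == src:
                        iv = ind[lin, h]
                        crossings[n_cross, 0] = lin
                        crossings[n_cross, 1] = h
                        crossings[n_cross, 2] = iv
                        n_cross += 1
                        if iv == 1:
                            donor[h] += 1
                            lineage_pop[lin] = don
                        else:
                            anc[h] += 1
                            lineage_pop[lin] = main
                        counts[src] -= 1
                        counts[don if iv == 1 else main] += 1
            ei += 1
    return True, coal_count, wait_sum, donor, anc, crossings[:n_cross].copy()


LOG2 = float(np.log(2.0))


def stats_logdensity(stats, theta: np.ndarray, phi: np.ndarray) -> float:
    """Log coalescent density from sweep statistics, including the
    2^{-(K - n_active)} convention factor for persistent indicators
    (constant K omitted)."""
    feasible, cc, ws, dn, an, crossings = stats
    if not feasible:
        return -np.inf
    out = float(np.sum(cc * np.log(2.0 / theta)) - np.sum(ws / theta))
    for h in range(len(dn)):
        if dn[h]:
            if phi[h] <= 0.0:
                return -np.inf
            out += dn[h] * np.log(phi[h])
        if an[h]:
            if phi[h] >= 1.0:
                return -np.inf
            out += an[h] * np.log1p(-phi[h])
    return out + LOG2 * len(crossings)
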