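"""Numba event loop for the lattice KMC used by the orchestrator.

The engine operates on flat node indices with a precomputed axis
neighbor table (2D and 3D share the code path). Rates follow exactly
the forms in :mod:`thrombosim.kmc`:

* hop: per-direction base rates ``D_p/dx² + max(0, u·e)/dx`` tabulated
  per node after each flow solve, blocked dynamically by occupancy;
* attach (mobile platelet): ``W(gamma) * (k_att_col * F_p [collagen
  adjacent] + k_att_pp * sum_q max(F_p, F_q))`` over adjacent bound
  platelets q — the pairwise max lets an activated deposit recruit
  passive platelets;
* detach (bound platelet): ``k_det * (1/F_p) * exp(gamma/gamma_c)``
  with the collagen prefactor if the platelet is bound to collagen.

Platelet ids are never recycled, so the event log (insert / attach /
detach / exit records with time stamps) replays exactly. A platelet
whose last bound neighbor detaches is released back to the mobile
state (cascade, logged as detachments at the same time stamp).

Neighbor-table conventions: entries >= 0 are lumen nodes, -1 is a
solid/blocked face, -2 is an open exit face (downstream of the outlet;
a hop through it removes the platelet).

Implementation note: no loop in this module uses ``continue`` or
``break`` — numba 0.67 miscompiles such control flow in ``while``
loops (assignments made before the jump can be lost), which was caught
by a clock-monotonicity check; control flow is flag-based instead, and
a test cross-validates the compiled kernel against its pure-Python
``py_func`` on identical inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# counters indices
NM, NB, NEXT_PID, IPTR, NEV, NATT, NHOP, NSKIP = range(8)
# event kinds
EV_INSERT, EV_ATTACH, EV_DETACH, EV_EXIT = 1, 2, 3, 4

EXIT = -2


@njit(cache=True)
def _mobile_rate(pid, pos, F, occ, bound_node, col_adj, hop, W, nbr,
                 katt_col, katt_pp):
    p = pos[pid]
    r = 0.0
    d2 = nbr.shape[1]
    for d in range(d2):
        j = nbr[p, d]
        if j == EXIT or (j >= 0 and occ[j] < 0):
            r += hop[p, d]
    att = 0.0
    if col_adj[p]:
        att += katt_col * F[pid]
    for d in range(d2):
        j = nbr[p, d]
        if j >= 0 and bound_node[j]:
            q = occ[j]
            fq = F[q] if F[q] > F[pid] else F[pid]
            att += katt_pp * fq
    return r + att * W[p]


@njit(cache=True)
def _detach_rate(pid, pos, F, colbound, edet, kdet_col, kdet_pp):
    k = kdet_col if colbound[pid] else kdet_pp
    return k / F[pid] * edet[pos[pid]]


@njit(cache=True)
def _refresh_mobile(pid, pos, F, occ, bound_node, col_adj, hop, W, nbr,
                    katt_col, katt_pp, rate, totals):
    new = _mobile_rate(pid, pos, F, occ, bound_node, col_adj, hop, W, nbr,
                       katt_col, katt_pp)
    totals[0] += new - rate[pid]
    rate[pid] = new


@njit(cache=True)
def _refresh_neighbors(node, skip_pid, pos, status, F, occ, bound_node,
                       col_adj, hop, W, nbr, katt_col, katt_pp, rate, totals):
    """Recompute rates of mobile platelets adjacent to ``node``."""
    d2 = nbr.shape[1]
    for d in range(d2):
        j = nbr[node, d]
        if j >= 0:
            q = occ[j]
            if q >= 0 and q != skip_pid and status[q] == 1:
                _refresh_mobile(q, pos, F, occ, bound_node, col_adj, hop, W,
                                nbr, katt_col, katt_pp, rate, totals)


@njit(cache=True)
def recompute_all(counters, totals, mlist, blist, pos, status, F, colbound,
                  rate, occ, bound_node, col_adj, hop, W, edet, nbr,
                  katt_col, katt_pp, kdet_col, kdet_pp):
    """Rebuild every cached rate (after flow or signaling updates)."""
    totals[0] = 0.0
    totals[1] = 0.0
    for k in range(counters[NM]):
        pid = mlist[k]
        rate[pid] = _mobile_rate(pid, pos, F, occ, bound_node, col_adj, hop,
                                 W, nbr, katt_col, katt_pp)
        totals[0] += rate[pid]
    for k in range(counters[NB]):
        pid = blist[k]
        rate[pid] = _detach_rate(pid, pos, F, colbound, edet,
                                 kdet_col, kdet_pp)
        totals[1] += rate[pid]


@njit(cache=True)
def _list_remove(lst, lpos, n, pid):
    i = lpos[pid]
    last = lst[n - 1]
    lst[i] = last
    lpos[last] = i
    return n - 1


@njit(cache=True)
def _log(ev_t, ev_kind, ev_pid, ev_node, counters, t, kind, pid, node):
    n = counters[NEV]
    if n < ev_t.shape[0]:
        ev_t[n] = t
        ev_kind[n] = kind
        ev_pid[n] = pid
        ev_node[n] = node
        counters[NEV] = n + 1


@njit(cache=True)
def _unbind_one(q, t, counters, totals, pos, status, F, colbound, rate,
                mlist, mpos, blist, bpos, occ, bound_node, col_adj, hop, W,
                nbr, katt_col, katt_pp, ev_t, ev_kind, ev_pid, ev_node):
    """Move one bound platelet back to the mobile state."""
    p = pos[q]
    counters[NB] = _list_remove(blist, bpos, counters[NB], q)
    totals[1] -= rate[q]
    bound_node[p] = False
    status[q] = 1
    colbound[q] = False
    mlist[counters[NM]] = q
    mpos[q] = counters[NM]
    counters[NM] += 1
    rate[q] = _mobile_rate(q, pos, F, occ, bound_node, col_adj, hop, W,
                           nbr, katt_col, katt_pp)
    totals[0] += rate[q]
    _log(ev_t, ev_kind, ev_pid, ev_node, counters, t, EV_DETACH, q, p)
    # adjacent mobiles lose an attachment partner
    d2 = nbr.shape[1]
    for d in range(d2):
        j = nbr[p, d]
        if j >= 0:
            w = occ[j]
            if w >= 0 and w != q and status[w] == 1:
                _refresh_mobile(w, pos, F, occ, bound_node, col_adj, hop, W,
                                nbr, katt_col, katt_pp, rate, totals)


@njit(cache=True)
def _cascade_candidates(q, pos, status, colbound, occ, bound_node, nbr,
                        stack, nstack):
    """Push bound neighbors of ``q`` that lost their last support."""
    p = pos[q]
    d2 = nbr.shape[1]
    for d in range(d2):
        j = nbr[p, d]
        if j >= 0:
            w = occ[j]
            if w >= 0 and w != q and status[w] == 2 and not colbound[w]:
                supported = False
                for dd in range(d2):
                    jj = nbr[pos[w], dd]
                    if jj >= 0 and bound_node[jj]:
                        supported = True
                if not supported and nstack < stack.shape[0]:
                    stack[nstack] = w
                    nstack += 1
    return nstack


@njit(cache=True)
def _unbind(pid, t, counters, totals, pos, status, F, colbound, rate,
            mlist, mpos, blist, bpos, occ, bound_node, col_adj, hop, W,
            nbr, katt_col, katt_pp, ev_t, ev_kind, ev_pid, ev_node, stack):
    """Detach ``pid`` (and cascade unsupported neighbors) to mobile."""
    nstack = 0
    stack[nstack] = pid
    nstack += 1
    while nstack > 0:
        nstack -= 1
        q = stack[nstack]
        if status[q] == 2:
            _unbind_one(q, t, counters, totals, pos, status, F, colbound,
                        rate, mlist, mpos, blist, bpos, occ, bound_node,
                        col_adj, hop, W, nbr, katt_col, katt_pp,
                        ev_t, ev_kind, ev_pid, ev_node)
            nstack = _cascade_candidates(q, pos, status, colbound, occ,
                                         bound_node, nbr, stack, nstack)


@njit(cache=True)
def _insert(t, counters, totals, pos, status, F, colbound, rate,
            mlist, mpos, occ, bound_node, col_adj, hop, W, nbr,
            inlet_nodes, inlet_cumw, f_init,
            ev_t, ev_kind, ev_pid, ev_node, katt_col, katt_pp):
    """Place one platelet at a flux-weighted inlet node (weighted redraw
    if the sampled node is transiently occupied)."""
    node = -1
    tries = 0
    while node < 0 and tries < 16:
        tries += 1
        k = np.searchsorted(inlet_cumw, np.random.random())
        if k >= inlet_nodes.shape[0]:
            k = inlet_nodes.shape[0] - 1
        cand = inlet_nodes[k]
        if occ[cand] < 0:
            node = cand
    if node >= 0:
        pid = counters[NEXT_PID]
        counters[NEXT_PID] = pid + 1
        pos[pid] = node
        status[pid] = 1
        F[pid] = f_init
        colbound[pid] = False
        occ[node] = pid
        mlist[counters[NM]] = pid
        mpos[pid] = counters[NM]
        counters[NM] += 1
        rate[pid] = _mobile_rate(pid, pos, F, occ, bound_node, col_adj,
                                 hop, W, nbr, katt_col, katt_pp)
        totals[0] += rate[pid]
        _log(ev_t, ev_kind, ev_pid, ev_node, counters, t, EV_INSERT,
             pid, node)
        _refresh_neighbors(node, pid, pos, status, F, occ, bound_node,
                           col_adj, hop, W, nbr, katt_col, katt_pp,
                           rate, totals)
    else:
        counters[NSKIP] += 1


@njit(cache=True)
def _select_pid(x, counters, totals, mlist, blist, rate):
    """Rate-proportional platelet selection (mobile group first)."""
    pid = -1
    if x < totals[0]:
        acc = 0.0
        k = 0
        while pid < 0 and k < counters[NM]:
            q = mlist[k]
            acc += rate[q]
            if x < acc:
                pid = q
            k += 1
        if pid < 0 and counters[NM] > 0:
            pid = mlist[counters[NM] - 1]
    else:
        y = x - totals[0]
        acc = 0.0
        k = 0
        while pid < 0 and k < counters[NB]:
            q = blist[k]
            acc += rate[q]
            if y < acc:
                pid = q
            k += 1
        if pid < 0 and counters[NB] > 0:
            pid = blist[counters[NB] - 1]
    return pid


@njit(cache=True)
def _execute_mobile(pid, t, counters, totals, pos, status, F, colbound,
                    rate, mlist, mpos, blist, bpos, occ, bound_node,
                    col_adj, hop, W, edet, nbr, katt_col, katt_pp,
                    kdet_col, kdet_pp, ev_t, ev_kind, ev_pid, ev_node):
    """Hop (possibly exiting the domain) or attach."""
    p = pos[pid]
    d2 = nbr.shape[1]
    y = np.random.random() * rate[pid]
    acc = 0.0
    chosen = -1
    d = 0
    while chosen < 0 and d < d2:
        j = nbr[p, d]
        if j == EXIT or (j >= 0 and occ[j] < 0):
            acc += hop[p, d]
            if y < acc:
                chosen = d
        d += 1
    if chosen >= 0:
        j = nbr[p, chosen]
        counters[NHOP] += 1
        if j == EXIT:
            occ[p] = -1
            totals[0] -= rate[pid]
            counters[NM] = _list_remove(mlist, mpos, counters[NM], pid)
            status[pid] = 0
            _log(ev_t, ev_kind, ev_pid, ev_node, counters, t, EV_EXIT,
                 pid, p)
            _refresh_neighbors(p, pid, pos, status, F, occ, bound_node,
                               col_adj, hop, W, nbr, katt_col, katt_pp,
                               rate, totals)
        else:
            occ[p] = -1
            occ[j] = pid
            pos[pid] = j
            _refresh_mobile(pid, pos, F, occ, bound_node, col_adj, hop, W,
                            nbr, katt_col, katt_pp, rate, totals)
            _refresh_neighbors(p, pid, pos, status, F, occ, bound_node,
                               col_adj, hop, W, nbr, katt_col, katt_pp,
                               rate, totals)
            _refresh_neighbors(j, pid, pos, status, F, occ, bound_node,
                               col_adj, hop, W, nbr, katt_col, katt_pp,
                               rate, totals)
    else:
        # attachment: bind to everything adjacent
        counters[NM] = _list_remove(mlist, mpos, counters[NM], pid)
        totals[0] -= rate[pid]
        status[pid] = 2
        bound_node[p] = True
        colbound[pid] = col_adj[p]
        blist[counters[NB]] = pid
        bpos[pid] = counters[NB]
        counters[NB] += 1
        rate[pid] = _detach_rate(pid, pos, F, colbound, edet,
                                 kdet_col, kdet_pp)
        totals[1] += rate[pid]
        counters[NATT] += 1
        _log(ev_t, ev_kind, ev_pid, ev_node, counters, t, EV_ATTACH, pid, p)
        _refresh_neighbors(p, pid, pos, status, F, occ, bound_node, col_adj,
                           hop, W, nbr, katt_col, katt_pp, rate, totals)


@njit(cache=True)
def advance(t, t_end, seed, counters, totals, pos, status, F, colbound, rate,
            mlist, mpos, blist, bpos, occ, bound_node, col_adj,
            hop, W, edet, nbr, ins_t, inlet_nodes, inlet_cumw, f_init,
            ev_t, ev_kind, ev_pid, ev_node,
            katt_col, katt_pp, kdet_col, kdet_pp):
    """Run the event loop from ``t`` to ``t_end``; returns the final time."""
    np.random.seed(seed)
    stack = np.empty(4096, dtype=np.int64)
    n_ins = ins_t.shape[0]
    events_since_resync = 0
    now = t
    done = False
    while not done:
        ip = counters[IPTR]
        if ip < n_ins:
            t_ins = ins_t[ip]
        else:
            t_ins = t_end + 1.0
        R = totals[0] + totals[1]
        if R <= 1e-12:
            t_next = t_ins
        else:
            u = np.random.random()
            if u < 1e-300:
                u = 1e-300
            t_next = now + (-np.log(u) / R)
        if t_ins <= t_next and t_ins <= t_end:
            # scheduled insertion comes first (memoryless discard of the
            # exponential draw is exact)
            now = t_ins
            counters[IPTR] = ip + 1
            _insert(now, counters, totals, pos, status, F, colbound, rate,
                    mlist, mpos, occ, bound_node, col_adj, hop, W, nbr,
                    inlet_nodes, inlet_cumw, f_init,
                    ev_t, ev_kind, ev_pid, ev_node, katt_col, katt_pp)
        elif t_next > t_end:
            now = t_end
            done = True
        else:
            now = t_next
            pid = _select_pid(np.random.random() * R, counters, totals,
                              mlist, blist, rate)
            if pid >= 0:
                if status[pid] == 2:
                    _unbind(pid, now, counters, totals, pos, status, F,
                            colbound, rate, mlist, mpos, blist, bpos, occ,
                            bound_node, col_adj, hop, W, nbr, katt_col,
                            katt_pp, ev_t, ev_kind, ev_pid, ev_node, stack)
                else:
                    _execute_mobile(pid, now, counters, totals, pos, status,
                                    F, colbound, rate, mlist, mpos, blist,
                                    bpos, occ, bound_node, col_adj, hop, W,
                                    edet, nbr, katt_col, katt_pp, kdet_col,
                                    kdet_pp, ev_t, ev_kind, ev_pid, ev_node)
                events_since_resync += 1
                if events_since_resync >= 65536:
                    # guard against floating-point drift in running totals
                    events_since_resync = 0
                    recompute_all(counters, totals, mlist, blist, pos,
                                  status, F, colbound, rate, occ, bound_node,
                                  col_adj, hop, W, edet, nbr, katt_col,
                                  katt_pp, kdet_col, kdet_pp)
    return now
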