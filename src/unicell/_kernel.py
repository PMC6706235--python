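"""Numba-compiled update loop.

This mirrors, draw for draw, the reference engine in
:meth:`unicell.world.World.step_update` / ``World._execute_cycle``. Numba
reproduces ``numpy.random.Generator`` streams bit-exactly, so both engines
advance a seeded world along the identical trajectory; the test suite asserts
exact state equality between them. Any semantic change here must be made in
the reference engine too (and vice versa) — the equivalence test will catch a
divergence.

Symbol codes: 0 = COPY, 1 = DIVIDE, 2 = PCD, >= 3 inert.
"""

import numpy as np
from numba import njit

# Same fixed offset table as unicell.world.DX8/DY8.
_DX8 = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
_DY8 = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)


@njit(cache=True)
def _bisect_right(cum, x):
    """First index i with cum[i] > x (== np.searchsorted(cum, x, 'right'))."""
    lo = 0
    hi = cum.shape[0]
    while lo < hi:
        mid = (lo + hi) // 2
        if x < cum[mid]:
            hi = mid
        else:
            lo = mid + 1
    return lo


@njit(cache=True)
def run_updates(genomes, buffers, alive, eligible, merit, mult, ip, progress,
                attempts, births, cycles_exec, ids, birth_upd, latched,
                attempted_now,
                ev_update, ev_cell, ev_kin, ev_nonkin, ev_cheat,
                W, H, L, S, mu, p_success, mode_direct, factor, kil, radius,
                cpo, exclude_original, stack_mult,
                update_start, n_updates, pop, next_id, rng):
    """Advance the world ``n_updates`` updates in place.

    Returns ``(status, updates_done, n_events, pop, next_id)`` with status 0
    on success and 1 on extinction (the partial update is not counted but its
    events are recorded).
    """
    C = W * H
    cum = np.empty(C, np.float64)
    w = np.empty(C, np.float64)
    n_ev = 0
    for step in range(n_updates):
        upd = update_start + step
        # freeze the merit table and the eligibility snapshot for this update;
        # w[c] is the scheduling weight (zeroed on death, newborns stay 0)
        n_elig = 0
        for c in range(C):
            attempted_now[c] = False
            if alive[c]:
                eligible[c] = True
                w[c] = merit[c]
                n_elig += 1
            else:
                eligible[c] = False
                w[c] = 0.0
        total = 0.0
        for c in range(C):
            total += w[c]
            cum[c] = total
        budget = cpo * pop
        granted = 0
        extinct = False
        while granted < budget:
            if n_elig == 0 or total <= 0.0:
                break
            u = rng.random()
            c = _bisect_right(cum, u * total)
            if c >= C:
                c = C - 1
            if not eligible[c]:
                continue  # float plateau edge: redraw
            cycles_exec[c] += 1
            granted += 1
            sym = genomes[c, ip[c]]
            advance = True
            if sym == 0:  # COPY
                pr = progress[c]
                if pr < L:
                    site = genomes[c, pr]
                    new = site
                    if mu > 0.0 and rng.random() < mu:
                        if exclude_original:
                            r = rng.integers(0, S - 1)
                            if r >= site:
                                r += 1
                            new = np.int8(r)
                        else:
                            new = np.int8(rng.integers(0, S))
                    buffers[c, pr] = new
                    progress[c] = pr + 1
            elif sym == 1:  # DIVIDE
                if progress[c] == L:
                    d = rng.integers(0, 8)
                    x = c % W
                    y = c // W
                    nx = (x + _DX8[d]) % W
                    ny = (y + _DY8[d]) % H
                    t = ny * W + nx
                    if alive[t]:
                        alive[t] = False
                        pop -= 1
                        if eligible[t]:
                            eligible[t] = False
                            n_elig -= 1
                        w[t] = 0.0
                        total = 0.0
                        for i in range(C):
                            total += w[i]
                            cum[i] = total
                    for i in range(L):
                        genomes[t, i] = buffers[c, i]
                        buffers[t, i] = 0
                    merit[t] = L * mult[c]
                    mult[t] = 1.0
                    ip[t] = 0
                    progress[t] = 0
                    attempts[t] = 0
                    births[t] = 0
                    cycles_exec[t] = 0
                    latched[t] = False
                    attempted_now[t] = False
                    ids[t] = next_id
                    next_id += 1
                    birth_upd[t] = upd
                    alive[t] = True
                    eligible[t] = False
                    pop += 1
                    births[c] += 1
                    progress[c] = 0
                    ip[c] = 0
                    advance = False
            elif sym == 2:  # PCD
                attempts[c] += 1
                attempted_now[c] = True
                if rng.random() < p_success:
                    n_kin = 0
                    n_nonkin = 0
                    n_cheat = 0
                    x = c % W
                    y = c // W
                    for dy in range(-radius, radius + 1):
                        for dx in range(-radius, radius + 1):
                            if dx == 0 and dy == 0:
                                continue
                            t = ((y + dy) % H) * W + ((x + dx) % W)
                            if not alive[t]:
                                continue
                            hd = 0
                            for i in range(L):
                                if genomes[t, i] != genomes[c, i]:
                                    hd += 1
                                    if hd > kil:
                                        break
                            if hd <= kil:
                                n_kin += 1
                                has_pcd = False
                                for i in range(L):
                                    if genomes[t, i] == 2:
                                        has_pcd = True
                                        break
                                if not has_pcd:
                                    n_cheat += 1
                                if mode_direct and factor != 1.0:
                                    if stack_mult or not latched[t]:
                                        mult[t] *= factor
                                        latched[t] = True
                            else:
                                n_nonkin += 1
                                if (not mode_direct) and factor != 1.0:
                                    if stack_mult or not latched[t]:
                                        mult[t] /= factor
                                        latched[t] = True
                    alive[c] = False
                    pop -= 1
                    if eligible[c]:
                        eligible[c] = False
                        n_elig -= 1
                    w[c] = 0.0
                    total = 0.0
                    for i in range(C):
                        total += w[i]
                        cum[i] = total
                    ev_update[n_ev] = upd
                    ev_cell[n_ev] = c
                    ev_kin[n_ev] = n_kin
                    ev_nonkin[n_ev] = n_nonkin
                    ev_cheat[n_ev] = n_cheat
                    n_ev += 1
                    advance = False
                    if pop == 0:
                        extinct = True
            # inert symbols: no effect
            if advance:
                ip[c] = (ip[c] + 1) % L
            if extinct:
                return 1, step, n_ev, pop, next_id
    return 0, n_updates, n_ev, pop, next_id
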