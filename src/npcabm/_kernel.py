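"""Numba kernels for the discrete-time lattice dynamics.

All state lives in flat numpy arrays owned by :class:`npcabm.engine.Simulation`;
the kernels mutate them in place.  Randomness comes exclusively from numba's
internal MT19937 stream, seeded once per run through :func:`seed_kernel`, so a
seed fully determines a trajectory.

Conventions
-----------
* cells are flat indices ``(x*ny + y)*nz + z`` over an ``(nx, ny, nz)`` grid;
  agent coordinates are kept unwrapped (useful for MSD measurements) and are
  reduced modulo the grid only when the lattice is periodic.
* ``apart[i]`` is the bound partner (-1 if free); ``abrule[i]`` the rule that
  formed the bond.  Bonds are symmetric by construction.
* per-cell and per-species doubly linked lists (``cell_head``/``cnext``/
  ``cprev`` and ``sp_head``/``snext``/``sprev``) support O(occupants)
  neighbourhood scans and O(species size) clamp/reaction passes.
* translocation counters per species: columns 0..3 =
  pore->nucleus, nucleus->pore, pore->cytoplasm, cytoplasm->pore.
"""

import numpy as np
from numba import njit

# error codes returned by run_kernel
ERR_OK = 0
ERR_PAIR_OVERFLOW = 1
ERR_CAPACITY = 2

_EPS = 1e-9


_MASK64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def make_rng_state(seed: int) -> np.ndarray:
    """Initial xorshift64* state from an integer seed (splitmix64 scramble)."""
    x = (int(seed) + 0x9E3779B97F4A7C15) & 0xFFFFFFFFFFFFFFFF
    for _ in range(3):
        x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & 0xFFFFFFFFFFFFFFFF
        x = (x ^ (x >> 27)) * 0x94D049BB133111EB & 0xFFFFFFFFFFFFFFFF
        x = x ^ (x >> 31)
    if x == 0:
        x = 0x9E3779B97F4A7C15
    return np.array([x], dtype=np.uint64)


@njit(cache=True, inline="always")
def _rand(rng):
    """xorshift64* uniform double in [0, 1); fast, seeded, reproducible."""
    x = rng[0]
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    rng[0] = x
    bits = (x * np.uint64(2685821657736338717)) >> np.uint64(11)
    return np.float64(bits) / 9007199254740992.0


@njit(cache=True, inline="always")
def _wrap(v, n):
    v = v % n
    if v < 0:
        v += n
    return v


@njit(cache=True, inline="always")
def _cell_index(x, y, z, ny, nz):
    return (x * ny + y) * nz + z


@njit(cache=True, inline="always")
def _ll_insert(i, cell, cell_head, cnext, cprev):
    h = cell_head[cell]
    cnext[i] = h
    cprev[i] = -1
    if h >= 0:
        cprev[h] = i
    cell_head[cell] = i


@njit(cache=True, inline="always")
def _ll_remove(i, cell, cell_head, cnext, cprev):
    p = cprev[i]
    n = cnext[i]
    if p >= 0:
        cnext[p] = n
    else:
        cell_head[cell] = n
    if n >= 0:
        cprev[n] = p


@njit(cache=True, inline="always")
def _sp_insert(i, sp, sp_head, snext, sprev):
    h = sp_head[sp]
    snext[i] = h
    sprev[i] = -1
    if h >= 0:
        sprev[h] = i
    sp_head[sp] = i


@njit(cache=True, inline="always")
def _sp_remove(i, sp, sp_head, snext, sprev):
    p = sprev[i]
    n = snext[i]
    if p >= 0:
        snext[p] = n
    else:
        sp_head[sp] = n
    if n >= 0:
        sprev[n] = p


@njit(cache=True, inline="always")
def _relocate(
    i, x, y, z, tcell,
    apos, acell, asp, acomp,
    occ, s_vol, cell_head, cnext, cprev,
    region, comp_of_region, trans,
):
    """Move agent *i* to (x, y, z)/tcell, maintaining occupancy, lists and
    translocation counters."""
    old = acell[i]
    vol = s_vol[asp[i]]
    occ[old] -= vol
    if occ[old] < 0.0:
        occ[old] = 0.0
    occ[tcell] += vol
    _ll_remove(i, old, cell_head, cnext, cprev)
    _ll_insert(i, tcell, cell_head, cnext, cprev)
    apos[i, 0] = x
    apos[i, 1] = y
    apos[i, 2] = z
    acell[i] = tcell
    newcomp = comp_of_region[region[tcell]]
    oldcomp = acomp[i]
    if newcomp != oldcomp:
        s = asp[i]
        if oldcomp == 2 and newcomp == 1:
            trans[s, 0] += 1
        elif oldcomp == 1 and newcomp == 2:
            trans[s, 1] += 1
        elif oldcomp == 2 and newcomp == 0:
            trans[s, 2] += 1
        elif oldcomp == 0 and newcomp == 2:
            trans[s, 3] += 1
        elif oldcomp == 0 and newcomp == 1:
            trans[s, 0] += 1
        elif oldcomp == 1 and newcomp == 0:
            trans[s, 2] += 1
        acomp[i] = newcomp


@njit(cache=True, inline="always")
def _neighbor_coords(x, y, z, k, nx, ny, nz, periodic):
    """k-th von Neumann neighbour; returns (ok, x2, y2, z2, cell)."""
    x2 = x
    y2 = y
    z2 = z
    if k == 0:
        x2 = x + 1
    elif k == 1:
        x2 = x - 1
    elif k == 2:
        y2 = y + 1
    elif k == 3:
        y2 = y - 1
    elif k == 4:
        z2 = z + 1
    else:
        z2 = z - 1
    if periodic:
        cx = _wrap(x2, nx)
        cy = _wrap(y2, ny)
        cz = _wrap(z2, nz)
        return True, x2, y2, z2, _cell_index(cx, cy, cz, ny, nz)
    if x2 < 0 or x2 >= nx or y2 < 0 or y2 >= ny or z2 < 0 or z2 >= nz:
        return False, x2, y2, z2, -1
    return True, x2, y2, z2, _cell_index(x2, y2, z2, ny, nz)


@njit(cache=True)
def _movement_phase(
    rng, n_alive, nx, ny, nz, periodic, cell_vol, bound_complex_mobile,
    apos, acell, asp, apart, abrule, acomp, aalive,
    occ, region, accessible, comp_of_region,
    s_pmove, s_vol, s_allowed,
    r_cmob,
    cell_head, cnext, cprev, alive_list,
    trans, order, moved,
):
    m = n_alive
    for k in range(m):
        i = alive_list[k]
        order[k] = i
        moved[i] = False
    # Fisher-Yates shuffle: agent processing order is re-randomised each step
    for k in range(m - 1, 0, -1):
        j = int(_rand(rng) * (k + 1))
        tmp = order[k]
        order[k] = order[j]
        order[j] = tmp
    for idx in range(m):
        i = order[idx]
        if moved[i]:
            continue
        j = apart[i]
        if j >= 0:
            moved[i] = True
            moved[j] = True
            if acell[i] != acell[j]:
                continue  # adjacent-cell bond: complex held in place
            if not bound_complex_mobile:
                continue
            if not r_cmob[abrule[i]]:
                continue
            pa = s_pmove[asp[i]]
            pb = s_pmove[asp[j]]
            pm = pa if pa < pb else pb
            if pm <= 0.0:
                continue
            u = _rand(rng)
            if u >= pm:
                continue
            k6 = int(u * 6.0 / pm)  # direction from the same uniform draw
            if k6 > 5:
                k6 = 5
            ok, x2, y2, z2, tcell = _neighbor_coords(
                apos[i, 0], apos[i, 1], apos[i, 2], k6, nx, ny, nz, periodic
            )
            if not ok or not accessible[tcell]:
                continue
            reg = region[tcell]
            if not s_allowed[asp[i], reg] or not s_allowed[asp[j], reg]:
                continue
            vol = s_vol[asp[i]] + s_vol[asp[j]]
            free = cell_vol - occ[tcell]
            if vol > free + _EPS:
                continue  # volume limit
            # reduced probability: accept with the free-volume fraction
            if occ[tcell] <= _EPS or _rand(rng) < free / cell_vol:
                _relocate(i, x2, y2, z2, tcell, apos, acell, asp, acomp,
                          occ, s_vol, cell_head, cnext, cprev,
                          region, comp_of_region, trans)
                _relocate(j, x2, y2, z2, tcell, apos, acell, asp, acomp,
                          occ, s_vol, cell_head, cnext, cprev,
                          region, comp_of_region, trans)
        else:
            moved[i] = True
            pm = s_pmove[asp[i]]
            if pm <= 0.0:
                continue
            u = _rand(rng)
            if u >= pm:
                continue
            k6 = int(u * 6.0 / pm)
            if k6 > 5:
                k6 = 5
            ok, x2, y2, z2, tcell = _neighbor_coords(
                apos[i, 0], apos[i, 1], apos[i, 2], k6, nx, ny, nz, periodic
            )
            if not ok or not accessible[tcell]:
                continue
            if not s_allowed[asp[i], region[tcell]]:
                continue
            vol = s_vol[asp[i]]
            free = cell_vol - occ[tcell]
            if vol > free + _EPS:
                continue
            if occ[tcell] <= _EPS or _rand(rng) < free / cell_vol:
                _relocate(i, x2, y2, z2, tcell, apos, acell, asp, acomp,
                          occ, s_vol, cell_head, cnext, cprev,
                          region, comp_of_region, trans)


@njit(cache=True)
def _form_bond(
    a, b, rule, cell_vol,
    apos, acell, asp, apart, abrule, acomp,
    occ, s_vol, s_allowed, region,
    cell_head, cnext, cprev, comp_of_region, trans,
):
    apart[a] = b
    apart[b] = a
    abrule[a] = rule
    abrule[b] = rule
    if acell[a] != acell[b]:
        # co-locate the pair in one cell when the volume limit allows;
        # otherwise the bond spans the two adjacent cells
        ca = acell[a]
        cb = acell[b]
        va = s_vol[asp[a]]
        vb = s_vol[asp[b]]
        if vb <= cell_vol - occ[ca] + _EPS and s_allowed[asp[b], region[ca]]:
            _relocate(b, apos[a, 0], apos[a, 1], apos[a, 2], ca,
                      apos, acell, asp, acomp, occ, s_vol,
                      cell_head, cnext, cprev, region, comp_of_region, trans)
        elif va <= cell_vol - occ[cb] + _EPS and s_allowed[asp[a], region[cb]]:
            _relocate(a, apos[b, 0], apos[b, 1], apos[b, 2], cb,
                      apos, acell, asp, acomp, occ, s_vol,
                      cell_head, cnext, cprev, region, comp_of_region, trans)


@njit(cache=True)
def _bind_rule(
    rng, p, pair_cap, nx, ny, nz, periodic, cell_vol,
    apos, acell, asp, apart, abrule, acomp, aalive,
    occ, region, accessible, comp_of_region,
    s_vol, s_allowed,
    r_a, r_b, r_pbind, r_same, r_disp, r_displaceable,
    sp_head, snext,
    cell_head, cnext, cprev,
    trans, pair_a, pair_b,
):
    pb = r_pbind[p]
    if pb <= 0.0:
        return ERR_OK
    a_sp = r_a[p]
    b_sp = r_b[p]
    same = r_same[p]
    disp = r_disp[p]
    npairs = 0
    a = sp_head[a_sp]
    while a >= 0:
        if apart[a] < 0:
            x = apos[a, 0]
            y = apos[a, 1]
            z = apos[a, 2]
            for k in range(7):
                if k == 0:
                    c = acell[a]
                else:
                    ok, _, _, _, c = _neighbor_coords(x, y, z, k - 1, nx, ny, nz, periodic)
                    if not ok:
                        continue
                b = cell_head[c]
                while b >= 0:
                    if b != a and asp[b] == b_sp:
                        free_b = apart[b] < 0
                        displaceable = (
                            disp and apart[b] >= 0 and r_displaceable[abrule[b]]
                        )
                        if free_b or displaceable:
                            if (not same) or b > a:
                                if npairs >= pair_cap:
                                    return ERR_PAIR_OVERFLOW
                                pair_a[npairs] = a
                                pair_b[npairs] = b
                                npairs += 1
                    b = cnext[b]
        a = snext[a]
    # randomised processing order; first success claims both agents
    for k in range(npairs - 1, 0, -1):
        j = int(_rand(rng) * (k + 1))
        ta = pair_a[k]
        pair_a[k] = pair_a[j]
        pair_a[j] = ta
        tb = pair_b[k]
        pair_b[k] = pair_b[j]
        pair_b[j] = tb
    for idx in range(npairs):
        a = pair_a[idx]
        b = pair_b[idx]
        if apart[a] >= 0:
            continue
        if apart[b] >= 0:
            if not (disp and r_displaceable[abrule[b]]):
                continue
        if _rand(rng) < pb:
            old = apart[b]
            if old >= 0:
                # displacement: the competing bond is broken first
                apart[old] = -1
                abrule[old] = -1
                apart[b] = -1
                abrule[b] = -1
            _form_bond(a, b, p, cell_vol, apos, acell, asp, apart, abrule,
                       acomp, occ, s_vol, s_allowed, region,
                       cell_head, cnext, cprev, comp_of_region, trans)
    return ERR_OK


@njit(cache=True)
def _unbind_rule(
    rng, p,
    asp, apart, abrule,
    r_a, r_b, r_punbind, r_same,
    sp_head, snext,
):
    pu = r_punbind[p]
    if pu <= 0.0:
        return
    a_sp = r_a[p]
    same = r_same[p]
    a = sp_head[a_sp]
    while a >= 0:
        nxt = snext[a]
        j = apart[a]
        if j >= 0 and abrule[a] == p and ((not same) or j > a):
            if _rand(rng) < pu:
                apart[a] = -1
                apart[j] = -1
                abrule[a] = -1
                abrule[j] = -1
        a = nxt


@njit(cache=True)
def _spawn(
    sp, x, y, z, cell,
    apos, acell, asp, apart, abrule, acomp, aalive,
    occ, s_vol, region, comp_of_region,
    cell_head, cnext, cprev, sp_head, snext, sprev,
    free_stack, counters, alive_list, alive_pos,
):
    if counters[0] <= 0:
        return -1
    counters[0] -= 1
    i = free_stack[counters[0]]
    apos[i, 0] = x
    apos[i, 1] = y
    apos[i, 2] = z
    acell[i] = cell
    asp[i] = sp
    apart[i] = -1
    abrule[i] = -1
    acomp[i] = comp_of_region[region[cell]]
    aalive[i] = True
    occ[cell] += s_vol[sp]
    _ll_insert(i, cell, cell_head, cnext, cprev)
    _sp_insert(i, sp, sp_head, snext, sprev)
    alive_list[counters[1]] = i
    alive_pos[i] = counters[1]
    counters[1] += 1
    return i


@njit(cache=True)
def _kill(
    i,
    acell, asp, apart, abrule, aalive,
    occ, s_vol,
    cell_head, cnext, cprev, sp_head, snext, sprev,
    free_stack, counters, alive_list, alive_pos,
):
    occ[acell[i]] -= s_vol[asp[i]]
    if occ[acell[i]] < 0.0:
        occ[acell[i]] = 0.0
    _ll_remove(i, acell[i], cell_head, cnext, cprev)
    _sp_remove(i, asp[i], sp_head, snext, sprev)
    aalive[i] = False
    apart[i] = -1
    abrule[i] = -1
    free_stack[counters[0]] = i
    counters[0] += 1
    pos = alive_pos[i]
    last = counters[1] - 1
    moved_agent = alive_list[last]
    alive_list[pos] = moved_agent
    alive_pos[moved_agent] = pos
    counters[1] = last


@njit(cache=True)
def _clamp_phase(
    rng, n_clamps, ny, nz, cell_vol,
    apos, acell, asp, apart, abrule, acomp, aalive,
    occ, s_vol, region, comp_of_region,
    cell_head, cnext, cprev, sp_head, snext, sprev,
    free_stack, counters, alive_list, alive_pos,
    c_sp, c_reg, c_target, c_off, c_cells, c_ins, c_rem,
    scratch,
):
    for c in range(n_clamps):
        sp = c_sp[c]
        reg = c_reg[c]
        target = c_target[c]
        # count free agents of the clamped species inside the clamp region
        cnt = 0
        a = sp_head[sp]
        while a >= 0:
            if apart[a] < 0 and region[acell[a]] == reg:
                cnt += 1
            a = snext[a]
        if cnt < target:
            ncells = c_off[c + 1] - c_off[c]
            if ncells <= 0:
                continue
            need = target - cnt
            for _ in range(need):
                placed = False
                for _try in range(100):
                    cell = c_cells[c_off[c] + int(_rand(rng) * ncells)]
                    if s_vol[sp] <= cell_vol - occ[cell] + _EPS:
                        x = cell // (ny * nz)
                        rem = cell % (ny * nz)
                        y = rem // nz
                        z = rem % nz
                        i = _spawn(sp, x, y, z, cell,
                                   apos, acell, asp, apart, abrule, acomp,
                                   aalive, occ, s_vol, region, comp_of_region,
                                   cell_head, cnext, cprev, sp_head, snext,
                                   sprev, free_stack, counters, alive_list,
                                   alive_pos)
                        if i < 0:
                            return ERR_CAPACITY
                        c_ins[c] += 1
                        placed = True
                        break
                if not placed:
                    break  # region momentarily too crowded; retry next step
        elif cnt > target:
            # collect removable (free, in-region) agents, then drop a random subset
            nfree = 0
            a = sp_head[sp]
            while a >= 0:
                if apart[a] < 0 and region[acell[a]] == reg:
                    scratch[nfree] = a
                    nfree += 1
                a = snext[a]
            excess = cnt - target
            for _ in range(excess):
                j = int(_rand(rng) * nfree)
                i = scratch[j]
                scratch[j] = scratch[nfree - 1]
                nfree -= 1
                _kill(i, acell, asp, apart, abrule, aalive, occ, s_vol,
                      cell_head, cnext, cprev, sp_head, snext, sprev,
                      free_stack, counters, alive_list, alive_pos)
                c_rem[c] += 1
    return ERR_OK


@njit(cache=True)
def _sink_phase(
    n_sinks,
    acell, asp, apart, abrule, aalive,
    occ, s_vol, region,
    cell_head, cnext, cprev, sp_head, snext, sprev,
    free_stack, counters, alive_list, alive_pos,
    snk_a, snk_b, snk_reg, snk_rem,
    scratch,
):
    for s in range(n_sinks):
        a_sp = snk_a[s]
        b_sp = snk_b[s]
        reg = snk_reg[s]
        n = 0
        a = sp_head[a_sp]
        while a >= 0:
            j = apart[a]
            if j >= 0 and asp[j] == b_sp and region[acell[a]] == reg and region[acell[j]] == reg:
                scratch[n] = a
                n += 1
            a = snext[a]
        for k in range(n):
            a = scratch[k]
            j = apart[a]
            _kill(a, acell, asp, apart, abrule, aalive, occ, s_vol,
                  cell_head, cnext, cprev, sp_head, snext, sprev,
                  free_stack, counters, alive_list, alive_pos)
            _kill(j, acell, asp, apart, abrule, aalive, occ, s_vol,
                  cell_head, cnext, cprev, sp_head, snext, sprev,
                  free_stack, counters, alive_list, alive_pos)
            snk_rem[s] += 1


@njit(cache=True)
def _record(
    r, cap, n_species,
    asp, acomp, aalive, trans,
    rec_counts, rec_trans,
):
    for s in range(n_species):
        for c in range(4):
            rec_counts[r, s, c] = 0
            rec_trans[r, s, c] = trans[s, c]
    for i in range(cap):
        if aalive[i]:
            rec_counts[r, asp[i], acomp[i]] += 1


@njit(cache=True)
def run_kernel(
    rng, n_steps, stride, rec_start,
    cap, pair_cap, n_species, n_rules, n_clamps, n_sinks,
    nx, ny, nz, periodic, cell_vol, bound_complex_mobile,
    apos, acell, asp, apart, abrule, acomp, aalive,
    occ, region, accessible, comp_of_region,
    s_pmove, s_vol, s_allowed,
    r_a, r_b, r_pbind, r_punbind, r_same, r_disp, r_displaceable, r_cmob,
    cell_head, cnext, cprev, sp_head, snext, sprev,
    free_stack, counters, alive_list, alive_pos, trans,
    c_sp, c_reg, c_target, c_off, c_cells, c_ins, c_rem,
    snk_a, snk_b, snk_reg, snk_rem,
    order, moved, pair_a, pair_b, evorder, scratch,
    rec_counts, rec_trans,
):
    """Advance *n_steps* timesteps, recording every *stride* steps.

    Returns (error_code, records_written)."""
    r = rec_start
    for t in range(n_steps):
        _movement_phase(
            rng, counters[1], nx, ny, nz, periodic, cell_vol, bound_complex_mobile,
            apos, acell, asp, apart, abrule, acomp, aalive,
            occ, region, accessible, comp_of_region,
            s_pmove, s_vol, s_allowed, r_cmob,
            cell_head, cnext, cprev, alive_list, trans, order, moved,
        )
        # reaction phase: bind and unbind passes over all rules, in an order
        # re-randomised every step so no agent type is systematically favoured
        nev = 2 * n_rules
        for k in range(nev):
            evorder[k] = k
        for k in range(nev - 1, 0, -1):
            j = int(_rand(rng) * (k + 1))
            tmp = evorder[k]
            evorder[k] = evorder[j]
            evorder[j] = tmp
        for k in range(nev):
            ev = evorder[k]
            p = ev // 2
            if ev % 2 == 0:
                err = _bind_rule(
                    rng, p, pair_cap, nx, ny, nz, periodic, cell_vol,
                    apos, acell, asp, apart, abrule, acomp, aalive,
                    occ, region, accessible, comp_of_region,
                    s_vol, s_allowed,
                    r_a, r_b, r_pbind, r_same, r_disp, r_displaceable,
                    sp_head, snext, cell_head, cnext, cprev,
                    trans, pair_a, pair_b,
                )
                if err != ERR_OK:
                    return err, r
            else:
                _unbind_rule(rng, p, asp, apart, abrule,
                             r_a, r_b, r_punbind, r_same, sp_head, snext)
        if n_sinks > 0:
            _sink_phase(
                n_sinks, acell, asp, apart, abrule, aalive,
                occ, s_vol, region,
                cell_head, cnext, cprev, sp_head, snext, sprev,
                free_stack, counters, alive_list, alive_pos,
                snk_a, snk_b, snk_reg, snk_rem, scratch,
            )
        if n_clamps > 0:
            err = _clamp_phase(
                rng, n_clamps, ny, nz, cell_vol,
                apos, acell, asp, apart, abrule, acomp, aalive,
                occ, s_vol, region, comp_of_region,
                cell_head, cnext, cprev, sp_head, snext, sprev,
                free_stack, counters, alive_list, alive_pos,
                c_sp, c_reg, c_target, c_off, c_cells, c_ins, c_rem,
                scratch,
            )
            if err != ERR_OK:
                return err, r
        if stride > 0 and (t + 1) % stride == 0:
            _record(r, cap, n_species, asp, acomp, aalive, trans,
                    rec_counts, rec_trans)
            r += 1
    return ERR_OK, r
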