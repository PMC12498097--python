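"""Numba kernels for the on-lattice tumor engine.

All kernels work on raw grid indices; the founder cell sits at ``(span, span)``
of a ``(2*span+1, 2*span+1)`` occupancy grid whose entries are live-cell
indices (or -1 for empty sites). Cell attribute arrays are kept compact in
``[0, n)``; death swap-removes the last cell into the freed slot.

Randomness comes from numba's internal RNG, seeded once per run by the
caller-supplied seed, so a run is fully reproducible from its seed.
"""

import numpy as np
from numba import njit

# Moore (8-direction) neighborhood rays, in fixed order.
_DX = np.array([1, 1, 0, -1, -1, -1, 0, 1], dtype=np.int64)
_DY = np.array([0, 1, 1, 1, 0, -1, -1, -1], dtype=np.int64)

STATUS_REACHED = 0
STATUS_EXTINCT = 1
STATUS_BOUNDARY = 2
STATUS_MAX_EVENTS = 3


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def eligible_directions(grid, x, y, q):
    """Distance to the nearest empty site along each of the 8 rays.

    Returns an int64[8] array: dist[d] = number of steps (1..q) to the first
    empty site along ray d, or -1 if no empty site lies within q steps
    (walking off the grid also makes a ray ineligible).
    """
    L = grid.shape[0]
    dist = np.full(8, -1, dtype=np.int64)
    for d in range(8):
        dx = _DX[d]
        dy = _DY[d]
        cx = x
        cy = y
        for t in range(1, q + 1):
            cx += dx
            cy += dy
            if cx < 0 or cx >= L or cy < 0 or cy >= L:
                break
            if grid[cx, cy] < 0:
                dist[d] = t
                break
    return dist


@njit(cache=True)
def push_ray(grid, xs, ys, x, y, d, dist):
    """Shift the occupied run at steps 1..dist-1 along ray d one step outward.

    The empty site at step ``dist`` absorbs the far end of the run; the site
    adjacent to the mother (step 1) is left empty and returned as the birth
    site. Cell coordinate arrays are updated in place.
    """
    dx = _DX[d]
    dy = _DY[d]
    for j in range(dist - 1, 0, -1):
        sx = x + j * dx
        sy = y + j * dy
        ci = grid[sx, sy]
        grid[sx + dx, sy + dy] = ci
        grid[sx, sy] = -1
        xs[ci] = sx + dx
        ys[ci] = sy + dy
    return x + dx, y + dy


@njit(cache=True)
def binomial_split(copies):
    """Duplicate to 2*copies and split Binomial(2*copies, 1/2)."""
    total = 2 * copies
    if total == 0:
        return 0, 0
    a = np.random.binomial(total, 0.5)
    return a, total - a


@njit(cache=True)
def _round_half_even(x):
    f = np.floor(x)
    r = x - f
    i = int(f)
    if r > 0.5:
        return i + 1
    if r < 0.5:
        return i
    return i if i % 2 == 0 else i + 1


@njit(cache=True)
def cosegregate_split(c1, c2, rho):
    """Correlated split of two species with cosegregation strength rho.

    Copies duplicate to 2*c1 and 2*c2; round_half_even(rho*min(2c1, 2c2))
    cross-species pairs each follow a single fair coin into one daughter;
    all unpaired copies segregate independently. Returns (a1, b1, a2, b2)
    with a1+b1 = 2*c1 and a2+b2 = 2*c2.
    """
    t1 = 2 * c1
    t2 = 2 * c2
    m = t1 if t1 < t2 else t2
    npair = _round_half_even(rho * m)
    if npair > 0:
        h = np.random.binomial(npair, 0.5)
    else:
        h = 0
    a1 = h
    if t1 - npair > 0:
        a1 += np.random.binomial(t1 - npair, 0.5)
    a2 = h
    if t2 - npair > 0:
        a2 += np.random.binomial(t2 - npair, 0.5)
    return a1, t1 - a1, a2, t2 - a2


@njit(cache=True)
def run_single(k, s, q, d, n_final, span, seed, max_events):
    """Single-species spatial run to n_final cells (or extinction)."""
    np.random.seed(seed)
    L = 2 * span + 1
    grid = np.full((L, L), -1, dtype=np.int32)
    cap = n_final + 1
    xs = np.empty(cap, np.int64)
    ys = np.empty(cap, np.int64)
    copies = np.zeros(cap, np.int64)
    xs[0] = span
    ys[0] = span
    copies[0] = k
    grid[span, span] = 0
    n = 1
    n_pos = 1 if k > 0 else 0
    rmax = 1.0 + s if s > 0.0 else 1.0
    qe = q if q < L else L
    t = 0.0
    events = 0
    status = STATUS_MAX_EVENTS
    while events < max_events:
        if n >= n_final:
            status = STATUS_REACHED
            break
        if n <= 0:
            status = STATUS_EXTINCT
            break
        r_div = n + s * n_pos
        r_tot = r_div + d * n
        t += np.random.exponential(1.0 / r_tot)
        events += 1
        if np.random.random() * r_tot < d * n:
            # death of a uniformly chosen cell
            i = int(np.random.random() * n)
            if copies[i] > 0:
                n_pos -= 1
            grid[xs[i], ys[i]] = -1
            last = n - 1
            if i != last:
                xs[i] = xs[last]
                ys[i] = ys[last]
                copies[i] = copies[last]
                grid[xs[i], ys[i]] = i
            n = last
            continue
        # division: cell chosen proportional to its rate (rejection on rmax)
        while True:
            i = int(np.random.random() * n)
            ri = 1.0 + s if copies[i] > 0 else 1.0
            if np.random.random() * rmax < ri:
                break
        dist = eligible_directions(grid, xs[i], ys[i], qe)
        nel = 0
        for dd in range(8):
            if dist[dd] > 0:
                nel += 1
        if nel == 0:
            continue  # blocked division: event consumed, no birth
        pick = int(np.random.random() * nel)
        dd = 0
        for j in range(8):
            if dist[j] > 0:
                if pick == 0:
                    dd = j
                    break
                pick -= 1
        fx = xs[i] + dist[dd] * _DX[dd]
        fy = ys[i] + dist[dd] * _DY[dd]
        if fx <= 0 or fx >= L - 1 or fy <= 0 or fy >= L - 1:
            status = STATUS_BOUNDARY
            break
        bx, by = push_ray(grid, xs, ys, xs[i], ys[i], dd, dist[dd])
        a, b = binomial_split(copies[i])
        if copies[i] > 0 and a == 0:
            n_pos -= 1
        copies[i] = a
        xs[n] = bx
        ys[n] = by
        copies[n] = b
        grid[bx, by] = n
        if b > 0:
            n_pos += 1
        n += 1
    return status, n, xs[:n].copy(), ys[:n].copy(), copies[:n].copy(), t, events


@njit(cache=True)
def _cls2(a, b, mode):
    """Fitness class of a two-type cell.

    mode 0 (wild-type/variant): 2 if any variant copy, 1 if wt-only, 0 if free.
    mode 1 (two species): 2 if both species present, 1 if exactly one, 0 free.
    """
    if mode == 0:
        if b > 0:
            return 2
        if a > 0:
            return 1
        return 0
    if a > 0 and b > 0:
        return 2
    if a > 0 or b > 0:
        return 1
    return 0


@njit(cache=True)
def run_two_type(k1, k2, s1, s2, rate_mode, rho, vvar, q, d, n_final, span,
                 seed, max_events):
    """Two-type spatial run (wild-type/variant or two-species).

    rate_mode selects the fitness-class rule (see ``_cls2``); rates are
    [1, 1+s1, 1+s2] per class. rho couples segregation of the two types
    (0 = independent). vvar > 0 converts one type-1 copy (chosen per-copy
    uniformly across the population) to type 2 when n_cells first reaches
    vvar; vvar <= 0 disables the trigger.

    Returns (status, n, xs, ys, c1, c2, time, events, trig_n, var_created).
    """
    np.random.seed(seed)
    L = 2 * span + 1
    grid = np.full((L, L), -1, dtype=np.int32)
    cap = n_final + 1
    xs = np.empty(cap, np.int64)
    ys = np.empty(cap, np.int64)
    c1 = np.zeros(cap, np.int64)
    c2 = np.zeros(cap, np.int64)
    xs[0] = span
    ys[0] = span
    c1[0] = k1
    c2[0] = k2
    grid[span, span] = 0
    n = 1
    ncls = np.zeros(3, np.int64)
    ncls[_cls2(k1, k2, rate_mode)] = 1
    rates = np.empty(3)
    rates[0] = 1.0
    rates[1] = 1.0 + s1
    rates[2] = 1.0 + s2
    rmax = rates[0]
    for j in range(1, 3):
        if rates[j] > rmax:
            rmax = rates[j]
    qe = q if q < L else L
    t = 0.0
    events = 0
    triggered = vvar <= 0
    trig_n = -1
    var_created = 0
    status = STATUS_MAX_EVENTS
    while events < max_events:
        if (not triggered) and n >= vvar:
            wtot = 0
            for j in range(n):
                wtot += c1[j]
            if wtot > 0:
                rr = np.random.random() * wtot
                acc = 0.0
                tgt = 0
                for j in range(n):
                    acc += c1[j]
                    if rr < acc:
                        tgt = j
                        break
                oc = _cls2(c1[tgt], c2[tgt], rate_mode)
                c1[tgt] -= 1
                c2[tgt] += 1
                ncls[oc] -= 1
                ncls[_cls2(c1[tgt], c2[tgt], rate_mode)] += 1
                var_created = 1
            trig_n = n
            triggered = True
        if n >= n_final:
            status = STATUS_REACHED
            break
        if n <= 0:
            status = STATUS_EXTINCT
            break
        r_div = ncls[0] * rates[0] + ncls[1] * rates[1] + ncls[2] * rates[2]
        r_tot = r_div + d * n
        t += np.random.exponential(1.0 / r_tot)
        events += 1
        if np.random.random() * r_tot < d * n:
            i = int(np.random.random() * n)
            ncls[_cls2(c1[i], c2[i], rate_mode)] -= 1
            grid[xs[i], ys[i]] = -1
            last = n - 1
            if i != last:
                xs[i] = xs[last]
                ys[i] = ys[last]
                c1[i] = c1[last]
                c2[i] = c2[last]
                grid[xs[i], ys[i]] = i
            n = last
            continue
        while True:
            i = int(np.random.random() * n)
            ri = rates[_cls2(c1[i], c2[i], rate_mode)]
            if np.random.random() * rmax < ri:
                break
        dist = eligible_directions(grid, xs[i], ys[i], qe)
        nel = 0
        for dd in range(8):
            if dist[dd] > 0:
                nel += 1
        if nel == 0:
            continue
        pick = int(np.random.random() * nel)
        dd = 0
        for j in range(8):
            if dist[j] > 0:
                if pick == 0:
                    dd = j
                    break
                pick -= 1
        fx = xs[i] + dist[dd] * _DX[dd]
        fy = ys[i] + dist[dd] * _DY[dd]
        if fx <= 0 or fx >= L - 1 or fy <= 0 or fy >= L - 1:
            status = STATUS_BOUNDARY
            break
        bx, by = push_ray(grid, xs, ys, xs[i], ys[i], dd, dist[dd])
        old_cls = _cls2(c1[i], c2[i], rate_mode)
        a1, b1, a2, b2 = cosegregate_split(c1[i], c2[i], rho)
        c1[i] = a1
        c2[i] = a2
        xs[n] = bx
        ys[n] = by
        c1[n] = b1
        c2[n] = b2
        grid[bx, by] = n
        ncls[old_cls] -= 1
        ncls[_cls2(a1, a2, rate_mode)] += 1
        ncls[_cls2(b1, b2, rate_mode)] += 1
        n += 1
    return (status, n, xs[:n].copy(), ys[:n].copy(), c1[:n].copy(),
            c2[:n].copy(), t, events, trig_n, var_created)
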