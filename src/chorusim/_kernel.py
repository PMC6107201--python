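"""Compiled inner loop of the single-night simulation.

The cycle loop runs thousands of times per night over tiny agent arrays, so
it is written as explicit loops and JIT-compiled with numba.  The per-female
selection logic here must agree choice-for-choice with the scalar reference
functions in :mod:`chorusim.strategies`; the test suite asserts this on
random states.

Randomness used inside the loop (random-strategy target draws, the one-cycle
random-walk direction of threshold females that give up, and mating-conflict
tie-breaks) is pre-drawn by the caller into pools consumed sequentially, so
the whole run is a pure function of its inputs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# strategy kind codes
KIND_BEST_OF_N = 0
KIND_BEST_OF_N_NO_SWITCH = 1
KIND_MIN_THRESHOLD = 2
KIND_RANDOM = 3

# status codes
SEARCHING = 0
MATED = 1
REMOVED = 2

# retarget reason codes
REASON_INIT = 0
REASON_TARGET_MATED = 1
REASON_BETTER_MALE = 2

#: event buffer columns: cycle, female, old target (-1 none), new target,
#: old pulse (-1 none), new pulse, reason
EVENT_COLS = 7


@njit(cache=True)
def _pick_best_of_n(f: int, fx, fy, male_x, male_y, pulse, alive,
                    n_alive: int, n: int, d2_scratch, sel_scratch) -> int:
    """Highest-pulse male among the n closest available ones; pulse ties go
    to the nearer male, distance ties to the lower id (selection order)."""
    M = male_x.size
    for m in range(M):
        dx = male_x[m] - fx[f]
        dy = male_y[m] - fy[f]
        d2_scratch[m] = dx * dx + dy * dy
        sel_scratch[m] = False
    n_eff = n if n < n_alive else n_alive
    best = -1
    best_pn = -1
    for _ in range(n_eff):
        mi = -1
        md = np.inf
        for m in range(M):
            if alive[m] and not sel_scratch[m] and d2_scratch[m] < md:
                md = d2_scratch[m]
                mi = m
        if mi < 0:
            break
        sel_scratch[mi] = True
        if pulse[mi] > best_pn:  # strict: earlier (nearer) picks win ties
            best_pn = pulse[mi]
            best = mi
    return best


@njit(cache=True)
def _pick_min_threshold(f: int, fx, fy, male_x, male_y, pulse, alive,
                        theta: int) -> int:
    """Closest available male with pulse >= theta; -1 when none exists."""
    best = -1
    bd = np.inf
    for m in range(male_x.size):
        if alive[m] and pulse[m] >= theta:
            dx = male_x[m] - fx[f]
            dy = male_y[m] - fy[f]
            d2 = dx * dx + dy * dy
            if d2 < bd:  # strict: exact ties keep the lower id
                bd = d2
                best = m
    return best


@njit(cache=True)
def simulate_night(
    male_x, male_y, pulse,
    fx, fy,
    kind: int, param: int,
    speed: float, contact_radius: float,
    width: float, depth: float,
    max_cycles: int,
    walk_angles,   # one uniform angle per female
    choice_pool,   # uniforms for random-strategy draws
    tie_pool,      # uniforms for mating-conflict tie-breaks
    record_events: bool,
    events,        # (cap, EVENT_COLS) int64 buffer
):
    """Run the cycle loop; mutates fx/fy in place and returns
    (status, mate_pn, dist, n_targets, cycles_active, cycles, hit_limit,
    n_events)."""
    M = male_x.size
    F = fx.size
    alive = np.ones(M, np.bool_)
    status = np.zeros(F, np.int8)
    target = np.full(F, -1, np.int64)
    dist = np.zeros(F)
    n_targets = np.zeros(F, np.int64)
    cycles_active = np.zeros(F, np.int64)
    mate_pn = np.full(F, -1, np.int64)
    rem = np.zeros(F)

    d2_scratch = np.empty(M)
    sel_scratch = np.zeros(M, np.bool_)
    touched = np.empty(M, np.int64)
    best_rem = np.empty(M)
    tie_count = np.zeros(M, np.int64)

    wi = 0  # walk-angle pool index
    ci = 0  # choice pool index
    ti = 0  # tie pool index
    n_events = 0
    ev_cap = events.shape[0]

    n_alive = M
    n_searching = F
    cycle = 0
    hit_limit = False

    while n_searching > 0:
        if cycle >= max_cycles:
            hit_limit = True
            for f in range(F):
                if status[f] == SEARCHING:
                    status[f] = REMOVED
                    cycles_active[f] = cycle
            break
        cycle += 1
        if n_alive == 0:
            # unreachable while females never outnumber males; give up
            for f in range(F):
                if status[f] == SEARCHING:
                    status[f] = REMOVED
                    cycles_active[f] = cycle
            break

        # ---- phase 1: retarget ----------------------------------------
        for f in range(F):
            if status[f] != SEARCHING:
                continue
            cur = target[f]
            cur_ok = cur >= 0 and alive[cur]
            if kind == KIND_BEST_OF_N:
                cand = _pick_best_of_n(f, fx, fy, male_x, male_y, pulse,
                                       alive, n_alive, param,
                                       d2_scratch, sel_scratch)
                if cur_ok and pulse[cand] <= pulse[cur]:
                    continue  # keep the standing target unless strictly better
                new = cand
            elif cur_ok:
                continue  # event-driven rules keep a living target
            elif kind == KIND_BEST_OF_N_NO_SWITCH:
                new = _pick_best_of_n(f, fx, fy, male_x, male_y, pulse,
                                      alive, n_alive, param,
                                      d2_scratch, sel_scratch)
            elif kind == KIND_MIN_THRESHOLD:
                new = _pick_min_threshold(f, fx, fy, male_x, male_y, pulse,
                                          alive, param)
            else:  # KIND_RANDOM
                k = int(choice_pool[ci] * n_alive)
                if k >= n_alive:
                    k = n_alive - 1
                ci += 1
                new = -1
                seen = 0
                for m in range(M):
                    if alive[m]:
                        if seen == k:
                            new = m
                            break
                        seen += 1
            if new < 0:
                # no acceptable male: one random-walk step, then leave unmated
                ang = walk_angles[wi]
                wi += 1
                nx = fx[f] + speed * np.cos(ang)
                ny = fy[f] + speed * np.sin(ang)
                fx[f] = min(max(nx, 0.0), width)
                fy[f] = min(max(ny, 0.0), depth)
                dist[f] += speed
                status[f] = REMOVED
                cycles_active[f] = cycle
                n_searching -= 1
            elif new != cur:
                n_targets[f] += 1
                if record_events and n_events < ev_cap:
                    if cur < 0:
                        reason = REASON_INIT
                    elif alive[cur]:
                        reason = REASON_BETTER_MALE
                    else:
                        reason = REASON_TARGET_MATED
                    events[n_events, 0] = cycle
                    events[n_events, 1] = f
                    events[n_events, 2] = cur
                    events[n_events, 3] = new
                    events[n_events, 4] = pulse[cur] if cur >= 0 else -1
                    events[n_events, 5] = pulse[new]
                    events[n_events, 6] = reason
                    n_events += 1
                target[f] = new

        # ---- phase 2: move --------------------------------------------
        for f in range(F):
            if status[f] != SEARCHING:
                continue
            m = target[f]
            dx = male_x[m] - fx[f]
            dy = male_y[m] - fy[f]
            d = np.sqrt(dx * dx + dy * dy)
            if d <= speed:
                fx[f] = male_x[m]
                fy[f] = male_y[m]
                dist[f] += d
                rem[f] = 0.0
            else:
                fx[f] += dx / d * speed
                fy[f] += dy / d * speed
                dist[f] += speed
                rem[f] = d - speed

        # ---- phase 3: mating resolution -------------------------------
        n_touched = 0
        for f in range(F):
            if status[f] != SEARCHING or rem[f] > contact_radius:
                continue
            m = target[f]
            if tie_count[m] == 0:
                touched[n_touched] = m
                n_touched += 1
                best_rem[m] = rem[f]
                tie_count[m] = 1
            elif rem[f] < best_rem[m]:
                best_rem[m] = rem[f]
                tie_count[m] = 1
            elif rem[f] == best_rem[m]:
                tie_count[m] += 1
        for j in range(n_touched):
            m = touched[j]
            k = tie_count[m]
            pick = 0
            if k > 1:
                pick = int(tie_pool[ti] * k)
                if pick >= k:
                    pick = k - 1
                ti += 1
            seen = 0
            for f in range(F):
                if (status[f] == SEARCHING and target[f] == m
                        and rem[f] == best_rem[m]):
                    if seen == pick:
                        status[f] = MATED
                        mate_pn[f] = pulse[m]
                        cycles_active[f] = cycle
                        alive[m] = False
                        n_alive -= 1
                        n_searching -= 1
                        break
                    seen += 1
            tie_count[m] = 0

    return (status, mate_pn, dist, n_targets, cycles_active, cycle,
            hit_limit, n_events)
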