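"""Numba inner loop for the Moran valley process.

One elementary step = one fitness-proportional birth plus one uniform death.
The kernel keeps, per individual: evolutionary stage, a ring/compact buffer of
active effect contributions (log(m) on the multiplicative scale, m-1 on the
additive scale), a cached background sum and a cached absolute fitness.  The
background is re-summed from the buffer at every division of that individual,
so no floating-point drift accumulates in bounded buffers.
"""

import numpy as np
from numba import njit

EPS = 1e-9

# lifetime-mode codes
MODE_DET = 0
MODE_GEOM = 1
MODE_INF = 2


@njit(cache=True, inline="always")
def _draw_m(fam, V, p1, p2):
    """One effect draw. fam: 0 lognormal(p1=mu,p2=sigma), 1 gamma(shape,scale),
    2 laplace(loc1,scale), 3 bernoulli(p1=lo,p2=hi)."""
    if V == 0.0:
        return 1.0
    if fam == 0:
        m = np.exp(p1 + p2 * np.random.standard_normal())
    elif fam == 1:
        m = np.random.gamma(p1, p2)
    elif fam == 2:
        u = np.random.random() - 0.5
        if u >= 0.0:
            m = 1.0 - p2 * np.log(1.0 - 2.0 * u)
        else:
            m = 1.0 + p2 * np.log(1.0 + 2.0 * u)
    else:
        m = p1 if np.random.random() < 0.5 else p2
    if m < EPS:
        m = EPS
    return m


@njit(cache=True, inline="always")
def _fitness(r, bg, mult):
    if mult:
        return r * np.exp(bg)
    w = r + bg
    return w if w > EPS else EPS


@njit(cache=True)
def run_core(
    N,
    t_max,
    seed,
    fam,
    V,
    tau,  # int; ignored for MODE_INF
    mode,
    mult,  # boolean: multiplicative scale
    p1,
    p2,  # family parameters, see _draw_m
    r0,
    r1,
    r2,
    u1,
    u2,
    init_s1,  # number of initial intermediate-stage individuals
    snap_steps,  # int64[:], sorted ascending, elementary steps to snapshot
    stride,  # int64; 0 disables the trace
    rec_cap,
    cap,  # per-individual buffer capacity
):
    np.random.seed(seed)

    rr = np.empty(3)
    rr[0], rr[1], rr[2] = r0, r1, r2

    stage = np.zeros(N, np.int8)
    for i in range(init_s1):
        stage[i] = 1
    contrib = np.zeros((N, cap))
    cnt = np.zeros(N, np.int64)
    head = np.zeros(N, np.int64)  # ring start, deterministic mode only
    bg = np.zeros(N)
    if not mult:
        pass  # additive: empty buffer => offset 0, fitness r_j
    w = np.empty(N)
    for i in range(N):
        w[i] = _fitness(rr[stage[i]], 0.0, mult)
    orig1 = np.full(N, -1, np.int64)
    orig2 = np.full(N, -1, np.int64)

    cnts = np.zeros(3, np.int64)
    cnts[0] = N - init_s1
    cnts[1] = init_s1

    # mutant-birth records
    rec_step = np.empty(rec_cap, np.int64)
    rec_stage = np.empty(rec_cap, np.int8)
    rec_relfit = np.empty(rec_cap, np.float64)
    nrec = 0
    n_s1_births = 0
    n_s2_births = 0

    # trace of population state every `stride` steps (step 0 included)
    n_tr_cap = (t_max // stride + 2) if stride > 0 else 0
    tr_step = np.empty(n_tr_cap, np.int64)
    tr_cnt = np.empty((n_tr_cap, 3), np.int64)
    tr_meanw = np.empty(n_tr_cap)
    tr_varw = np.empty(n_tr_cap)
    ntr = 0
    if stride > 0:
        tr_step[0] = 0
        tr_cnt[0, 0], tr_cnt[0, 1], tr_cnt[0, 2] = cnts[0], cnts[1], cnts[2]
        tr_meanw[0] = w.mean()
        tr_varw[0] = w.var()
        ntr = 1

    n_snap = snap_steps.shape[0]
    snap_w = np.empty((n_snap, N))
    snap_stage = np.empty((n_snap, N), np.int8)
    isnap = 0

    s1_fix = np.int64(-1)
    s2_fix = np.int64(-1)
    # with no inflow of mutants the stage composition can become absorbing
    absorbing_ok = (u1 == 0.0) and (n_snap == 0) and (stride == 0)

    inv_tau = 1.0 / tau if (mode == MODE_GEOM and tau > 0) else 0.0
    step = np.int64(0)
    for step_i in range(1, t_max + 1):
        step = np.int64(step_i)
        # --- choose reproducer proportional to fitness
        W = 0.0
        for i in range(N):
            W += w[i]
        target = np.random.random() * W
        mom = N - 1
        acc = 0.0
        for i in range(N):
            acc += w[i]
            if target < acc:
                mom = i
                break
        # --- choose death target uniformly among the other N-1
        d = np.random.randint(0, N - 1)
        if d >= mom:
            d += 1

        # --- division: mother acquires this division's effect(s)
        if V > 0.0:
            if mode == MODE_DET:
                m = _draw_m(fam, V, p1, p2)
                c = np.log(m) if mult else m - 1.0
                if cnt[mom] == tau:
                    old = contrib[mom, head[mom]]
                    contrib[mom, head[mom]] = c
                    h = head[mom] + 1
                    if h == tau:
                        h = 0
                        # full re-sum once per tau divisions bounds fp drift
                        s = 0.0
                        for k in range(tau):
                            s += contrib[mom, k]
                        bg[mom] = s
                    else:
                        bg[mom] += c - old
                    head[mom] = h
                else:
                    contrib[mom, cnt[mom]] = c
                    cnt[mom] += 1
                    bg[mom] += c
            elif mode == MODE_GEOM:
                j = 0
                for k in range(cnt[mom]):
                    if np.random.random() >= inv_tau:
                        contrib[mom, j] = contrib[mom, k]
                        j += 1
                n_new = np.random.poisson(1.0)
                for k in range(n_new):
                    m = _draw_m(fam, V, p1, p2)
                    c = np.log(m) if mult else m - 1.0
                    if j < cap:
                        contrib[mom, j] = c
                        j += 1
                cnt[mom] = j
                s = 0.0
                for k in range(j):
                    s += contrib[mom, k]
                bg[mom] = s
            else:  # MODE_INF: permanent effects, single accumulator
                m = _draw_m(fam, V, p1, p2)
                bg[mom] += np.log(m) if mult else m - 1.0

        # --- the second daughter replaces the dead individual
        old_stage = stage[d]
        if old_stage != stage[mom]:
            cnts[old_stage] -= 1
            cnts[stage[mom]] += 1
        stage[d] = stage[mom]
        bg[d] = bg[mom]
        cnt[d] = cnt[mom]
        head[d] = head[mom]
        if V > 0.0 and mode != MODE_INF:
            for k in range(cnt[mom]):
                contrib[d, k] = contrib[mom, k]
        orig1[d] = orig1[mom]
        orig2[d] = orig2[mom]

        # --- the replacing daughter may advance one evolutionary stage
        mutated = False
        st = stage[d]
        if st == 0:
            if u1 > 0.0 and np.random.random() < u1:
                stage[d] = 1
                cnts[0] -= 1
                cnts[1] += 1
                orig1[d] = nrec if nrec < rec_cap else -2
                orig2[d] = -1
                n_s1_births += 1
                mutated = True
        elif st == 1:
            if u2 > 0.0 and np.random.random() < u2:
                stage[d] = 2
                cnts[1] -= 1
                cnts[2] += 1
                orig2[d] = nrec if nrec < rec_cap else -2
                n_s2_births += 1
                mutated = True

        # --- refresh cached fitnesses
        w[mom] = _fitness(rr[stage[mom]], bg[mom], mult)
        w[d] = _fitness(rr[stage[d]], bg[d], mult)

        if mutated and nrec < rec_cap:
            Wn = 0.0
            for i in range(N):
                Wn += w[i]
            rec_step[nrec] = step
            rec_stage[nrec] = stage[d]
            rec_relfit[nrec] = w[d] * N / Wn
            nrec += 1

        # --- fixation bookkeeping
        if s1_fix < 0 and cnts[1] == N:
            s1_fix = step
        if cnts[2] == N:
            s2_fix = step

        # --- traces / snapshots
        if stride > 0 and step % stride == 0:
            tr_step[ntr] = step
            tr_cnt[ntr, 0], tr_cnt[ntr, 1], tr_cnt[ntr, 2] = cnts[0], cnts[1], cnts[2]
            tr_meanw[ntr] = w.mean()
            tr_varw[ntr] = w.var()
            ntr += 1
        if isnap < n_snap and step == snap_steps[isnap]:
            for i in range(N):
                snap_w[isnap, i] = w[i]
                snap_stage[isnap, i] = stage[i]
            isnap += 1

        if s2_fix >= 0:
            break
        if absorbing_ok and cnts[1] == 0 and cnts[2] == 0:
            break  # all-S0 with u1 = 0: no further stage dynamics possible
        if absorbing_ok and u2 == 0.0 and cnts[1] == N:
            break  # all-S1 with u2 = 0: S2 can never arise

    # which recorded mutants founded the lineage present at final-stage fixation
    rec_success = np.zeros(rec_cap, np.bool_)
    if s2_fix >= 0:
        for i in range(N):
            if orig1[i] >= 0:
                rec_success[orig1[i]] = True
            if orig2[i] >= 0:
                rec_success[orig2[i]] = True

    return (
        s1_fix,
        s2_fix,
        step,
        n_s1_births,
        n_s2_births,
        nrec,
        rec_step[:nrec],
        rec_stage[:nrec],
        rec_relfit[:nrec],
        rec_success[:nrec],
        ntr,
        tr_step[:ntr],
        tr_cnt[:ntr],
        tr_meanw[:ntr],
        tr_varw[:ntr],
        isnap,
        snap_w,
        snap_stage,
    )
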