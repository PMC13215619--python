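"""Jit-compiled inner loops for the built-in Holling-II channel systems.

These kernels hard-code the three built-in closures (0 = bernoulli,
1 = effective, 2 = split) for speed; arbitrary user-supplied (S, f)
systems go through the pure-Python paths in :mod:`rmstoch.ssa`.

Each kernel seeds numba's internal RNG from a 32-bit state derived at the
call site from a numpy ``SeedSequence``, so replicate streams are
independent and order-independent.
"""

from __future__ import annotations

import numpy as np
from numba import njit

BERNOULLI = 0
EFFECTIVE = 1
SPLIT = 2

CLOSURE_CODES = {"bernoulli": BERNOULLI, "effective": EFFECTIVE, "split": SPLIT}


@njit(cache=True)
def ssa_core(
    code,
    m,
    c,
    k,
    e,
    omega,
    xn0,
    xp0,
    t_max,
    max_events,
    seed,
    record,
    rec_t,
    rec_xn,
    rec_xp,
    rec_ev,
    stop_on_face,
):
    """Gillespie direct method for the integer-valued closures.

    Returns (n_rec, terminal_code, t, xn, xp, face, face_time, n_events)
    with terminal codes 0 = t_max, 1 = max_events, 2 = frozen, and face
    codes 0 = none, 1 = prey axis (XN=0 first), 2 = predator axis,
    3 = corner.
    """
    np.random.seed(seed)
    t = 0.0
    xn = xn0
    xp = xp0
    n_rec = 0
    if record:
        rec_t[0] = 0.0
        rec_xn[0] = xn
        rec_xp[0] = xp
        rec_ev[0] = 0
        n_rec = 1
    face = 0
    face_time = -1.0
    if xn == 0 and xp == 0:
        face = 3
        face_time = 0.0
    elif xn == 0:
        face = 1
        face_time = 0.0
    elif xp == 0:
        face = 2
        face_time = 0.0
    term = 0
    n_events = 0
    while True:
        if stop_on_face and face != 0:
            break
        N = xn / omega
        P = xp / omega
        fp = m * N * P / (1.0 + N)
        lam0 = omega * N
        lam1 = omega * N * N / k
        lam2 = omega * c * P
        if code == BERNOULLI:
            lam3 = omega * e * fp
            lam4 = omega * (1.0 - e) * fp
        else:  # split (effective is refused upstream)
            lam3 = omega * fp
            lam4 = omega * e * fp
        tot = lam0 + lam1 + lam2 + lam3 + lam4
        if tot <= 0.0:
            term = 2
            break
        if n_events >= max_events:
            term = 1
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        dt = -np.log(u) / tot
        if t + dt > t_max:
            t = t_max
            term = 0
            break
        t += dt
        v = np.random.random() * tot
        if v < lam0:
            ev = 1
            xn += 1
        elif v < lam0 + lam1:
            ev = 2
            xn -= 1
        elif v < lam0 + lam1 + lam2:
            ev = 3
            xp -= 1
        elif v < lam0 + lam1 + lam2 + lam3:
            ev = 4
            if code == BERNOULLI:
                xn -= 1
                xp += 1
            else:
                xn -= 1
        else:
            ev = 5
            if code == BERNOULLI:
                xn -= 1
            else:
                xp += 1
        n_events += 1
        if face == 0:
            if xn == 0 and xp == 0:
                face = 3
                face_time = t
            elif xn == 0:
                face = 1
                face_time = t
            elif xp == 0:
                face = 2
                face_time = t
        if record and n_rec < rec_t.shape[0]:
            rec_t[n_rec] = t
            rec_xn[n_rec] = xn
            rec_xp[n_rec] = xp
            rec_ev[n_rec] = ev
            n_rec += 1
    return n_rec, term, t, xn, xp, face, face_time, n_events


@njit(cache=True)
def em_core(
    code,
    m,
    c,
    k,
    e,
    omega,
    n0,
    p0,
    dt,
    n_steps,
    seed,
    event_fact,
    absorbed_mode,
    clip_eps,
    stride,
    rec_n,
    rec_p,
):
    """Euler-Maruyama loop for the chemical Langevin densities.

    Records every ``stride``-th step into ``rec_n``/``rec_p`` (index 0 is
    the initial state).  In absorbed mode the first proposal leaving the
    open quadrant is projected onto the boundary, the path frozen, and
    the remaining record slots filled with the frozen state; in
    open-proxy mode components below ``clip_eps`` are raised to ``clip_eps``.

    Returns (tau, face, N, P) with tau = -1.0 when never absorbed.
    """
    np.random.seed(seed)
    N = n0
    P = p0
    rec_n[0] = N
    rec_p[0] = P
    j = 1
    tau = -1.0
    face = 0
    sqdt = np.sqrt(dt)
    for i in range(1, n_steps + 1):
        fp = m * N * P / (1.0 + N)
        b1 = N * (1.0 - N / k) - fp
        b2 = -c * P + e * fp
        if event_fact:
            g1 = 0.0
            g2 = 0.0
            z = np.random.standard_normal()
            g1 += np.sqrt(N / omega) * z
            z = np.random.standard_normal()
            g1 -= np.sqrt(N * N / k / omega) * z
            z = np.random.standard_normal()
            g2 -= np.sqrt(c * P / omega) * z
            if code == BERNOULLI:
                z = np.random.standard_normal()
                r = np.sqrt(e * fp / omega)
                g1 -= r * z
                g2 += r * z
                z = np.random.standard_normal()
                g1 -= np.sqrt((1.0 - e) * fp / omega) * z
            elif code == EFFECTIVE:
                z = np.random.standard_normal()
                r = np.sqrt(fp / omega)
                g1 -= r * z
                g2 += e * r * z
            else:
                z = np.random.standard_normal()
                g1 -= np.sqrt(fp / omega) * z
                z = np.random.standard_normal()
                g2 += np.sqrt(e * fp / omega) * z
        else:
            a11 = (N + N * N / k + fp) / omega
            if code == BERNOULLI:
                a12 = -e * fp / omega
                a22 = (c * P + e * fp) / omega
            elif code == EFFECTIVE:
                a12 = -e * fp / omega
                a22 = (c * P + e * e * fp) / omega
            else:
                a12 = 0.0
                a22 = (c * P + e * fp) / omega
            l11 = np.sqrt(a11) if a11 > 0.0 else 0.0
            l21 = a12 / l11 if l11 > 0.0 else 0.0
            d2 = a22 - l21 * l21
            l22 = np.sqrt(d2) if d2 > 0.0 else 0.0
            z1 = np.random.standard_normal()
            z2 = np.random.standard_normal()
            g1 = l11 * z1
            g2 = l21 * z1 + l22 * z2
        Np = N + b1 * dt + sqdt * g1
        Pp = P + b2 * dt + sqdt * g2
        if absorbed_mode:
            if Np <= 0.0 or Pp <= 0.0:
                if Np <= 0.0 and Pp <= 0.0:
                    face = 3
                elif Np <= 0.0:
                    face = 1
                else:
                    face = 2
                N = Np if Np > 0.0 else 0.0
                P = Pp if Pp > 0.0 else 0.0
                tau = i * dt
                while j < rec_n.shape[0]:
                    rec_n[j] = N
                    rec_p[j] = P
                    j += 1
                break
            N = Np
            P = Pp
        else:
            # clip anything below clip_eps so the proxy path keeps a
            # strictly positive margin from the boundary
            N = Np if Np >= clip_eps else clip_eps
            P = Pp if Pp >= clip_eps else clip_eps
        if i % stride == 0 and j < rec_n.shape[0]:
            rec_n[j] = N
            rec_p[j] = P
            j += 1
    return tau, face, N, P
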