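"""Independent reference implementation of the lattice Monte Carlo dynamics.

Used as an oracle: it consumes the same explicit uniform-draw stream as the
production kernel but computes every energy difference by recomputing the
*total* Hamiltonian from scratch in plain Python.  After replaying the same
stream, the two implementations must land in the identical state.
"""

import math

import numpy as np

PERIM = [(-1, 0), (-1, 1), (2, 0), (2, 1), (0, -1), (1, -1), (0, 2), (1, 2)]


def is_open(st, c):
    if st.ch_sens[c].sum() != 4:
        return False
    if st.params.inactivation and st.ch_species[c] == 0 and st.ch_inact[c]:
        return False
    return True


def ref_total_energy(st):
    """Plain-Python Hamiltonian: gating + allosteric + contacts + lipid bonds."""
    p = st.params
    L = st.L
    e = 0.0
    for x in range(L):
        for y in range(L):
            s = st.lat[x, y]
            if s >= 2:
                continue
            for nx, ny in (((x + 1) % L, y), (x, (y + 1) % L)):
                sn = st.lat[nx, ny]
                if sn < 2 and sn == s:
                    e -= p.j_ll
    jcl = p.j_cl
    for c in range(st.n_channels):
        vhalf = p.v_half_na if st.ch_species[c] == 0 else p.v_half_k
        k = int(st.ch_sens[c].sum())
        e += k * (-p.q_s * (st.vm - vhalf) / p.kt_mv)
        e += p.a * k * (4 - k)
        if p.inactivation and st.ch_species[c] == 0 and st.ch_inact[c]:
            e += -p.q_inact * (st.vm - p.v_half_inact) / p.kt_mv
        func = 1 if is_open(st, c) else 0
        for dx, dy in PERIM:
            s = st.lat[(st.ch_x[c] + dx) % L, (st.ch_y[c] + dy) % L]
            if s < 2:
                e += jcl[func, s]
    return e


def ref_run(st, n_moves, mix, stream):
    """Replay ``stream`` (iterator of uniforms) with full-recompute ΔE."""
    draws = iter(stream)
    L = st.L
    n_ch = st.n_channels
    beta = st.beta_rel

    def metropolis(de):
        if de > 1e-9:
            return next(draws) < math.exp(-de * beta)
        return True

    for _ in range(n_moves):
        r = next(draws)
        if r < mix.sensor + mix.inact and n_ch > 0:
            c = int(next(draws) * n_ch)
            if r < mix.sensor:
                g = int(next(draws) * 4)
            else:
                g = 4
                if not (st.params.inactivation and st.ch_species[c] == 0):
                    continue  # flag only on Na channels: null move
            e0 = ref_total_energy(st)
            if g < 4:
                st.ch_sens[c, g] = 1 - st.ch_sens[c, g]
            else:
                st.ch_inact[c] = 1 - st.ch_inact[c]
            if not metropolis(ref_total_energy(st) - e0):
                if g < 4:
                    st.ch_sens[c, g] = 1 - st.ch_sens[c, g]
                else:
                    st.ch_inact[c] = 1 - st.ch_inact[c]
        elif r < mix.sensor + mix.inact + mix.lipid:
            x = int(next(draws) * L)
            y = int(next(draws) * L)
            if st.lat[x, y] >= 2:
                continue
            d = int(next(draws) * 4)
            dx = 1 if d == 0 else (-1 if d == 1 else 0)
            dy = 1 if d == 2 else (-1 if d == 3 else 0)
            nx, ny = (x + dx) % L, (y + dy) % L
            s1, s2 = st.lat[x, y], st.lat[nx, ny]
            if s2 >= 2 or s1 == s2:
                continue
            e0 = ref_total_energy(st)
            st.lat[x, y], st.lat[nx, ny] = s2, s1
            if not metropolis(ref_total_energy(st) - e0):
                st.lat[x, y], st.lat[nx, ny] = s1, s2
        elif r < mix.sensor + mix.inact + mix.lipid + mix.translate and n_ch > 0:
            c = int(next(draws) * n_ch)
            d = int(next(draws) * 4)
            x, y = int(st.ch_x[c]), int(st.ch_y[c])
            if d == 0:
                lead = [((x + 2) % L, y), ((x + 2) % L, (y + 1) % L)]
                trail = [(x, y), (x, (y + 1) % L)]
                na = ((x + 1) % L, y)
            elif d == 1:
                lead = [((x - 1) % L, y), ((x - 1) % L, (y + 1) % L)]
                trail = [((x + 1) % L, y), ((x + 1) % L, (y + 1) % L)]
                na = ((x - 1) % L, y)
            elif d == 2:
                lead = [(x, (y + 2) % L), ((x + 1) % L, (y + 2) % L)]
                trail = [(x, y), ((x + 1) % L, y)]
                na = (x, (y + 1) % L)
            else:
                lead = [(x, (y - 1) % L), ((x + 1) % L, (y - 1) % L)]
                trail = [(x, (y - 1 + 2) % L), ((x + 1) % L, (y - 1 + 2) % L)]
                na = (x, (y - 1) % L)
            if st.lat[lead[0]] >= 2 or st.lat[lead[1]] >= 2:
                continue
            e0 = ref_total_energy(st)
            l0, l1 = st.lat[lead[0]], st.lat[lead[1]]

            def apply(anchor):
                st.lat[trail[0]], st.lat[trail[1]] = l0, l1
                st.owner[trail[0]] = st.owner[trail[1]] = -1
                st.lat[lead[0]] = st.lat[lead[1]] = 2
                st.owner[lead[0]] = st.owner[lead[1]] = c
                st.ch_x[c], st.ch_y[c] = anchor

            def revert():
                st.lat[lead[0]], st.lat[lead[1]] = l0, l1
                st.owner[lead[0]] = st.owner[lead[1]] = -1
                st.lat[trail[0]] = st.lat[trail[1]] = 2
                st.owner[trail[0]] = st.owner[trail[1]] = c
                st.ch_x[c], st.ch_y[c] = (x, y)

            apply(na)
            if not metropolis(ref_total_energy(st) - e0):
                revert()
        elif n_ch > 0:
            c = int(next(draws) * n_ch)
            u = next(draws)
            if u < 0.5:
                st.ch_sens[c] = np.roll(st.ch_sens[c], 1)
            else:
                st.ch_sens[c] = np.roll(st.ch_sens[c], -1)
            # sensor permutation leaves the Hamiltonian invariant: always accept
    return st
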