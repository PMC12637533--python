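"""Numba kernels for the lattice Monte Carlo channel-gating simulator.

Site coding in ``lat``: 0 = saturated lipid, 1 = unsaturated lipid,
2 = channel-occupied.  ``owner`` holds the channel index at channel sites
(−1 elsewhere).  Channels occupy 2×2 footprints with periodic wrapping;
their 8 edge-adjacent perimeter sites define the channel–lipid contacts.

All energies are in units of kT at the reference temperature; the
Metropolis acceptance at simulation temperature T multiplies energy
differences by beta_rel = T_ref[K] / T[K].

Move codes for :func:`run_moves` proposals: gate flip (sensor or, for Na
channels, the inactivation flag), Kawasaki exchange of unlike neighbour
lipids, channel translation by one site (displaced lipids back-fill the
vacated strip), and channel rotation (cyclic permutation of the sensors).
Invalid proposals (e.g. exchange picked on a channel site) are null moves:
they count as attempts and are rejected.
"""

import numpy as np
from numba import njit

# perimeter offsets of a 2x2 footprint anchored at (0, 0): 8 edge-adjacent sites
_PERIM = np.array(
    [(-1, 0), (-1, 1), (2, 0), (2, 1), (0, -1), (1, -1), (0, 2), (1, 2)],
    dtype=np.int64,
)


@njit(cache=True)
def _is_open(ch_sens, ch_inact, ch_species, c, inact_on):
    k = ch_sens[c, 0] + ch_sens[c, 1] + ch_sens[c, 2] + ch_sens[c, 3]
    if k != 4:
        return False
    if inact_on and ch_species[c] == 0 and ch_inact[c] == 1:
        return False
    return True


@njit(cache=True)
def _contact_sum(lat, L, x, y, func, jcl):
    """Channel-lipid contact energy of a footprint at (x, y) in state ``func``."""
    e = 0.0
    for p in range(8):
        px = (x + _PERIM[p, 0]) % L
        py = (y + _PERIM[p, 1]) % L
        s = lat[px, py]
        if s < 2:
            e += jcl[func, s]
    return e


@njit(cache=True)
def _gating_energy(ch_sens, ch_inact, ch_species, c, vm, qs, vhalf_na, vhalf_k,
                   q_inact, vhalf_inact, kt_mv, a_allo, inact_on):
    """Gating + allosteric + inactivation energy of one channel (no contacts)."""
    vhalf = vhalf_na if ch_species[c] == 0 else vhalf_k
    e_act = -qs * (vm - vhalf) / kt_mv
    k = ch_sens[c, 0] + ch_sens[c, 1] + ch_sens[c, 2] + ch_sens[c, 3]
    e = k * e_act + a_allo * k * (4 - k)
    if inact_on and ch_species[c] == 0 and ch_inact[c] == 1:
        e += -q_inact * (vm - vhalf_inact) / kt_mv
    return e


@njit(cache=True)
def total_energy(lat, owner, ch_species, ch_x, ch_y, ch_sens, ch_inact,
                 vm, qs, vhalf_na, vhalf_k, kt_mv, a_allo, jll, jcl,
                 q_inact, vhalf_inact, inact_on):
    L = lat.shape[0]
    e = 0.0
    # lipid-lipid: right and down bonds (2 L^2 bonds over the torus)
    for x in range(L):
        for y in range(L):
            s = lat[x, y]
            if s >= 2:
                continue
            sr = lat[x, (y + 1) % L]
            if sr < 2 and sr == s:
                e -= jll
            sd = lat[(x + 1) % L, y]
            if sd < 2 and sd == s:
                e -= jll
    n_ch = ch_species.size
    for c in range(n_ch):
        e += _gating_energy(ch_sens, ch_inact, ch_species, c, vm, qs, vhalf_na,
                            vhalf_k, q_inact, vhalf_inact, kt_mv, a_allo, inact_on)
        func = 1 if _is_open(ch_sens, ch_inact, ch_species, c, inact_on) else 0
        e += _contact_sum(lat, L, ch_x[c], ch_y[c], func, jcl)
    return e


@njit(cache=True)
def _site_lipid_energy(lat, owner, L, x, y, species, ex, ey, jll, jcl,
                       ch_sens, ch_inact, ch_species, inact_on):
    """Bond + contact energy of putting lipid ``species`` at (x, y).

    The partner site (ex, ey) of an exchange is excluded (its mutual bond is
    unchanged by a swap of unlike lipids).
    """
    e = 0.0
    for d in range(4):
        nx = (x + (1 if d == 0 else -1 if d == 1 else 0)) % L
        ny = (y + (1 if d == 2 else -1 if d == 3 else 0)) % L
        if nx == ex and ny == ey:
            continue
        s = lat[nx, ny]
        if s < 2:
            if s == species:
                e -= jll
        else:
            c = owner[nx, ny]
            func = 1 if _is_open(ch_sens, ch_inact, ch_species, c, inact_on) else 0
            e += jcl[func, species]
    return e


@njit(cache=True)
def _local_region_energy(lat, owner, L, sites, n_sites,
                         ch_species, ch_x, ch_y, ch_sens, ch_inact,
                         jll, jcl, inact_on, aff, n_aff):
    """Lipid bonds incident to ``sites`` (each bond once) plus the full
    contact energy of the channels listed in ``aff``."""
    e = 0.0
    for i in range(n_sites):
        x, y = sites[i, 0], sites[i, 1]
        s = lat[x, y]
        for d in range(4):
            dx = 1 if d == 0 else (-1 if d == 1 else 0)
            dy = 1 if d == 2 else (-1 if d == 3 else 0)
            nx = (x + dx) % L
            ny = (y + dy) % L
            # count the bond once: skip if the neighbour is also a changed
            # site and comes earlier in the list
            dup = False
            for j in range(n_sites):
                if sites[j, 0] == nx and sites[j, 1] == ny:
                    if j < i:
                        dup = True
                    break
            if dup:
                continue
            if s < 2:
                sn = lat[nx, ny]
                if sn < 2 and sn == s:
                    e -= jll
            # channel-lipid contacts are accounted via the affected channels
    for k in range(n_aff):
        c = aff[k]
        func = 1 if _is_open(ch_sens, ch_inact, ch_species, c, inact_on) else 0
        e += _contact_sum(lat, L, ch_x[c], ch_y[c], func, jcl)
    return e


@njit(cache=True)
def run_moves(lat, owner, ch_species, ch_x, ch_y, ch_sens, ch_inact,
              n_moves, vm, beta_rel,
              qs, vhalf_na, vhalf_k, kt_mv, a_allo, jll, jcl,
              q_inact, vhalf_inact, inact_on,
              p_sens, p_inact, p_lip, p_trans, seed, rand_buf):
    """Attempt ``n_moves`` Metropolis moves in place.

    All randomness is consumed as uniform draws; a non-empty ``rand_buf``
    replaces the seeded stream (used by tests to replay the exact same
    proposal sequence through an independent reference implementation).
    Returns (sum over attempts of open Na count, same for K, accepted
    moves) so callers can form window-averaged open-channel counts.
    """
    np.random.seed(seed)
    use_buf = rand_buf.size > 0
    ptr = 0
    L = lat.shape[0]
    n_ch = ch_species.size

    # running open counts, updated incrementally on gate flips
    n_open_na = 0
    n_open_k = 0
    for c in range(n_ch):
        if _is_open(ch_sens, ch_inact, ch_species, c, inact_on):
            if ch_species[c] == 0:
                n_open_na += 1
            else:
                n_open_k += 1

    sum_na = 0.0
    sum_k = 0.0
    accepted = 0
    sites = np.empty((4, 2), dtype=np.int64)
    aff = np.empty(16, dtype=np.int64)

    for _ in range(n_moves):
        if use_buf:
            r = rand_buf[ptr]
            ptr += 1
        else:
            r = np.random.random()
        if r < p_sens + p_inact and n_ch > 0:
            # ---- gate flip: sensor, or (slow branch) Na inactivation flag ---
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            c = int(u * n_ch)
            was_open = _is_open(ch_sens, ch_inact, ch_species, c, inact_on)
            if r < p_sens:
                if use_buf:
                    u = rand_buf[ptr]
                    ptr += 1
                else:
                    u = np.random.random()
                g = int(u * 4)
                vhalf = vhalf_na if ch_species[c] == 0 else vhalf_k
                act = ch_sens[c, g]
                e_act = -qs * (vm - vhalf) / kt_mv
                k = ch_sens[c, 0] + ch_sens[c, 1] + ch_sens[c, 2] + ch_sens[c, 3]
                k2 = k + (1 - 2 * act)
                de = (1 - 2 * act) * e_act + a_allo * (k2 * (4 - k2) - k * (4 - k))
                ch_sens[c, g] = 1 - act
            else:
                g = 4
                if not (inact_on and ch_species[c] == 0):
                    sum_na += n_open_na
                    sum_k += n_open_k
                    continue  # flag exists only on Na channels: null move
                ina = ch_inact[c]
                e_in = -q_inact * (vm - vhalf_inact) / kt_mv
                de = (1 - 2 * ina) * e_in
                ch_inact[c] = 1 - ina
            now_open = _is_open(ch_sens, ch_inact, ch_species, c, inact_on)
            if now_open != was_open:
                fb = 1 if was_open else 0
                fa = 1 if now_open else 0
                de += (_contact_sum(lat, L, ch_x[c], ch_y[c], fa, jcl)
                       - _contact_sum(lat, L, ch_x[c], ch_y[c], fb, jcl))
            if de > 1e-9:
                if use_buf:
                    u = rand_buf[ptr]
                    ptr += 1
                else:
                    u = np.random.random()
                accept = u < np.exp(-de * beta_rel)
            else:
                accept = True
            if accept:
                accepted += 1
                if now_open != was_open:
                    if ch_species[c] == 0:
                        n_open_na += 1 if now_open else -1
                    else:
                        n_open_k += 1 if now_open else -1
            else:  # revert
                if g < 4:
                    ch_sens[c, g] = 1 - ch_sens[c, g]
                else:
                    ch_inact[c] = 1 - ch_inact[c]
        elif r < p_sens + p_inact + p_lip:
            # ---- Kawasaki lipid exchange ------------------------------------
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            x = int(u * L)
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            y = int(u * L)
            if lat[x, y] >= 2:
                pass  # null move
            else:
                if use_buf:
                    u = rand_buf[ptr]
                    ptr += 1
                else:
                    u = np.random.random()
                d = int(u * 4)
                dx = 1 if d == 0 else (-1 if d == 1 else 0)
                dy = 1 if d == 2 else (-1 if d == 3 else 0)
                nx = (x + dx) % L
                ny = (y + dy) % L
                s1 = lat[x, y]
                s2 = lat[nx, ny]
                if s2 >= 2 or s1 == s2:
                    pass  # null move
                else:
                    e_before = (
                        _site_lipid_energy(lat, owner, L, x, y, s1, nx, ny, jll, jcl,
                                           ch_sens, ch_inact, ch_species, inact_on)
                        + _site_lipid_energy(lat, owner, L, nx, ny, s2, x, y, jll, jcl,
                                             ch_sens, ch_inact, ch_species, inact_on))
                    e_after = (
                        _site_lipid_energy(lat, owner, L, x, y, s2, nx, ny, jll, jcl,
                                           ch_sens, ch_inact, ch_species, inact_on)
                        + _site_lipid_energy(lat, owner, L, nx, ny, s1, x, y, jll, jcl,
                                             ch_sens, ch_inact, ch_species, inact_on))
                    de = e_after - e_before
                    if de > 1e-9:
                        if use_buf:
                            u = rand_buf[ptr]
                            ptr += 1
                        else:
                            u = np.random.random()
                        accept = u < np.exp(-de * beta_rel)
                    else:
                        accept = True
                    if accept:
                        lat[x, y] = s2
                        lat[nx, ny] = s1
                        accepted += 1
        elif r < p_sens + p_inact + p_lip + p_trans and n_ch > 0:
            # ---- channel translation by one site ----------------------------
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            c = int(u * n_ch)
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            d = int(u * 4)
            x, y = ch_x[c], ch_y[c]
            # leading strip (entered) and trailing strip (vacated)
            if d == 0:    # +x
                lead = ((x + 2) % L, y), ((x + 2) % L, (y + 1) % L)
                trail = (x, y), (x, (y + 1) % L)
                nxa, nya = (x + 1) % L, y
            elif d == 1:  # -x
                lead = ((x - 1) % L, y), ((x - 1) % L, (y + 1) % L)
                trail = ((x + 1) % L, y), ((x + 1) % L, (y + 1) % L)
                nxa, nya = (x - 1) % L, y
            elif d == 2:  # +y
                lead = (x, (y + 2) % L), ((x + 1) % L, (y + 2) % L)
                trail = (x, y), ((x + 1) % L, y)
                nxa, nya = x, (y + 1) % L
            else:         # -y
                lead = (x, (y - 1) % L), ((x + 1) % L, (y - 1) % L)
                trail = (x, (y + 1) % L), ((x + 1) % L, (y + 1) % L)
                nxa, nya = x, (y - 1) % L
            if lat[lead[0][0], lead[0][1]] >= 2 or lat[lead[1][0], lead[1][1]] >= 2:
                pass  # blocked by a channel (own footprint cannot block: strips differ)
            else:
                sites[0, 0], sites[0, 1] = lead[0]
                sites[1, 0], sites[1, 1] = lead[1]
                sites[2, 0], sites[2, 1] = trail[0]
                sites[3, 0], sites[3, 1] = trail[1]
                # affected channels: the mover plus owners adjacent to changed sites
                n_aff = 0
                aff[n_aff] = c
                n_aff += 1
                for i in range(4):
                    for dd in range(4):
                        ddx = 1 if dd == 0 else (-1 if dd == 1 else 0)
                        ddy = 1 if dd == 2 else (-1 if dd == 3 else 0)
                        ax = (sites[i, 0] + ddx) % L
                        ay = (sites[i, 1] + ddy) % L
                        o = owner[ax, ay]
                        if o >= 0:
                            found = False
                            for j in range(n_aff):
                                if aff[j] == o:
                                    found = True
                                    break
                            if not found:
                                aff[n_aff] = o
                                n_aff += 1
                e_before = _local_region_energy(
                    lat, owner, L, sites, 4, ch_species, ch_x, ch_y, ch_sens,
                    ch_inact, jll, jcl, inact_on, aff, n_aff)
                l0 = lat[lead[0][0], lead[0][1]]
                l1 = lat[lead[1][0], lead[1][1]]
                # apply: lipids back-fill the vacated strip in order
                lat[trail[0][0], trail[0][1]] = l0
                lat[trail[1][0], trail[1][1]] = l1
                owner[trail[0][0], trail[0][1]] = -1
                owner[trail[1][0], trail[1][1]] = -1
                lat[lead[0][0], lead[0][1]] = 2
                lat[lead[1][0], lead[1][1]] = 2
                owner[lead[0][0], lead[0][1]] = c
                owner[lead[1][0], lead[1][1]] = c
                ch_x[c], ch_y[c] = nxa, nya
                e_after = _local_region_energy(
                    lat, owner, L, sites, 4, ch_species, ch_x, ch_y, ch_sens,
                    ch_inact, jll, jcl, inact_on, aff, n_aff)
                de = e_after - e_before
                if de > 1e-9:
                    if use_buf:
                        u = rand_buf[ptr]
                        ptr += 1
                    else:
                        u = np.random.random()
                    accept = u < np.exp(-de * beta_rel)
                else:
                    accept = True
                if accept:
                    accepted += 1
                else:  # revert
                    lat[lead[0][0], lead[0][1]] = l0
                    lat[lead[1][0], lead[1][1]] = l1
                    owner[lead[0][0], lead[0][1]] = -1
                    owner[lead[1][0], lead[1][1]] = -1
                    lat[trail[0][0], trail[0][1]] = 2
                    lat[trail[1][0], trail[1][1]] = 2
                    owner[trail[0][0], trail[0][1]] = c
                    owner[trail[1][0], trail[1][1]] = c
                    ch_x[c], ch_y[c] = x, y
        elif n_ch > 0:
            # ---- channel rotation (cyclic sensor permutation) ---------------
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            c = int(u * n_ch)
            if use_buf:
                u = rand_buf[ptr]
                ptr += 1
            else:
                u = np.random.random()
            if u < 0.5:
                tmp = ch_sens[c, 3]
                ch_sens[c, 3] = ch_sens[c, 2]
                ch_sens[c, 2] = ch_sens[c, 1]
                ch_sens[c, 1] = ch_sens[c, 0]
                ch_sens[c, 0] = tmp
            else:
                tmp = ch_sens[c, 0]
                ch_sens[c, 0] = ch_sens[c, 1]
                ch_sens[c, 1] = ch_sens[c, 2]
                ch_sens[c, 2] = ch_sens[c, 3]
                ch_sens[c, 3] = tmp
            # the Hamiltonian is invariant under sensor permutation: dE = 0
            accepted += 1

        sum_na += n_open_na
        sum_k += n_open_k

    return sum_na, sum_k, accepted
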