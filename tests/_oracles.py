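"""Independent reference implementations used only by the test suite.

Everything here is written as a separate code path from the package:
explicit constants, arbitrary-precision arithmetic (mpmath) for the
relaxation model, and brute-force enumeration for speciation, digest,
pair counting and threshold crossing. Nothing imports from gdcoil.
"""

import mpmath as mp

mp.mp.dps = 50

# constants, restated independently of the package
MU0_4PI = mp.mpf("1e-7")
GAMMA_I = mp.mpf("2.6752218744e8")
MU_B = mp.mpf("9.2740100783e-24")
HBAR = mp.mpf("1.054571817e-34")
N_A = mp.mpf("6.02214076e23")
WATER_MM = mp.mpf("55500")
PI = mp.pi


def omega_pair(nu_mhz, g=2):
    w_i = 2 * PI * mp.mpf(nu_mhz) * mp.mpf(10) ** 6
    gamma_s = mp.mpf(g) * MU_B / HBAR
    return w_i, (gamma_s / GAMMA_I) * w_i


def lipari_szabo(w, tau_g, tau_l, s2):
    w, tau_g, tau_l, s2 = map(mp.mpf, (w, tau_g, tau_l, s2))
    return (s2 * tau_g / (1 + (w * tau_g) ** 2)
            + (1 - s2) * tau_l / (1 + (w * tau_l) ** 2))


def electron_rates(w_s, delta2, tau_v, spin=mp.mpf(7) / 2):
    w_s, delta2, tau_v = map(mp.mpf, (w_s, delta2, tau_v))
    pref = 4 * spin * (spin + 1) - 3
    x = (w_s * tau_v) ** 2
    r1e = (delta2 * tau_v / 25) * pref * (1 / (1 + x) + 4 / (1 + 4 * x))
    r2e = (delta2 * tau_v / 50) * pref * (3 + 5 / (1 + x) + 2 / (1 + 4 * x))
    return r1e, r2e


def freed(w, tau_d, t_je=mp.inf):
    w, tau_d = mp.mpf(w), mp.mpf(tau_d)
    leak = mp.mpf(0) if t_je == mp.inf else tau_d / mp.mpf(t_je)
    z = mp.sqrt(1j * w * tau_d + leak)
    return mp.re((1 + z / 4) / (1 + z + 4 * z ** 2 / 9 + z ** 3 / 9))


def second_sphere(nu_mhz, q, r_ss_ang, tau_m, tau_rg, tau_rl, s2,
                  delta2, tau_v, g=2, spin=mp.mpf(7) / 2):
    w_i, w_s = omega_pair(nu_mhz, g)
    r1e, r2e = electron_rates(w_s, delta2, tau_v, spin)
    tau_m, tau_rg, tau_rl = map(mp.mpf, (tau_m, tau_rg, tau_rl))

    def eff(tau_rot, rate):
        return 1 / (1 / tau_rot + 1 / tau_m + rate)

    j_i = lipari_szabo_eff(w_i, eff(tau_rg, r1e), eff(tau_rl, r1e), s2)
    j_s = lipari_szabo_eff(w_s, eff(tau_rg, r2e), eff(tau_rl, r2e), s2)
    r_m = mp.mpf(r_ss_ang) * mp.mpf("1e-10")
    const = (mp.mpf(2) / 15 * MU0_4PI ** 2 * GAMMA_I ** 2
             * mp.mpf(g) ** 2 * MU_B ** 2 * spin * (spin + 1) / r_m ** 6)
    rate_1m = const * (3 * j_i + 7 * j_s)
    return (mp.mpf(q) / WATER_MM) / (1 / rate_1m + tau_m)


def lipari_szabo_eff(w, tau_g, tau_l, s2):
    s2 = mp.mpf(s2)
    return (s2 * tau_g / (1 + (w * tau_g) ** 2)
            + (1 - s2) * tau_l / (1 + (w * tau_l) ** 2))


def outer_sphere(nu_mhz, a_ang, d, delta2, tau_v, g=2, spin=mp.mpf(7) / 2):
    w_i, w_s = omega_pair(nu_mhz, g)
    r1e, r2e = electron_rates(w_s, delta2, tau_v, spin)
    a_m = mp.mpf(a_ang) * mp.mpf("1e-10")
    d = mp.mpf(d)
    tau_d = a_m ** 2 / d
    gamma_s = mp.mpf(g) * MU_B / HBAR
    c_os = (32 * PI / 405 * MU0_4PI ** 2 * GAMMA_I ** 2 * gamma_s ** 2
            * HBAR ** 2 * spin * (spin + 1) * N_A / (a_m * d))
    return c_os * (3 * freed(w_i, tau_d, 1 / r1e)
                   + 7 * freed(w_s, tau_d, 1 / r2e))


def total_r1(nu_mhz, q, r_ss_ang, tau_m, tau_rg, tau_rl, s2,
             a_ang, d, delta2, tau_v):
    return (second_sphere(nu_mhz, q, r_ss_ang, tau_m, tau_rg, tau_rl,
                          s2, delta2, tau_v)
            + outer_sphere(nu_mhz, a_ang, d, delta2, tau_v))


# -- brute-force references -------------------------------------------------

def speciation_grid(m_t, p_t, e_t, ka_p, ka_e, n_grid=10 ** 6,
                    n_refine=3):
    """Free-metal concentration by grid search over [0, M_T] with
    successive refinement of the bracketing interval (concentrations in
    uM, constants in 1/M)."""
    import numpy as np

    kp, ke = ka_p * 1e-6, ka_e * 1e-6

    def balance(m):
        return (m + kp * m * p_t / (1 + kp * m)
                + ke * m * e_t / (1 + ke * m) - m_t)

    lo, hi = 0.0, float(m_t)
    for _ in range(n_refine):
        grid = np.linspace(lo, hi, n_grid + 1)
        vals = balance(grid)
        idx = int(np.searchsorted(vals >= 0, True))
        idx = max(idx, 1)
        lo, hi = grid[idx - 1], grid[idx]
    m = 0.5 * (lo + hi)
    mp_ = kp * m * p_t / (1 + kp * m)
    me_ = ke * m * e_t / (1 + ke * m)
    return m, mp_, me_


def first_crossing(time, signal, threshold):
    """Exhaustive scan over adjacent sample pairs for the first
    crossing of the normalized signal below threshold."""
    norm = [s / signal[0] for s in signal]
    if norm[0] <= threshold:
        return time[0], False
    for i in range(1, len(norm)):
        if norm[i] <= threshold:
            t0, t1 = time[i - 1], time[i]
            y0, y1 = norm[i - 1], norm[i]
            return t0 + (threshold - y0) * (t1 - t0) / (y1 - y0), False
    return time[-1], True


def digest_scan(residues, crosslinked):
    """Character-by-character trypsin scanner (no regex): cut after K/R
    unless followed by P or the K position (1-based) is cross-linked."""
    frags, cur = [], []
    for i, ch in enumerate(residues):
        cur.append(ch)
        last = i == len(residues) - 1
        if (not last and ch in "KR" and residues[i + 1] != "P"
                and (i + 1) not in crosslinked):
            frags.append("".join(cur))
            cur = []
    if cur:
        frags.append("".join(cur))
    return frags


def pair_counts(center_xyz, targets_xyz, edges):
    """All-pairs distance histogram via an explicit double loop."""
    counts = [0] * (len(edges) - 1)
    cx, cy, cz = center_xyz
    for (x, y, z) in targets_xyz:
        d = ((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2) ** 0.5
        for b in range(len(edges) - 1):
            if edges[b] <= d < edges[b + 1]:
                counts[b] += 1
                break
    return counts
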