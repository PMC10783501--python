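"""Independent brute-force oracles for the binding equilibria.

These deliberately avoid every solver code path in the package: the
isotherm and the self-consistent equilibrium are solved by dense-grid
sign-change search plus bisection on residuals written out directly from
the governing relations. Slow but trustworthy.
"""

import numpy as np

KB = 0.01380649  # pN nm / K


def mvh_residual(gamma, c_total, c_dna, Kd, n):
    cb = gamma * c_dna
    return gamma * Kd - (c_total - cb) * (1 - n * gamma) ** n / (
        1 - n * gamma + gamma
    ) ** (n - 1)


def solve_mvh_grid(c_total, c_dna, Kd, n, pts=1_000_001):
    """Isotherm root by grid sign-change search with linear interpolation."""
    if c_total == 0:
        return 0.0
    gmax = min(1.0 / n, c_total / c_dna)
    g = np.linspace(0.0, gmax * (1 - 1e-12), pts)
    r = mvh_residual(g, c_total, c_dna, Kd, n)
    idx = np.where(np.diff(np.sign(r)) != 0)[0]
    if len(idx) == 0:
        return float(g[-1])  # saturated within the grid
    i = idx[0]
    g0, g1, r0, r1 = g[i], g[i + 1], r[i], r[i + 1]
    return float(g0 - r0 * (g1 - g0) / (r1 - r0))


def kd_with_torque(gamma, dLk0, Kd0, n, dz, dth, Nbp, C, T, h=10.5):
    """Effective Kd at fractional binding gamma on a constrained molecule."""
    N = gamma * Nbp
    dLk = dLk0 + N * dth / 360.0
    Lc = 0.34 * Nbp + N * dz
    torque = (C * KB * T * 2 * np.pi / Lc) * 0.2 * dLk
    return Kd0 * np.exp(torque * np.deg2rad(dth) / (KB * T))


def solve_selfconsistent_grid(
    c_total, c_dna, Kd0, n, dz, dth, Nbp, C, T, dLk0, coarse=201, inner=300_001
):
    """Self-consistency root gamma - MvH(Kd_eff(gamma)) by coarse grid +
    bisection refinement."""
    gmax = min(1.0 / n, c_total / c_dna)

    def R(g):
        kd = kd_with_torque(g, dLk0, Kd0, n, dz, dth, Nbp, C, T)
        return g - solve_mvh_grid(c_total, c_dna, kd, n, pts=inner)

    gs = np.linspace(1e-9, gmax * (1 - 1e-9), coarse)
    rs = np.array([R(g) for g in gs])
    idx = np.where(np.diff(np.sign(rs)) != 0)[0]
    if len(idx) == 0:
        raise RuntimeError("self-consistency residual has no sign change")
    lo, hi = gs[idx[0]], gs[idx[0] + 1]
    rlo = R(lo)
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        rm = R(mid)
        if np.sign(rm) == np.sign(rlo):
            lo, rlo = mid, rm
        else:
            hi = mid
    return 0.5 * (lo + hi)
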