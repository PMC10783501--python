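"""Finite-concentration McGhee-von Hippel isotherm and the strain-modified Kd.

The McGhee-von Hippel model treats DNA as a one-dimensional lattice on which
each bound ligand occludes ``n`` base pairs; overlap exclusion makes binding
sub-Langmuir even without cooperativity. The finite-concentration extension
used here additionally accounts for ligand depletion when the DNA base-pair
concentration is comparable to the ligand concentration, so the free ligand
concentration is ``c_total - c_bound`` rather than ``c_total``.

With fractional binding ``gamma = c_bound / c_dna_bp`` (bound ligands per
base pair), the isotherm solved here is::

    gamma * Kd = (c_total - gamma*c_dna_bp) * (1 - n*gamma)**n
                                            / (1 - n*gamma + gamma)**(n-1)

which has a unique root in [0, 1/n).

Mechanical strain shifts the dissociation constant Arrhenius-like: because
each intercalation event lengthens the helix by ``dz`` and unwinds it by
``dtheta``, a stretching force favours binding and an overwinding torque
opposes it::

    Kd_eff = Kd0 * exp(+Gamma_over * dtheta_rad / kBT) * exp(-F * dz / kBT)

with ``Gamma_over`` the torque in the overwinding-positive sign convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .params import IntercalatorParams, thermal_energy

__all__ = ["IsothermSolution", "mvh_residual", "solve_mvh", "effective_kd"]

# Relative residual bound guaranteed for returned isotherm solutions.
_RESIDUAL_RTOL = 1e-12


@dataclass(frozen=True)
class IsothermSolution:
    """Solved binding equilibrium at fixed (torque-independent) Kd.

    ``gamma`` is the fractional binding (bound dyes per base pair),
    ``c_bound = gamma * c_dna_bp`` and ``c_free = c_total - c_bound``,
    both in molar.
    """

    gamma: float
    c_bound: float
    c_free: float


def mvh_residual(
    gamma: float,
    c_total: float,
    c_dna_bp: float,
    Kd: float,
    n: float,
    printed_variant: bool = False,
) -> float:
    """Signed residual of the isotherm at fractional binding ``gamma``.

    Negative below the root, positive above it. ``printed_variant`` swaps
    the site-exclusion numerator for ``(1 - n*c_bound/c_total)**n``; that
    variant is unphysical (it does not cap binding at one ligand per ``n``
    base pairs in dilute DNA) and exists for comparison only.
    """
    c_bound = gamma * c_dna_bp
    if printed_variant:
        numer = (1.0 - n * c_bound / c_total) ** n if c_total > 0 else 0.0
    else:
        numer = (1.0 - n * gamma) ** n
    denom = (1.0 - n * gamma + gamma) ** (n - 1.0)
    return gamma * Kd - (c_total - c_bound) * numer / denom


def solve_mvh(
    c_total: float,
    c_dna_bp: float,
    Kd: float,
    n: float,
    printed_variant: bool = False,
) -> IsothermSolution:
    """Solve the finite-concentration McGhee-von Hippel isotherm.

    Parameters
    ----------
    c_total:
        Total ligand concentration, molar.
    c_dna_bp:
        DNA concentration in molar base pairs.
    Kd:
        Dissociation constant, molar (possibly strain-modified).
    n:
        Binding site size, base pairs (>= 1, may be non-integer).
    printed_variant:
        Use the alternative numerator dialect (see :func:`mvh_residual`);
        for comparison only, never in the self-consistent solver.

    Returns
    -------
    IsothermSolution
        The unique solution with ``gamma`` in [0, 1/n).

    Raises
    ------
    ValueError
        On invalid parameters.
    RuntimeError
        If the bracketed root search fails (should not occur for valid
        inputs).
    """
    if c_total < 0:
        raise ValueError(f"c_total must be non-negative, got {c_total}")
    if c_dna_bp <= 0:
        raise ValueError(f"c_dna_bp must be positive, got {c_dna_bp}")
    if Kd <= 0:
        raise ValueError(f"Kd must be positive, got {Kd}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")

    if c_total == 0.0:
        return IsothermSolution(gamma=0.0, c_bound=0.0, c_free=0.0)

    if printed_variant:
        # The alternative numerator vanishes at c_bound = c_total/n instead
        # of at lattice saturation; the denominator additionally requires
        # gamma < 1/(n-1). A root need not exist in this range — one of the
        # defects of this dialect.
        gamma_max = c_total / (n * c_dna_bp)
        if n > 1.0:
            gamma_max = min(gamma_max, 1.0 / (n - 1.0))
    else:
        # gamma is bounded by lattice saturation (1/n) and by total ligand.
        gamma_max = min(1.0 / n, c_total / c_dna_bp)
    lo, hi = 0.0, gamma_max * (1.0 - 1e-14)

    def f(g: float) -> float:
        return mvh_residual(g, c_total, c_dna_bp, Kd, n, printed_variant)

    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0.0:  # pragma: no cover - c_total > 0 makes f(0) = -c_total < 0
        raise RuntimeError("bracket failure: residual positive at gamma = 0")
    saturated = f_hi <= 0.0
    if saturated and printed_variant:
        raise RuntimeError(
            "bracket failure: the printed-variant residual has no root in "
            f"[0, {gamma_max:.6g}) (c_total={c_total:.3e}, "
            f"c_dna_bp={c_dna_bp:.3e}, Kd={Kd:.3e}, n={n})"
        )
    if saturated:
        # Numerically saturated: the root sits within rounding of gamma_max.
        g = hi
    else:
        g = brentq(f, lo, hi, xtol=1e-16, rtol=8.9e-16, maxiter=200)
        # Polish check: residual must be small relative to the balance terms.
        scale = max(abs(g * Kd), c_total, 1e-300)
        if abs(f(g)) > _RESIDUAL_RTOL * scale:  # pragma: no cover - defensive
            raise RuntimeError(
                f"isotherm root not converged: residual {f(g):.3e} at "
                f"gamma={g:.6e} (c_total={c_total:.3e}, "
                f"c_dna_bp={c_dna_bp:.3e}, Kd={Kd:.3e}, n={n})"
            )

    c_bound = g * c_dna_bp
    return IsothermSolution(gamma=g, c_bound=c_bound, c_free=c_total - c_bound)


def effective_kd(
    Kd0: float,
    torque: float,
    force: float,
    dye: IntercalatorParams,
    T: float = 297.0,
) -> float:
    """Strain-modified dissociation constant.

    ``torque`` is the torque in the DNA in the overwinding-positive
    convention (pN·nm): overwinding raises Kd (hinders intercalation),
    unwinding torque lowers it. A stretching force ``force`` (pN) lowers
    Kd because intercalation lengthens the helix.
    """
    if Kd0 <= 0:
        raise ValueError(f"Kd0 must be positive, got {Kd0}")
    kBT = thermal_energy(T)
    dtheta_rad = math.radians(dye.dtheta)
    return Kd0 * math.exp(torque * dtheta_rad / kBT) * math.exp(-force * dye.dz / kBT)
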