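"""Domain parameter types, physical constants, and the intercalator preset registry.

Unit conventions used throughout the package:

* concentrations — molar (DNA concentration in molar *base pairs*)
* lengths — nanometres
* torque and energy — pN·nm
* angles — degrees in all parameter structures, converted to radians only
  inside energy expressions
* temperature — kelvin
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = [
    "KB_PN_NM_PER_K",
    "BASE_RISE_NM",
    "IntercalatorParams",
    "DNASubstrate",
    "Conditions",
    "SolverSettings",
    "thermal_energy",
    "get_preset",
    "recommended_torsional_stiffness",
    "PRESETS",
]

#: Boltzmann's constant in pN·nm per kelvin (1.380649e-23 J/K = 1.380649e-2 pN·nm/K).
KB_PN_NM_PER_K = 0.01380649

#: Helix rise of bare B-form DNA, nm per base pair.
BASE_RISE_NM = 0.34


def thermal_energy(T: float) -> float:
    """Thermal energy k_B·T in pN·nm for an absolute temperature in kelvin.

    Raises
    ------
    ValueError
        If ``T`` is not positive.
    """
    if T <= 0:
        raise ValueError(f"absolute temperature must be positive, got {T}")
    return KB_PN_NM_PER_K * T


@dataclass(frozen=True)
class IntercalatorParams:
    """Binding and helix-deformation parameters of one intercalating ligand.

    Attributes
    ----------
    name:
        Human-readable ligand name.
    n:
        Binding site size in base pairs (may be non-integer; lattice
        exclusion parameter of the McGhee-von Hippel model).
    Kd0:
        Dissociation constant of the torsionally relaxed, force-free
        molecule, in molar.
    dz:
        Helix lengthening per bound ligand, nm.
    dtheta:
        Helix unwinding per bound ligand, degrees.
    """

    name: str
    n: float
    Kd0: float
    dz: float
    dtheta: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"binding site size n must be >= 1, got {self.n}")
        if self.Kd0 <= 0:
            raise ValueError(f"Kd0 must be positive, got {self.Kd0}")
        if self.dz < 0:
            raise ValueError(f"dz must be non-negative, got {self.dz}")
        if not 0 <= self.dtheta < 360:
            raise ValueError(f"dtheta must be in [0, 360), got {self.dtheta}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "IntercalatorParams":
        return cls(**d)


@dataclass(frozen=True)
class DNASubstrate:
    """One DNA species: length, torsional stiffness and initial topology.

    ``dLk0`` is the linking difference of the bare (dye-free) molecule
    relative to bare torsionally relaxed DNA, in turns; it may instead be
    supplied as a supercoiling density via :meth:`from_sigma0`.

    ``topology`` is ``"closed"`` (torsionally constrained: covalently closed
    plasmid, or a molecule tethered at both ends through multiple bonds) or
    ``"open"`` (nicked, linear, or otherwise free to relax torsion).
    """

    N_bp: int
    C: float = 100.0  # torsional stiffness, nm
    helical_repeat: float = 10.5  # bp per turn of bare DNA
    dLk0: float = 0.0  # turns
    topology: str = "closed"

    def __post_init__(self) -> None:
        if self.N_bp < 1:
            raise ValueError(f"N_bp must be >= 1, got {self.N_bp}")
        if self.helical_repeat <= 0:
            raise ValueError("helical_repeat must be positive")
        if self.C <= 0:
            raise ValueError("torsional stiffness C must be positive")
        if self.topology not in ("closed", "open"):
            raise ValueError(
                f"topology must be 'closed' or 'open', got {self.topology!r}"
            )

    @property
    def Lk0(self) -> float:
        """Relaxed linking number of the bare molecule, turns."""
        return self.N_bp / self.helical_repeat

    @property
    def Lc0(self) -> float:
        """Bare contour length, nm."""
        return BASE_RISE_NM * self.N_bp

    @property
    def sigma0(self) -> float:
        """Initial supercoiling density of the bare molecule."""
        return self.dLk0 / self.Lk0

    @classmethod
    def from_sigma0(cls, N_bp: int, sigma0: float, **kwargs) -> "DNASubstrate":
        """Construct with the initial topology given as a supercoiling density."""
        Lk0 = N_bp / kwargs.get("helical_repeat", 10.5)
        return cls(N_bp=N_bp, dLk0=sigma0 * Lk0, **kwargs)

    def with_(self, **changes) -> "DNASubstrate":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "DNASubstrate":
        return cls(**d)


@dataclass(frozen=True)
class Conditions:
    """Solution and mechanical conditions of one equilibrium.

    Attributes
    ----------
    c_total:
        Total ligand concentration, molar.
    c_dna_bp:
        DNA concentration in molar base pairs (molecule concentration is
        ``c_dna_bp / N_bp``).
    T:
        Absolute temperature, kelvin. Default 297 K (24 °C).
    F:
        Stretching force, pN. Zero for molecules in free solution.
    staining_factor:
        Multiplicative correction on the effective dye concentration for
        gel staining (the gel matrix and de-staining reduce the dye
        available to the DNA). 1 means no correction; gel data use 0.1.
    """

    c_total: float
    c_dna_bp: float
    T: float = 297.0
    F: float = 0.0
    staining_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.c_total < 0:
            raise ValueError("c_total must be non-negative")
        if self.c_dna_bp <= 0:
            raise ValueError("c_dna_bp must be positive")
        if self.T <= 0:
            raise ValueError("temperature must be positive")
        if self.F < 0:
            raise ValueError("force must be non-negative")
        if not 0 < self.staining_factor <= 1:
            raise ValueError("staining_factor must be in (0, 1]")

    def with_(self, **changes) -> "Conditions":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Conditions":
        return cls(**d)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings of the self-consistent equilibrium solver."""

    relaxation: float = 0.5  # damping factor of the fixed-point iteration
    tol: float = 1e-10  # convergence tolerance on fractional binding
    max_iter: int = 10000
    oracle_grid: int = 1_000_000  # grid points for brute-force validation

    def __post_init__(self) -> None:
        if not 0 < self.relaxation < 2:
            raise ValueError("relaxation must be in (0, 2)")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SolverSettings":
        return cls(**d)


# Preset registry. n in bp, Kd0 in M, dz in nm, dtheta in degrees.
PRESETS: dict[str, IntercalatorParams] = {
    "etbr": IntercalatorParams("EtBr", n=1.9, Kd0=7.7e-6, dz=0.34, dtheta=27.0),
    "sybr_gold": IntercalatorParams("SYBR_Gold", n=1.6, Kd0=0.2e-6, dz=0.34, dtheta=19.1),
    "sytox_orange": IntercalatorParams("SYTOX_Orange", n=3.0, Kd0=0.4e-6, dz=0.30, dtheta=19.1),
    "tmp": IntercalatorParams("TMP", n=2.0, Kd0=1e-4, dz=0.34, dtheta=28.0),
}

# Recommended torsional stiffness when modelling each dye: measurements of
# DNA in free solution with EtBr found C ~ 50 nm; everything else uses the
# single-molecule consensus value of 100 nm.
_RECOMMENDED_C: dict[str, float] = {
    "etbr": 50.0,
    "sybr_gold": 100.0,
    "sytox_orange": 100.0,
    "tmp": 100.0,
}


def get_preset(name: str) -> IntercalatorParams:
    """Look up an intercalator preset by name (case-insensitive).

    Available presets: EtBr, SYBR_Gold, SYTOX_Orange, TMP.
    """
    key = name.strip().lower()
    if key not in PRESETS:
        available = ", ".join(p.name for p in PRESETS.values())
        raise KeyError(f"unknown intercalator preset {name!r}; available: {available}")
    return PRESETS[key]


def recommended_torsional_stiffness(name: str) -> float:
    """Recommended torsional stiffness C (nm) to pair with a preset dye."""
    key = name.strip().lower()
    if key not in _RECOMMENDED_C:
        available = ", ".join(p.name for p in PRESETS.values())
        raise KeyError(f"unknown intercalator preset {name!r}; available: {available}")
    return _RECOMMENDED_C[key]
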