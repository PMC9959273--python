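"""Sphere–plate DLVO forward model and physical-constant calculators.

The interaction between a colloid-probe sphere (radius ``r``, nm) and a flat
sample-coated substrate at surface separation ``D`` (nm) is modelled as the sum
of an exponentially screened electrostatic double-layer (EDL) repulsion and an
unretarded van der Waals (VDW) attraction::

    F_EDL(D) = kappa * r * Z * exp(-kappa * D)        [nN]
    F_VDW(D) = -A_H * r / (6 * D**2)                  [nN, A_H in J]
    F_DLVO(D) = F_EDL(D) + F_VDW(D)

with the Debye parameter ``kappa`` (1/nm) set by the electrolyte, the
interaction constant ``Z`` (nN) set by the Stern-layer potential, and the
Hamaker constant ``A_H`` (J) set by the dielectric contrast of the two bodies
across the medium. Repulsion is positive; ``D`` is the sphere-surface to
plate-surface separation.

Public interfaces use nm, nN, J, V, mol/m^3 and K throughout; conversion to SI
happens only inside the formulas.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhysicalConstants",
    "CODATA",
    "Medium",
    "ProbeGeometry",
    "DLVOParameters",
    "HamakerInputs",
    "SternPotential",
    "edl_force",
    "vdw_force",
    "dlvo_force",
    "dlvo_slope",
    "kappa_from_ionic_strength",
    "z_from_stern_potential",
    "hamaker_constant",
    "limit_distance",
    "DEFAULT_HAMAKER",
    "DEFAULT_SLOPE_THRESHOLD",
]

# J/nm -> nN  (1 J/m = 1 N, so 1 J/nm = 1e9 N = 1e18 nN)
_J_PER_NM_TO_NN = 1.0e18
_M_TO_NM = 1.0e9
_N_TO_NN = 1.0e9

#: Literature Hamaker constant for cellulose nanocrystals across water, J.
DEFAULT_HAMAKER = 3.6e-21

#: Default |dF/dD| criterion defining the limit distance, nN/nm.
DEFAULT_SLOPE_THRESHOLD = 1.8e-3


@dataclass(frozen=True)
class PhysicalConstants:
    """Fundamental constants (CODATA 2018), SI units."""

    faraday: float = 96485.33212  # C/mol
    gas_constant: float = 8.314462618  # J/(mol K)
    boltzmann: float = 1.380649e-23  # J/K
    planck: float = 6.62607015e-34  # J s
    vacuum_permittivity: float = 8.8541878128e-12  # F/m

    def __post_init__(self) -> None:
        for name in ("faraday", "gas_constant", "boltzmann", "planck", "vacuum_permittivity"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")


CODATA = PhysicalConstants()


@dataclass(frozen=True)
class Medium:
    """Aqueous electrolyte medium.

    Parameters
    ----------
    rel_permittivity : float
        Relative static permittivity of the solvent (78.5 for water at 25 C).
    ionic_strength : float
        Electrolyte concentration c0 in mol/m^3 (1 mol/m^3 == 1 mM).
    temperature : float
        Absolute temperature in K.
    refractive_index, static_dielectric : float
        Optical refractive index and static dielectric constant of the
        medium as the third body in Hamaker-constant calculations.
    """

    rel_permittivity: float = 78.5
    ionic_strength: float = 1.0
    temperature: float = 298.15
    refractive_index: float = 1.333
    static_dielectric: float = 78.5

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")
        if not self.rel_permittivity > 1:
            raise ValueError("rel_permittivity must be > 1")


@dataclass(frozen=True)
class ProbeGeometry:
    """Colloid-probe geometry: silica sphere radius in nm (5 um default)."""

    sphere_radius: float = 5000.0

    def __post_init__(self) -> None:
        if not self.sphere_radius > 0:
            raise ValueError("sphere_radius must be > 0 nm")


@dataclass(frozen=True)
class DLVOParameters:
    """Parameter bundle for one interacting probe–substrate pair.

    kappa in 1/nm, z_const in nN, hamaker in J.
    """

    kappa: float
    z_const: float
    hamaker: float = DEFAULT_HAMAKER
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)

    def __post_init__(self) -> None:
        if not self.kappa > 0:
            raise ValueError("kappa must be > 0 nm^-1")
        if self.z_const < 0:
            raise ValueError("z_const must be >= 0 nN")
        if self.hamaker < 0:
            raise ValueError("hamaker must be >= 0 J")


@dataclass(frozen=True)
class HamakerInputs:
    """Dielectric data for the two-term Lifshitz Hamaker constant.

    eps1/eps2/eps3 are static dielectric constants and n1/n2/n3 visible-light
    refractive indices of body 1, body 2 and the intervening medium; nu_e is
    the main electronic (UV) absorption frequency in Hz.
    """

    eps1: float
    eps2: float
    eps3: float
    n1: float
    n2: float
    n3: float
    nu_e: float = 3.0e15
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("eps1", "eps2", "eps3", "n1", "n2", "n3"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not self.nu_e > 0:
            raise ValueError("nu_e must be > 0 Hz")
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0 K")


@dataclass(frozen=True)
class SternPotential:
    """Stern-layer potential in volts. The sign is carried but tanh^2 makes
    the interaction constant an even function of it."""

    psi_delta: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.psi_delta):
            raise ValueError("psi_delta must be finite")


def _check_distance(distance):
    d = np.asarray(distance, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be > 0 nm (surface separation)")
    return d


def edl_force(params: DLVOParameters, distance):
    """Electrostatic double-layer force kappa*r*Z*exp(-kappa*D) in nN.

    Strictly positive and strictly decreasing in ``distance`` when Z > 0;
    ln(F_EDL) is affine in D with slope -kappa, which is what the log-linear
    fitting stage exploits.
    """
    d = _check_distance(distance)
    r = params.geometry.sphere_radius
    out = params.kappa * r * params.z_const * np.exp(-params.kappa * d)
    return out if out.ndim else float(out)


def vdw_force(params: DLVOParameters, distance):
    """Unretarded sphere–plate van der Waals force -A_H*r/(6 D^2) in nN."""
    d = _check_distance(distance)
    r = params.geometry.sphere_radius
    out = -params.hamaker * r / (6.0 * d**2) * _J_PER_NM_TO_NN
    return out if out.ndim else float(out)


def dlvo_force(params: DLVOParameters, distance):
    """Net DLVO force (nN): EDL repulsion plus VDW attraction, exactly."""
    return edl_force(params, distance) + vdw_force(params, distance)


def dlvo_slope(params: DLVOParameters, distance):
    """Analytic derivative dF_DLVO/dD in nN/nm."""
    d = _check_distance(distance)
    r = params.geometry.sphere_radius
    edl = -params.kappa**2 * r * params.z_const * np.exp(-params.kappa * d)
    vdw = params.hamaker * r / (3.0 * d**3) * _J_PER_NM_TO_NN
    out = edl + vdw
    return out if out.ndim else float(out)


def kappa_from_ionic_strength(medium: Medium, constants: PhysicalConstants = CODATA) -> float:
    """Debye parameter kappa = sqrt(2 F^2 c0 / (eps eps0 R T)) in 1/nm.

    For a 1:1 electrolyte in water at 25 C this reproduces the textbook
    Debye length 0.304/sqrt(c[M]) nm.
    """
    if not medium.ionic_strength > 0:
        raise ValueError("ionic_strength must be > 0 (zero gives an infinite screening length)")
    num = 2.0 * constants.faraday**2 * medium.ionic_strength
    den = (
        medium.rel_permittivity
        * constants.vacuum_permittivity
        * constants.gas_constant
        * medium.temperature
    )
    return math.sqrt(num / den) / _M_TO_NM


def z_from_stern_potential(
    medium: Medium, psi: SternPotential, constants: PhysicalConstants = CODATA
) -> float:
    """Interaction constant Z = 64 pi eps eps0 (RT/F)^2 tanh^2(F psi/(4RT)), nN.

    Even in the potential; saturates at 64 pi eps eps0 (RT/F)^2 for large
    |psi| and vanishes for an uncharged interface.
    """
    rt_over_f = constants.gas_constant * medium.temperature / constants.faraday
    pref = (
        64.0
        * math.pi
        * medium.rel_permittivity
        * constants.vacuum_permittivity
        * rt_over_f**2
    )
    t = math.tanh(psi.psi_delta / (4.0 * rt_over_f))
    return pref * t * t * _N_TO_NN


def hamaker_constant(inputs: HamakerInputs, constants: PhysicalConstants = CODATA) -> float:
    """Two-term Lifshitz Hamaker constant for bodies 1 and 2 across medium 3, J.

    Zero-frequency (static dielectric) term plus the dispersion term over the
    visible refractive indices::

        A = (3/4) k T * (e1-e3)/(e1+e3) * (e2-e3)/(e2+e3)
          + (3 h nu_e / 8 sqrt(2)) * (n1^2-n3^2)(n2^2-n3^2)
            / [ s1 * s2 * (s1 + s2) ],   s_i = sqrt(n_i^2 + n3^2)

    Symmetric under swapping bodies 1 and 2; identically zero for
    index- and dielectric-matched media. For identical bodies this reduces to
    (3/4)kT[(e1-e3)/(e1+e3)]^2 + (3 h nu_e/16 sqrt2)(n1^2-n3^2)^2/(n1^2+n3^2)^1.5.
    """
    kT = constants.boltzmann * inputs.temperature
    zero_freq = (
        0.75
        * kT
        * (inputs.eps1 - inputs.eps3)
        / (inputs.eps1 + inputs.eps3)
        * (inputs.eps2 - inputs.eps3)
        / (inputs.eps2 + inputs.eps3)
    )
    n1sq, n2sq, n3sq = inputs.n1**2, inputs.n2**2, inputs.n3**2
    s1 = math.sqrt(n1sq + n3sq)
    s2 = math.sqrt(n2sq + n3sq)
    dispersion = (
        3.0
        * constants.planck
        * inputs.nu_e
        / (8.0 * math.sqrt(2.0))
        * (n1sq - n3sq)
        * (n2sq - n3sq)
        / (s1 * s2 * (s1 + s2))
    )
    return zero_freq + dispersion


def limit_distance(
    params: DLVOParameters,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    search_range: tuple[float, float] = (0.5, 2000.0),
) -> float:
    """Largest separation (nm) at which |dF_DLVO/dD| equals ``slope_threshold``.

    Operationalizes the "slope of the curve shifts to zero" criterion that
    defines the equilibrium spacing of particles in suspension: beyond this
    distance the net force profile is effectively flat. Found by bracketed
    root-finding on the analytic derivative; monotone increasing in Z at
    fixed kappa and monotone decreasing in the threshold.
    """
    if not params.z_const > 0:
        raise ValueError("limit_distance requires Z > 0 (a repulsive tail)")
    if not slope_threshold > 0:
        raise ValueError("slope_threshold must be > 0 nN/nm")

    def g(d: float) -> float:
        return abs(dlvo_slope(params, d)) - slope_threshold

    lo, hi = search_range
    grid = np.geomspace(lo, hi, 512)
    vals = np.array([g(d) for d in grid])
    sign = np.sign(vals)
    crossings = np.nonzero(sign[:-1] * sign[1:] <= 0)[0]
    if crossings.size == 0:
        raise ValueError(
            f"|dF/dD| never crosses {slope_threshold} nN/nm in [{lo}, {hi}] nm"
        )
    i = crossings[-1]  # largest-D crossing
    if vals[i] == 0.0:
        return float(grid[i])
    return float(brentq(g, grid[i], grid[i + 1], xtol=1e-10, rtol=1e-12))
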