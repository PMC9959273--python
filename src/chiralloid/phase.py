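"""QCM adsorption quantification, phase-separation analysis and rheological
state classification for nanocrystal suspensions.

Three experimental strands meet here:

* **QCM**: the Sauerbrey relation converts a rigid-film frequency shift into
  areal mass, ``dm = -C * df / nu`` (C = 17.7 ng/(cm^2 Hz) for a 5 MHz
  crystal), and the areal mass is normalized by the coating loading to a
  specific adsorption in mg per g of coating.
* **Phase separation**: the anisotropic (liquid-crystalline) volume fraction
  of a settled suspension is the anisotropic-band height over the total
  height; scanning it against concentration locates the biphasic window
  between C_a (anisotropic phase first appears) and C_i (fully anisotropic).
* **Rheology**: an oscillatory sweep with G' > G'' over the whole frequency
  range marks a rigid gel (kinetic arrest); a steady-shear viscosity profile
  with two shear-thinning regions bracketing a weak-thinning plateau is the
  three-region signature of a liquid-crystalline suspension.

A suspension that gels at or below its C_a is kinetically arrested before
chiral ordering can develop — the structural color of the dried film is then
suppressed (:func:`kinetic_arrest`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "QCMTrace",
    "PhaseRecord",
    "RheoSweep",
    "CriticalConcentration",
    "GelClassification",
    "sauerbrey_mass",
    "specific_adsorption",
    "anisotropic_fraction",
    "critical_concentrations",
    "classify_gel",
    "lc_viscosity_regions",
    "kinetic_arrest",
    "DEFAULT_SAUERBREY_COEFF",
    "DEFAULT_COATING_AREAL_MASS",
]

#: Mass sensitivity of a 5 MHz quartz crystal, ng/(cm^2 Hz).
DEFAULT_SAUERBREY_COEFF = 17.7

#: Inferred areal mass of the nanocrystal coating on the sensor, ug/cm^2.
#: Back-solved from the reference conversion 676 ng/cm^2 -> 87 mg/g; not a
#: measured quantity, so treat as a placeholder to be overridden when the
#: sensor loading is known.
DEFAULT_COATING_AREAL_MASS = 7.77


@dataclass
class QCMTrace:
    """Frequency-shift time series of one overtone of a quartz crystal."""

    time: np.ndarray  # s
    delta_f: np.ndarray  # Hz
    overtone: int = 1
    sauerbrey_coeff: float = DEFAULT_SAUERBREY_COEFF  # ng/(cm^2 Hz)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.delta_f = np.asarray(self.delta_f, dtype=float)
        if self.time.shape != self.delta_f.shape or self.time.ndim != 1:
            raise ValueError("time and delta_f must be 1-d arrays of equal length")
        if self.overtone <= 0 or self.overtone % 2 == 0:
            raise ValueError("overtone must be an odd positive harmonic order")
        if not self.sauerbrey_coeff > 0:
            raise ValueError("sauerbrey_coeff must be > 0")


@dataclass(frozen=True)
class PhaseRecord:
    """Heights of the anisotropic band and the whole suspension column at one
    concentration (any consistent length unit)."""

    concentration: float  # wt%
    aniso_height: float
    total_height: float

    def __post_init__(self) -> None:
        if not self.total_height > 0:
            raise ValueError("total_height must be > 0")
        if not 0 <= self.aniso_height <= self.total_height:
            raise ValueError("aniso_height must be within [0, total_height]")


@dataclass
class RheoSweep:
    """One rheology sweep: oscillatory (omega, G', G'') or steady
    (shear_rate, viscosity)."""

    mode: str  # "oscillatory" | "steady"
    omega: np.ndarray | None = None  # rad/s
    g_prime: np.ndarray | None = None  # Pa
    g_double_prime: np.ndarray | None = None  # Pa
    shear_rate: np.ndarray | None = None  # 1/s
    viscosity: np.ndarray | None = None  # Pa s

    def __post_init__(self) -> None:
        if self.mode == "oscillatory":
            arrays = {"omega": self.omega, "g_prime": self.g_prime,
                      "g_double_prime": self.g_double_prime}
        elif self.mode == "steady":
            arrays = {"shear_rate": self.shear_rate, "viscosity": self.viscosity}
        else:
            raise ValueError("mode must be 'oscillatory' or 'steady'")
        n = None
        for name, arr in arrays.items():
            if arr is None:
                raise ValueError(f"{self.mode} sweep requires {name}")
            arr = np.asarray(arr, dtype=float)
            setattr(self, name, arr)
            if np.any(arr <= 0):
                raise ValueError(f"{name} must be strictly positive")
            if n is None:
                n = arr.size
            elif arr.size != n:
                raise ValueError("sweep arrays must have equal length")


@dataclass(frozen=True)
class CriticalConcentration:
    """A critical concentration, possibly only bracketed as a bound.

    ``relation`` is '=' when the transition is bracketed by the tested grid,
    '<' when it lies below the lowest tested concentration and '>' when above
    the highest.
    """

    value: float  # wt%
    relation: str = "="

    def __post_init__(self) -> None:
        if self.relation not in ("=", "<", ">"):
            raise ValueError("relation must be '=', '<' or '>'")

    @property
    def bracketed(self) -> bool:
        return self.relation == "="

    def __str__(self) -> str:
        return f"{self.value:g}" if self.bracketed else f"{self.relation} {self.value:g}"


@dataclass(frozen=True)
class GelClassification:
    """Oscillatory-sweep verdict; crossover frequency reported when one exists."""

    label: str  # "gel" | "liquid_like"
    crossover_omega: float | None = None


def sauerbrey_mass(trace: QCMTrace, equilibrium_window: tuple[float, float]) -> float:
    """Adsorbed areal mass (ng/cm^2) from the equilibrium frequency shift.

    dm = -C * mean(delta_f) / overtone, averaged over the equilibrium time
    window (s). Valid for thin rigid films; the window mean must be <= 0
    (a frequency drop) for an adsorption reading.
    """
    t0, t1 = equilibrium_window
    if t0 >= t1:
        raise ValueError("equilibrium_window must be an increasing (t0, t1)")
    if t0 < trace.time[0] or t1 > trace.time[-1]:
        raise ValueError(
            f"window [{t0}, {t1}] s outside trace span "
            f"[{trace.time[0]}, {trace.time[-1]}] s"
        )
    mask = (trace.time >= t0) & (trace.time <= t1)
    if not mask.any():
        raise ValueError("equilibrium window contains no samples")
    mean_df = float(trace.delta_f[mask].mean())
    if mean_df > 0:
        raise ValueError(f"window mean delta_f = {mean_df:.3g} Hz > 0: not an adsorption step")
    return -trace.sauerbrey_coeff * mean_df / trace.overtone


def specific_adsorption(
    areal_mass: float, coating_areal_mass: float = DEFAULT_COATING_AREAL_MASS
) -> float:
    """Adsorbed mass per gram of coating, mg/g.

    ``areal_mass`` in ng/cm^2 over ``coating_areal_mass`` in ug/cm^2; the
    ng/ug ratio is numerically the mg/g value. Scale-invariant in the two
    inputs jointly.
    """
    if not coating_areal_mass > 0:
        raise ValueError("coating_areal_mass must be > 0 ug/cm^2")
    return areal_mass / coating_areal_mass


def anisotropic_fraction(record: PhaseRecord) -> float:
    """Anisotropic-phase volume fraction: band height / total height, in [0,1]."""
    return record.aniso_height / record.total_height


def critical_concentrations(
    records: list[PhaseRecord], tol: float = 0.02
) -> tuple[CriticalConcentration, CriticalConcentration]:
    """Locate C_a and C_i on a concentration series.

    C_a is the lowest tested concentration whose anisotropic fraction exceeds
    ``tol``; C_i the lowest whose fraction reaches 1 - tol. When the
    transition is not bracketed by the tested grid the result is reported as
    a bound: e.g. a series that is fully anisotropic everywhere yields
    C_i '< c_min'.
    """
    if not records:
        raise ValueError("no phase records")
    conc = np.array([r.concentration for r in records])
    if np.any(np.diff(conc) < 0):
        raise ValueError("records must be sorted by concentration")
    frac = np.array([anisotropic_fraction(r) for r in records])

    above_a = np.nonzero(frac > tol)[0]
    if above_a.size == 0:
        c_a = CriticalConcentration(float(conc[-1]), ">")
    elif above_a[0] == 0:
        c_a = CriticalConcentration(float(conc[0]), "<")
    else:
        c_a = CriticalConcentration(float(conc[above_a[0]]), "=")

    above_i = np.nonzero(frac >= 1.0 - tol)[0]
    if above_i.size == 0:
        c_i = CriticalConcentration(float(conc[-1]), ">")
    elif above_i[0] == 0:
        c_i = CriticalConcentration(float(conc[0]), "<")
    else:
        c_i = CriticalConcentration(float(conc[above_i[0]]), "=")
    return c_a, c_i


def classify_gel(sweep: RheoSweep) -> GelClassification:
    """Gel vs liquid-like from an oscillatory sweep.

    A rigid gel keeps G' > G'' over the whole sampled frequency range; any
    frequency with G'' >= G' makes the state liquid-like, and the G'/G''
    crossover frequency is interpolated (log-log) when the sweep crosses.
    Invariant to a common positive rescaling of both moduli.
    """
    if sweep.mode != "oscillatory":
        raise ValueError("classify_gel needs an oscillatory sweep")
    if sweep.omega.size < 2:
        raise ValueError("sweep must sample more than one frequency")
    ratio = np.log(sweep.g_prime / sweep.g_double_prime)
    if np.all(ratio > 0):
        return GelClassification("gel")
    crossover = None
    sign_change = np.nonzero(ratio[:-1] * ratio[1:] < 0)[0]
    if sign_change.size:
        i = int(sign_change[0])
        lw = np.log(sweep.omega)
        w = lw[i] - ratio[i] * (lw[i + 1] - lw[i]) / (ratio[i + 1] - ratio[i])
        crossover = float(np.exp(w))
    elif np.any(ratio == 0):
        crossover = float(sweep.omega[np.nonzero(ratio == 0)[0][0]])
    return GelClassification("liquid_like", crossover)


def _piecewise_loglog_fit(x: np.ndarray, y: np.ndarray, n_segments: int, min_pts: int = 3):
    """Continuous piecewise-linear least squares in log-log space.

    Breakpoints are searched on the sample grid; returns (slopes, sse).
    """
    n = x.size
    if n_segments == 1:
        coef = np.polyfit(x, y, 1)
        resid = y - np.polyval(coef, x)
        return [float(coef[0])], float(resid @ resid)

    def design(breaks):
        cols = [np.ones_like(x), x] + [np.maximum(x - b, 0.0) for b in breaks]
        return np.column_stack(cols)

    best = None
    idx = range(min_pts, n - min_pts)
    if n_segments == 2:
        candidates = [(i,) for i in idx]
    else:
        candidates = [
            (i, j) for i in idx for j in idx if j - i >= min_pts
        ]
    for cand in candidates:
        breaks = [x[i] for i in cand]
        A = design(breaks)
        beta, *_ = np.linalg.lstsq(A, y, rcond=None)
        resid = y - A @ beta
        sse = float(resid @ resid)
        if best is None or sse < best[1]:
            slopes = np.cumsum(beta[1:])
            best = ([float(s) for s in slopes], sse)
    if best is None:
        raise ValueError("sweep too short for segmented fit")
    return best


def lc_viscosity_regions(
    sweep: RheoSweep,
    shallow_slope: float = -0.2,
    steep_slope: float = -0.4,
) -> str:
    """Classify a steady-shear viscosity profile.

    A liquid-crystalline suspension shows three regions in log-log: shear
    thinning at low rates (texture refinement), a weak-thinning middle
    plateau, and thinning again at high rates (particle alignment). The
    profile is segmented by three-piece continuous least squares; the pattern
    (steep, shallow, steep) — middle slope above ``shallow_slope``, outer
    slopes below ``steep_slope`` — reads ``lc_three_region``. A shallow-then-
    steep two-piece pattern reads ``newtonian_then_thinning``; anything else
    ``simple_shear_thinning``. Invariant to vertical scaling of viscosity.
    """
    if sweep.mode != "steady":
        raise ValueError("lc_viscosity_regions needs a steady-shear sweep")
    x = np.log10(sweep.shear_rate)
    y = np.log10(sweep.viscosity)
    if np.ptp(x) < 3.0:
        raise ValueError(
            f"sweep spans {np.ptp(x):.2f} decades of shear rate; need >= 3 for segmentation"
        )
    slopes3, _ = _piecewise_loglog_fit(x, y, 3)
    s1, s2, s3 = slopes3
    if s1 < steep_slope and s2 > shallow_slope and s3 < steep_slope:
        return "lc_three_region"
    slopes2, _ = _piecewise_loglog_fit(x, y, 2)
    t1, t2 = slopes2
    if t1 > shallow_slope and t2 < steep_slope:
        return "newtonian_then_thinning"
    return "simple_shear_thinning"


def kinetic_arrest(gelation_concentration: float, c_a: CriticalConcentration) -> bool:
    """Flag a formulation as color-suppressing.

    True when gelation sets in at or below the concentration where the
    anisotropic phase first appears: the network freezes before chiral
    ordering can develop, so the dried film shows no structural color.
    """
    return gelation_concentration <= c_a.value
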