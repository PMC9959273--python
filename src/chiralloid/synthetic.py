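"""Seeded synthetic-data generators emulating every instrument the pipeline
consumes: colloid-probe force curves, QCM adsorption traces, phase-separation
series and rheology sweeps.

Each generator is deterministic given its (spec, seed): identical inputs give
bit-identical outputs. The force-curve generator is the DLVO forward model
plus a short-range exponential contact artifact (standing in for the
unmodelled steric/adhesion contribution at close approach) and additive
Gaussian noise; its defaults — 2e-3 nN force noise, a 0.5 nN artifact with a
5 nm decay, a 200 nm approach ramp — emulate the scatter of colloid-probe
measurements in fluid. The default measurement campaign is 100 repeats at 10
substrate locations per pair, for each of the seven reference probe–substrate
pairs shipped in ``data/reference_pairs.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .curves import CurveSet, ForceCurve
from .phase import PhaseRecord, QCMTrace, RheoSweep, DEFAULT_SAUERBREY_COEFF
from .physics import DEFAULT_HAMAKER, DLVOParameters, ProbeGeometry, dlvo_force

__all__ = [
    "ForceCurveSpec",
    "ScenarioSpec",
    "load_reference_pairs",
    "reference_parameters",
    "gen_force_curve",
    "gen_table1_suite",
    "gen_qcm_trace",
    "gen_phase_series",
    "gen_rheo_sweep",
    "DEFAULT_NOISE_SD",
    "DEFAULT_ARTIFACT_AMPLITUDE",
    "DEFAULT_ARTIFACT_DECAY",
]

#: Default additive force noise sd, nN.
DEFAULT_NOISE_SD = 2.0e-3
#: Default short-range contact artifact: amplitude (nN) and decay length (nm).
DEFAULT_ARTIFACT_AMPLITUDE = 0.5
DEFAULT_ARTIFACT_DECAY = 5.0


def load_reference_pairs() -> pd.DataFrame:
    """The seven-pair reference parameter table shipped with the package."""
    with resources.files("chiralloid.data").joinpath("reference_pairs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", comment="#")


def reference_parameters(
    pair_label: str, hamaker: float = DEFAULT_HAMAKER, sphere_radius: float = 5000.0
) -> DLVOParameters:
    """DLVO parameters of one reference pair by label."""
    table = load_reference_pairs()
    row = table[table.pair_label == pair_label]
    if row.empty:
        raise KeyError(f"unknown pair label {pair_label!r}; known: {list(table.pair_label)}")
    return DLVOParameters(
        kappa=float(row.kappa_per_nm.iloc[0]),
        z_const=float(row.z_nN.iloc[0]),
        hamaker=hamaker,
        geometry=ProbeGeometry(sphere_radius),
    )


@dataclass(frozen=True)
class ForceCurveSpec:
    """Recipe for one synthetic approach curve."""

    params: DLVOParameters
    d_range: tuple[float, float] = (2.0, 200.0)
    n_points: int = 200
    noise_sd: float = DEFAULT_NOISE_SD
    contact_artifact_amplitude: float = DEFAULT_ARTIFACT_AMPLITUDE
    contact_decay: float = DEFAULT_ARTIFACT_DECAY
    seed: int = 0
    pair_label: str = ""
    location_id: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.d_range
        if not (0 < lo < hi):
            raise ValueError("d_range must be positive and ordered")
        if self.n_points < 32:
            raise ValueError("n_points must be >= 32")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ScenarioSpec:
    """A measurement scenario: which pair series to emulate and at which
    additive levels. ``base_params`` defaults to the shipped reference table."""

    scenario: str = "cos_series"  # pure_cnc | paas_series | cos_series | all
    levels: tuple = ()
    base_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("pure_cnc", "paas_series", "cos_series", "all"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")

    def pair_table(self) -> pd.DataFrame:
        table = self.base_params if self.base_params is not None else load_reference_pairs()
        if self.scenario == "pure_cnc":
            return table[table.pair_label == "CNC-CNC"]
        if self.scenario == "paas_series":
            return table[table.pair_label.isin(["CNC-CNC", "PAAS-CNC"])]
        if self.scenario == "cos_series":
            return table[table.pair_label.str.contains("COS") | (table.pair_label == "CNC-CNC")]
        return table


def gen_force_curve(spec: ForceCurveSpec) -> ForceCurve:
    """Forward-model force curve: DLVO + contact artifact + Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    d = np.linspace(spec.d_range[0], spec.d_range[1], spec.n_points)
    f = dlvo_force(spec.params, d)
    if spec.contact_artifact_amplitude:
        f = f + spec.contact_artifact_amplitude * np.exp(-d / spec.contact_decay)
    if spec.noise_sd:
        f = f + rng.normal(0.0, spec.noise_sd, size=d.size)
    return ForceCurve(
        distance=d,
        force=f,
        direction="extend",
        pair_label=spec.pair_label,
        location_id=spec.location_id,
        replicate_id=spec.replicate_id,
    )


def gen_table1_suite(
    spec: ScenarioSpec | None = None,
    replicates: int = 100,
    seed: int = 0,
    n_locations: int = 10,
    noise_sd: float = DEFAULT_NOISE_SD,
    contact_artifact_amplitude: float = DEFAULT_ARTIFACT_AMPLITUDE,
    d_range: tuple[float, float] = (2.0, 200.0),
    n_points: int = 200,
    hamaker: float = DEFAULT_HAMAKER,
    sphere_radius: float = 5000.0,
) -> CurveSet:
    """Emulate a whole measurement campaign over a pair series.

    One curve per (pair, replicate); replicates are spread over
    ``n_locations`` substrate locations. Child seeds are spawned from the
    master seed, so the suite is reproducible as a whole.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    spec = spec or ScenarioSpec(scenario="all")
    table = spec.pair_table()
    seeds = np.random.SeedSequence(seed).generate_state(len(table) * replicates) % (2**31)
    curves = []
    k = 0
    for _, row in table.iterrows():
        params = DLVOParameters(
            kappa=float(row.kappa_per_nm),
            z_const=float(row.z_nN),
            hamaker=hamaker,
            geometry=ProbeGeometry(sphere_radius),
        )
        for rep in range(replicates):
            curves.append(
                gen_force_curve(
                    ForceCurveSpec(
                        params=params,
                        d_range=d_range,
                        n_points=n_points,
                        noise_sd=noise_sd,
                        contact_artifact_amplitude=contact_artifact_amplitude,
                        seed=int(seeds[k]),
                        pair_label=str(row.pair_label),
                        location_id=rep % n_locations,
                        replicate_id=rep,
                    )
                )
            )
            k += 1
    return CurveSet(
        curves=curves,
        metadata={
            "scenario": spec.scenario,
            "replicates": replicates,
            "seed": seed,
            "noise_sd": noise_sd,
        },
    )


def gen_qcm_trace(
    plateau_mass: float,
    overtone: int = 1,
    noise_sd: float = 0.2,
    rinse_drop_fraction: float = 0.0,
    seed: int = 0,
    sauerbrey_coeff: float = DEFAULT_SAUERBREY_COEFF,
    duration: float = 3600.0,
    dt: float = 5.0,
    t_inject: float = 600.0,
    t_rinse: float = 2400.0,
    tau: float = 150.0,
) -> QCMTrace:
    """Sauerbrey-consistent adsorption trace with a rinse step.

    Baseline at zero shift, an exponential adsorption transient approaching
    the ``plateau_mass`` (ng/cm^2), a rinse at ``t_rinse`` that releases
    ``rinse_drop_fraction`` of the adsorbed layer, and a final plateau whose
    Sauerbrey mass is ``plateau_mass * (1 - rinse_drop_fraction)``.
    """
    if plateau_mass < 0:
        raise ValueError("plateau_mass must be >= 0")
    if not 0 <= rinse_drop_fraction <= 1:
        raise ValueError("rinse_drop_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + dt / 2, dt)
    df_ads = -plateau_mass * overtone / sauerbrey_coeff
    df_final = df_ads * (1.0 - rinse_drop_fraction)
    df = np.zeros_like(t)
    ads = (t >= t_inject) & (t < t_rinse)
    df[ads] = df_ads * (1.0 - np.exp(-(t[ads] - t_inject) / tau))
    rinse = t >= t_rinse
    df_at_rinse = df_ads * (1.0 - np.exp(-(t_rinse - t_inject) / tau))
    df[rinse] = df_final + (df_at_rinse - df_final) * np.exp(-(t[rinse] - t_rinse) / tau)
    if noise_sd:
        df = df + rng.normal(0.0, noise_sd, size=t.size)
    return QCMTrace(time=t, delta_f=df, overtone=overtone, sauerbrey_coeff=sauerbrey_coeff)


def gen_phase_series(
    c_a: float,
    c_i: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    total_height: float = 40.0,
    onset_fraction: float = 0.05,
) -> list[PhaseRecord]:
    """Monotone anisotropic-fraction series over a concentration grid.

    Fraction 0 below ``c_a``; from ``c_a`` a thin anisotropic band of
    ``onset_fraction`` appears and ramps linearly to 1 at ``c_i``; fully
    anisotropic above. Gaussian noise (sd in fraction units) is added and the
    fraction clipped to [0, 1].
    """
    if c_a > c_i:
        raise ValueError("c_a must be <= c_i")
    rng = np.random.default_rng(seed)
    records = []
    for c in concentrations:
        if c < c_a:
            frac = 0.0
        elif c >= c_i:
            frac = 1.0
        elif c_i == c_a:
            frac = 1.0
        else:
            frac = onset_fraction + (1.0 - onset_fraction) * (c - c_a) / (c_i - c_a)
        if noise_sd:
            frac = float(np.clip(frac + rng.normal(0.0, noise_sd), 0.0, 1.0))
        records.append(
            PhaseRecord(concentration=float(c), aniso_height=frac * total_height,
                        total_height=total_height)
        )
    return records


def _loglog_piecewise(x: np.ndarray, breaks, slopes, y0: float) -> np.ndarray:
    """Continuous piecewise power law in log-log space."""
    y = np.full_like(x, y0, dtype=float)
    knots = [x[0], *breaks, x[-1]]
    level = y0
    out = np.empty_like(x)
    for seg, s in enumerate(slopes):
        lo, hi = knots[seg], knots[seg + 1]
        mask = (x >= lo) & (x <= hi)
        out[mask] = level + s * (x[mask] - lo)
        level = level + s * (hi - lo)
    return out


def gen_rheo_sweep(kind: str, seed: int = 0, n_points: int = 40) -> RheoSweep:
    """Parametric rheology sweep with a controlled qualitative structure.

    ``gel``/``liquid_like`` are oscillatory sweeps (G', G'' power laws with or
    without a crossover); ``lc_three_region``, ``simple`` and
    ``newtonian_then_thinning`` are steady-shear viscosity profiles with the
    named log-log slope pattern, lightly perturbed by seeded lognormal noise.
    """
    rng = np.random.default_rng(seed)
    jitter = lambda n: np.exp(rng.normal(0.0, 0.01, size=n))  # noqa: E731
    if kind == "gel":
        omega = np.geomspace(0.1, 100.0, n_points)
        g1 = 50.0 * omega**0.08 * jitter(n_points)
        g2 = 12.0 * omega**0.10 * jitter(n_points)
        return RheoSweep(mode="oscillatory", omega=omega, g_prime=g1, g_double_prime=g2)
    if kind == "liquid_like":
        omega = np.geomspace(0.1, 100.0, n_points)
        g1 = 2.0 * omega**1.3 * jitter(n_points)
        g2 = 8.0 * omega**0.9 * jitter(n_points)
        return RheoSweep(mode="oscillatory", omega=omega, g_prime=g1, g_double_prime=g2)
    if kind in ("lc_three_region", "simple", "newtonian_then_thinning"):
        rate = np.geomspace(1e-2, 1e2, n_points)
        x = np.log10(rate)
        if kind == "lc_three_region":
            logv = _loglog_piecewise(x, breaks=[-0.7, 0.9], slopes=[-0.8, -0.1, -0.6], y0=2.0)
        elif kind == "simple":
            logv = 1.0 - 0.5 * x
        else:
            logv = _loglog_piecewise(x, breaks=[0.0], slopes=[0.0, -0.7], y0=1.0)
        visc = 10.0**logv * jitter(n_points)
        return RheoSweep(mode="steady", shear_rate=rate, viscosity=visc)
    raise ValueError(f"unknown sweep kind {kind!r}")
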