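"""Estimation of DLVO parameters from colloid-probe force curves.

The estimation pipeline mirrors how such force curves are analyzed in
practice:

1. the approach trace is baseline-zeroed and restricted to its
   large-distance repulsive tail, where the double-layer term dominates;
2. the known sphere–plate van der Waals attraction ``-A_H r / 6 D^2`` (with
   the Hamaker constant fixed at its literature value, not fitted) is removed,
   leaving the pure screened-Coulomb tail;
3. ``ln F`` is regressed on ``D`` by ordinary least squares, so the Debye
   parameter is ``kappa = -slope`` and the interaction constant
   ``Z = exp(intercept) / (kappa r)``.

With ``hamaker=0`` step 2 is skipped and the fit is the classical
"neglect-VDW-in-the-tail" log-linear fit. A one-parameter variant re-fits all
curves with kappa held at a reference value, which isolates differences in Z
(i.e. in surface potential) across sample pairs measured in nominally the
same electrolyte.

The statsmodels-style surface is :class:`DLVOForceModel` (data + options) and
:class:`DLVOFitResults` (estimates, uncertainties, diagnostics, ``summary()``,
``predict()``, ``plot()``); :func:`loglinear_fit` and
:func:`refit_fixed_kappa` are thin functional wrappers over it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.signal import savgol_filter

from .curves import ForceCurve, select_tail
from .physics import (
    DEFAULT_HAMAKER,
    DEFAULT_SLOPE_THRESHOLD,
    DLVOParameters,
    ProbeGeometry,
    dlvo_force,
    limit_distance,
)

__all__ = [
    "TailPolicy",
    "DLVOForceModel",
    "DLVOFitResults",
    "FitResult",
    "PairSummary",
    "loglinear_fit",
    "refit_fixed_kappa",
    "extract_limit_distance",
    "aggregate_pairs",
    "summarize_pairs",
]

_J_PER_NM_TO_NN = 1.0e18


@dataclass(frozen=True)
class TailPolicy:
    """Rules selecting the large-distance tail used in the log-linear fit.

    ``d_min=None`` derives the cut as ``2 / kappa_init`` from a coarse
    two-point log-slope estimate of the screening length, i.e. the tail starts
    two screening lengths out, past the short-range contact artifacts.
    ``min_force`` (nN) keeps the fit above the instrument noise floor — the
    default is about five times a typical force noise sd of 2e-3 nN.
    """

    d_min: float | None = None
    min_force: float = 1.0e-2

    def resolve_d_min(self, curve: ForceCurve) -> float:
        if self.d_min is not None:
            return self.d_min
        kappa0 = _coarse_kappa(curve, self.min_force)
        d_min = 2.0 / kappa0
        return float(np.clip(d_min, curve.distance[0], curve.distance[-1]))


def _coarse_kappa(curve: ForceCurve, min_force: float) -> float:
    """Two-point log-slope screening estimate used only to place the tail cut."""
    c = curve.sorted()
    pos = np.nonzero(c.force > max(min_force, 0.0))[0]
    if pos.size < 2:
        raise ValueError("cannot estimate a screening length: fewer than 2 positive-force points")
    i = pos[int(0.5 * (pos.size - 1))]
    j = pos[int(0.9 * (pos.size - 1))]
    if j <= i:
        i, j = pos[0], pos[-1]
    dd = c.distance[j] - c.distance[i]
    if dd <= 0 or c.force[j] >= c.force[i]:
        return 0.04  # fall back to a typical dilute-aqueous value, 1/nm
    return float(np.log(c.force[i] / c.force[j]) / dd)


class DLVOForceModel:
    """Sphere–plate DLVO model bound to one measured force curve.

    Parameters
    ----------
    curve : ForceCurve
        Approach trace, baseline-corrected, distances in nm and forces in nN.
    geometry : ProbeGeometry, optional
        Colloid-probe radius (default 5 um sphere).
    hamaker : float, optional
        Hamaker constant in J, held fixed during fitting. Set to 0 to fit the
        pure double-layer tail without the van der Waals correction.
    tail_policy : TailPolicy, optional

    Examples
    --------
    >>> res = DLVOForceModel(curve).fit()
    >>> res.kappa, res.z_const, res.r_squared     # doctest: +SKIP
    """

    def __init__(
        self,
        curve: ForceCurve,
        geometry: ProbeGeometry | None = None,
        hamaker: float = DEFAULT_HAMAKER,
        tail_policy: TailPolicy | None = None,
    ):
        self.curve = curve
        self.geometry = geometry or ProbeGeometry()
        if hamaker < 0:
            raise ValueError("hamaker must be >= 0 J")
        self.hamaker = hamaker
        self.tail_policy = tail_policy or TailPolicy()

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, distance_col: str = "distance_nm", force_col: str = "force_nN", **kw
    ) -> "DLVOForceModel":
        """Build from a dataframe with distance/force columns (nm, nN)."""
        curve = ForceCurve(
            distance=df[distance_col].to_numpy(dtype=float),
            force=df[force_col].to_numpy(dtype=float),
            pair_label=str(df["pair_label"].iloc[0]) if "pair_label" in df else "",
        )
        return cls(curve, **kw)

    def _tail(self) -> ForceCurve:
        d_min = self.tail_policy.resolve_d_min(self.curve)
        return select_tail(self.curve, d_min, self.tail_policy.min_force)

    def _log_edl(self, tail: ForceCurve) -> np.ndarray:
        """ln of the double-layer part: measured force plus the known VDW pull."""
        r = self.geometry.sphere_radius
        edl = tail.force + self.hamaker * r / (6.0 * tail.distance**2) * _J_PER_NM_TO_NN
        if np.any(edl <= 0):
            raise ValueError("non-positive forces in tail after the van der Waals correction")
        return np.log(edl)

    def fit(self, fixed_kappa: float | None = None) -> "DLVOFitResults":
        """Estimate (kappa, Z) by OLS on the log-transformed tail.

        With ``fixed_kappa`` the screening parameter is held and only the
        intercept (hence Z) is estimated — the cross-sample re-fit mode.
        """
        tail = self._tail()
        d = tail.distance
        y = self._log_edl(tail)
        if np.ptp(d) == 0:
            raise ValueError("degenerate tail: zero distance variance")
        r = self.geometry.sphere_radius

        if fixed_kappa is None:
            ols = sm.OLS(y, sm.add_constant(d)).fit()
            intercept, slope = ols.params
            kappa = -float(slope)
            if kappa <= 0:
                raise ValueError("fitted tail is not decaying (kappa <= 0); check preprocessing")
            kappa_se = float(ols.bse[1])
            r2 = float(ols.rsquared)
            cov = ols.cov_params()
            z = math.exp(intercept) / (kappa * r)
            # delta method on Z(intercept, slope)
            dz_db = z
            dz_ds = z / kappa
            z_var = (
                dz_db**2 * cov[0, 0] + dz_ds**2 * cov[1, 1] + 2 * dz_db * dz_ds * cov[0, 1]
            )
            z_se = math.sqrt(max(z_var, 0.0))
        else:
            if fixed_kappa <= 0:
                raise ValueError("fixed_kappa must be > 0 nm^-1")
            kappa = float(fixed_kappa)
            shifted = y + kappa * d
            intercept = float(np.mean(shifted))
            kappa_se = 0.0
            n = len(d)
            intercept_se = float(np.std(shifted, ddof=1) / math.sqrt(n)) if n > 1 else 0.0
            z = math.exp(intercept) / (kappa * r)
            z_se = z * intercept_se
            pred = intercept - kappa * d
            ss_res = float(np.sum((y - pred) ** 2))
            ss_tot = float(np.sum((y - y.mean()) ** 2))
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
            r2 = min(max(r2, 0.0), 1.0)

        return DLVOFitResults(
            kappa=kappa,
            z_const=z,
            kappa_se=kappa_se,
            z_se=z_se,
            r_squared=r2,
            n_points=len(d),
            tail_range=(float(d[0]), float(d[-1])),
            pair_label=tail.pair_label,
            geometry=self.geometry,
            hamaker=self.hamaker,
            kappa_fixed=fixed_kappa is not None,
            model=self,
        )


@dataclass
class DLVOFitResults:
    """Fitted DLVO parameters for one curve, with uncertainties and diagnostics."""

    kappa: float  # 1/nm
    z_const: float  # nN
    kappa_se: float
    z_se: float
    r_squared: float
    n_points: int
    tail_range: tuple[float, float]
    pair_label: str = ""
    geometry: ProbeGeometry = field(default_factory=ProbeGeometry)
    hamaker: float = DEFAULT_HAMAKER
    kappa_fixed: bool = False
    model: DLVOForceModel | None = None

    @property
    def params(self) -> DLVOParameters:
        """The fitted parameter bundle, usable with the forward model."""
        return DLVOParameters(
            kappa=self.kappa, z_const=self.z_const, hamaker=self.hamaker, geometry=self.geometry
        )

    @property
    def debye_length(self) -> float:
        """Screening length 1/kappa in nm."""
        return 1.0 / self.kappa

    def predict(self, distance) -> np.ndarray:
        """Forward DLVO force (nN) at the given separations (nm)."""
        return dlvo_force(self.params, distance)

    def limit_distance(self, slope_threshold: float = DEFAULT_SLOPE_THRESHOLD) -> float:
        """Analytic limit distance of the fitted force profile (nm)."""
        return limit_distance(self.params, slope_threshold)

    def summary(self) -> str:
        lines = [
            "DLVO sphere-plate log-linear fit",
            "=" * 48,
            f"pair label        {self.pair_label or '-'}",
            f"n tail points     {self.n_points}",
            f"tail range        {self.tail_range[0]:.2f} .. {self.tail_range[1]:.2f} nm",
            f"sphere radius     {self.geometry.sphere_radius:.0f} nm",
            f"Hamaker constant  {self.hamaker:.3g} J (fixed)",
            "-" * 48,
            f"kappa             {self.kappa:.5g} 1/nm"
            + ("  (fixed)" if self.kappa_fixed else f"  +/- {self.kappa_se:.2g}"),
            f"Debye length      {self.debye_length:.4g} nm",
            f"Z                 {self.z_const:.5g} nN  +/- {self.z_se:.2g}",
            f"R^2 (ln F on D)   {self.r_squared:.6f}",
            "=" * 48,
        ]
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 300):
        """Overlay the measured curve and the fitted DLVO profile (log force)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if self.model is not None:
            c = self.model.curve.sorted()
            ax.plot(c.distance, c.force, ".", ms=3, alpha=0.5, label="measured")
        lo, hi = self.tail_range
        grid = np.linspace(max(lo * 0.5, 1e-2), hi * 1.2, n_grid)
        ax.plot(grid, self.predict(grid), "-", label="DLVO fit")
        ax.axvspan(lo, hi, alpha=0.1, label="fit tail")
        ax.set_xlabel("separation D (nm)")
        ax.set_ylabel("force (nN)")
        ax.set_yscale("symlog", linthresh=1e-4)
        ax.legend()
        return ax

    def to_dict(self) -> dict:
        return {
            "pair_label": self.pair_label,
            "kappa_per_nm": self.kappa,
            "z_nN": self.z_const,
            "kappa_se": self.kappa_se,
            "z_se": self.z_se,
            "r_squared": self.r_squared,
            "n_points": self.n_points,
            "tail_lo_nm": self.tail_range[0],
            "tail_hi_nm": self.tail_range[1],
        }


#: Spec-facing alias: the per-curve fit record.
FitResult = DLVOFitResults


@dataclass
class PairSummary:
    """Replicate-aggregated statistics for one probe–substrate pair."""

    pair_label: str
    kappa_mean: float
    z_mean: float
    limit_distance_mean: float
    limit_distance_sd: float
    zeta_probe: float | None = None
    zeta_substrate: float | None = None
    n_curves: int = 0
    kappa_sd: float = 0.0
    z_sd: float = 0.0


def loglinear_fit(
    curve: ForceCurve,
    geometry: ProbeGeometry | None = None,
    tail_policy: TailPolicy | None = None,
    hamaker: float = DEFAULT_HAMAKER,
) -> DLVOFitResults:
    """Free log-linear fit: kappa from the slope, Z from the intercept."""
    return DLVOForceModel(curve, geometry, hamaker, tail_policy).fit()


def refit_fixed_kappa(
    curve: ForceCurve,
    kappa_fixed: float,
    geometry: ProbeGeometry | None = None,
    tail_policy: TailPolicy | None = None,
    hamaker: float = DEFAULT_HAMAKER,
) -> DLVOFitResults:
    """One-parameter re-fit of Z with the screening parameter held fixed."""
    return DLVOForceModel(curve, geometry, hamaker, tail_policy).fit(fixed_kappa=kappa_fixed)


def extract_limit_distance(
    curve_or_fit,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
    mode: str = "analytic",
    geometry: ProbeGeometry | None = None,
    window: int = 11,
    polyorder: int = 2,
) -> float:
    """Limit distance (nm) from a fitted profile or directly from data.

    ``analytic`` evaluates the threshold criterion on the fitted analytic
    profile (fitting the curve first if a raw curve is given). ``empirical``
    smooths the measured slope with a local polynomial (Savitzky–Golay,
    window 11, order 2) and scans from the far end inward for the first point
    whose slope drops below ``-slope_threshold``.
    """
    if mode == "analytic":
        fit = curve_or_fit
        if isinstance(curve_or_fit, ForceCurve):
            fit = loglinear_fit(curve_or_fit, geometry)
        return fit.limit_distance(slope_threshold)
    if mode != "empirical":
        raise ValueError(f"unknown mode {mode!r}")
    if not isinstance(curve_or_fit, ForceCurve):
        raise ValueError("empirical mode needs a ForceCurve")
    c = curve_or_fit.sorted()
    if len(c) < window:
        raise ValueError(f"curve shorter than the smoothing window ({window})")
    dx = np.diff(c.distance)
    if np.allclose(dx, dx[0], rtol=1e-6):
        slope = savgol_filter(c.force, window, polyorder, deriv=1, delta=float(dx[0]))
    else:  # non-uniform grid: smooth then finite-difference
        smoothed = savgol_filter(c.force, window, polyorder)
        slope = np.gradient(smoothed, c.distance)
    hits = np.nonzero(slope <= -slope_threshold)[0]
    if hits.size == 0:
        raise ValueError(
            f"slope never reaches -{slope_threshold} nN/nm within "
            f"[{c.distance[0]}, {c.distance[-1]}] nm"
        )
    return float(c.distance[hits[-1]])


def aggregate_pairs(
    results: list[DLVOFitResults],
    limit_distances: list[float] | None = None,
    zeta: tuple[float, float] | None = None,
) -> PairSummary:
    """Aggregate replicate fits for one pair into means and sample sds."""
    if not results:
        raise ValueError("no fit results to aggregate")
    labels = {r.pair_label for r in results}
    if len(labels) > 1:
        raise ValueError(f"mixed pair labels in aggregation: {sorted(labels)}")
    kappas = np.array([r.kappa for r in results])
    zs = np.array([r.z_const for r in results])
    if limit_distances is None:
        limit_distances = [r.limit_distance() for r in results]
    ld = np.asarray(limit_distances, dtype=float)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if x.size > 1 else 0.0

    return PairSummary(
        pair_label=labels.pop(),
        kappa_mean=float(kappas.mean()),
        z_mean=float(zs.mean()),
        limit_distance_mean=float(ld.mean()),
        limit_distance_sd=_sd(ld),
        zeta_probe=None if zeta is None else zeta[0],
        zeta_substrate=None if zeta is None else zeta[1],
        n_curves=len(results),
        kappa_sd=_sd(kappas),
        z_sd=_sd(zs),
    )


def summarize_pairs(
    results: list[DLVOFitResults],
    zeta_by_pair: dict[str, tuple[float, float]] | None = None,
    slope_threshold: float = DEFAULT_SLOPE_THRESHOLD,
) -> pd.DataFrame:
    """Group fits by pair label into a per-pair summary table.

    Columns mirror the conventional reporting for such series: zeta potential
    of probe and substrate, limit distance mean +/- sd, kappa and Z means.
    """
    by_label: dict[str, list[DLVOFitResults]] = {}
    for r in results:
        by_label.setdefault(r.pair_label, []).append(r)
    rows = []
    for label in sorted(by_label):
        zeta = (zeta_by_pair or {}).get(label)
        fits = by_label[label]
        ld = [f.limit_distance(slope_threshold) for f in fits]
        s = aggregate_pairs(fits, limit_distances=ld, zeta=zeta)
        rows.append(
            {
                "pair_label": s.pair_label,
                "zeta_probe_mV": s.zeta_probe,
                "zeta_substrate_mV": s.zeta_substrate,
                "limit_distance_nm": s.limit_distance_mean,
                "limit_distance_sd_nm": s.limit_distance_sd,
                "kappa_per_nm": s.kappa_mean,
                "z_nN": s.z_mean,
                "n_curves": s.n_curves,
            }
        )
    return pd.DataFrame(rows)
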