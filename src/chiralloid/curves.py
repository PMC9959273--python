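"""Data model and text I/O for AFM force–distance curves.

Native format: headered TSV with columns ``distance_nm, force_nN, direction,
pair_label, location_id, replicate_id``; multi-curve files separate curves
with blank lines. A bare two-column dialect (distance_nm, force_nN) is also
accepted for single curves. Preprocessing covers extend/retract selection,
baseline zeroing against the far-field window and tail selection for the
log-linear DLVO fit.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ForceCurve",
    "CurveSet",
    "read_curves",
    "write_curves",
    "select_extend",
    "baseline_correct",
    "select_tail",
]

_COLUMNS = ["distance_nm", "force_nN", "direction", "pair_label", "location_id", "replicate_id"]
_MIN_POINTS = 8


@dataclass
class ForceCurve:
    """One approach or retract trace: paired distance (nm) / force (nN) arrays.

    Distances must be strictly monotone; curves loaded from disk are
    normalized to ascending order with duplicate distances averaged.
    """

    distance: np.ndarray
    force: np.ndarray
    direction: str = "extend"
    pair_label: str = ""
    location_id: int = 0
    replicate_id: int = 0

    def __post_init__(self) -> None:
        self.distance = np.asarray(self.distance, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.distance.shape != self.force.shape or self.distance.ndim != 1:
            raise ValueError("distance and force must be 1-d arrays of equal length")
        if len(self.distance) < _MIN_POINTS:
            raise ValueError(f"a force curve needs >= {_MIN_POINTS} points, got {len(self.distance)}")
        if not (np.isfinite(self.distance).all() and np.isfinite(self.force).all()):
            raise ValueError("non-finite values in force curve")
        steps = np.diff(self.distance)
        if not (np.all(steps > 0) or np.all(steps < 0)):
            raise ValueError("distances must be strictly monotone")
        if self.direction not in ("extend", "retract"):
            raise ValueError("direction must be 'extend' or 'retract'")

    def __len__(self) -> int:
        return len(self.distance)

    def sorted(self) -> "ForceCurve":
        """Copy with distances ascending."""
        if self.distance[0] < self.distance[-1]:
            return self
        return replace(self, distance=self.distance[::-1].copy(), force=self.force[::-1].copy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "distance_nm": self.distance,
                "force_nN": self.force,
                "direction": self.direction,
                "pair_label": self.pair_label,
                "location_id": self.location_id,
                "replicate_id": self.replicate_id,
            }
        )


@dataclass
class CurveSet:
    """A bag of force curves plus free-form metadata.

    ``metadata['heterogeneous']`` is set when the curves do not all share one
    pair label (e.g. a mixed measurement session).
    """

    curves: list[ForceCurve] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {c.pair_label for c in self.curves}
        if len(labels) > 1:
            self.metadata.setdefault("heterogeneous", True)

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    @property
    def pair_labels(self) -> list[str]:
        return sorted({c.pair_label for c in self.curves})


def _curve_from_frame(df: pd.DataFrame, index: int) -> tuple[ForceCurve | None, int]:
    """Build one curve from a parsed block; returns (curve, n_dropped_rows)."""
    numeric = df[["distance_nm", "force_nN"]].apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    dropped = int((~keep).sum())
    df = df.loc[keep]
    numeric = numeric.loc[keep]
    if df.empty:
        return None, dropped
    d = numeric["distance_nm"].to_numpy()
    if len(d) >= 2:
        steps = np.diff(d)
        # non-strict monotone is tolerated (duplicate distances are averaged);
        # anything else means the file rows are shuffled
        if not (np.all(steps >= 0) or np.all(steps <= 0)):
            raise ValueError(f"curve {index}: distances are not monotone (shuffled rows?)")
    grouped = (
        pd.DataFrame({"distance_nm": d, "force_nN": numeric["force_nN"].to_numpy()})
        .groupby("distance_nm", as_index=False)
        .mean()
        .sort_values("distance_nm")
    )
    meta = df.iloc[0]
    curve = ForceCurve(
        distance=grouped["distance_nm"].to_numpy(),
        force=grouped["force_nN"].to_numpy(),
        direction=str(meta.get("direction", "extend")),
        pair_label=str(meta.get("pair_label", "")),
        location_id=int(meta.get("location_id", 0)),
        replicate_id=int(meta.get("replicate_id", 0)),
    )
    return curve, dropped


def read_curves(path, dialect: str = "multi_curve_tsv") -> CurveSet:
    """Read a native TSV/CSV force-curve file into a validated ``CurveSet``.

    Rows with non-finite entries are dropped and counted in
    ``metadata['dropped_rows']``; files whose distances are neither ascending
    nor descending raise, naming the offending curve index.
    """
    if dialect not in ("two_column_tsv", "multi_curve_tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    if not text.strip():
        raise ValueError(f"empty force-curve file: {path}")
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"

    lines = [ln for ln in text.splitlines() if not ln.lstrip().startswith("#")]
    header = None
    blocks: list[list[str]] = [[]]
    for ln in lines:
        if not ln.strip():
            if blocks[-1]:
                blocks.append([])
            continue
        if header is None and any(c.isalpha() for c in ln.split(sep)[0]):
            header = ln
            continue
        blocks[-1].append(ln)
    blocks = [b for b in blocks if b]
    if not blocks:
        raise ValueError(f"no data rows in {path}")
    if header is None:
        header = sep.join(_COLUMNS[:2])

    curves: list[ForceCurve] = []
    dropped_total = 0
    for i, block in enumerate(blocks):
        df = pd.read_csv(io.StringIO(header + "\n" + "\n".join(block)), sep=sep)
        curve, dropped = _curve_from_frame(df, i)
        dropped_total += dropped
        if curve is not None:
            curves.append(curve)
    if dialect == "two_column_tsv" and len(curves) != 1:
        raise ValueError(f"two_column_tsv expects exactly one curve, found {len(curves)}")
    return CurveSet(curves=curves, metadata={"dropped_rows": dropped_total, "source": str(path)})


def write_curves(curves: CurveSet, path) -> None:
    """Write a ``CurveSet`` to the native TSV dialect (blank-line separated).

    Round-trips through :func:`read_curves` to 1e-9 relative on both columns.
    """
    sep = "," if Path(path).suffix.lower() == ".csv" else "\t"
    with open(path, "w") as fh:
        fh.write(sep.join(_COLUMNS) + "\n")
        for i, c in enumerate(curves):
            if i:
                fh.write("\n")
            for d, f in zip(c.distance, c.force):
                fh.write(
                    sep.join(
                        [
                            f"{d:.12g}",
                            f"{f:.12g}",
                            c.direction,
                            c.pair_label,
                            str(c.location_id),
                            str(c.replicate_id),
                        ]
                    )
                    + "\n"
                )


def select_extend(curve_or_set):
    """Keep only approach-phase data (the extend trace).

    The approach trace is analyzed because the retract trace carries the
    probe–substrate adhesion hysteresis. Accepts a single curve (identity or
    error) or a set (filters to extend curves).
    """
    if isinstance(curve_or_set, CurveSet):
        kept = [c for c in curve_or_set if c.direction == "extend"]
        if not kept:
            raise ValueError("no extend (approach) curves in set")
        return CurveSet(curves=kept, metadata=dict(curve_or_set.metadata))
    if curve_or_set.direction != "extend":
        raise ValueError("curve lacks an approach phase (retract-only)")
    return curve_or_set


def baseline_correct(curve: ForceCurve, window_fraction: float = 0.2) -> ForceCurve:
    """Zero the force baseline against the far-field window.

    The mean force over the farthest ``window_fraction`` of distances is
    subtracted, so the corrected curve decays to zero where the surfaces no
    longer interact. Idempotent.
    """
    if not 0 < window_fraction <= 0.5:
        raise ValueError("window_fraction must be in (0, 0.5]")
    c = curve.sorted()
    n_win = int(np.ceil(window_fraction * len(c)))
    if n_win < 3:
        raise ValueError(f"baseline window has {n_win} points; need >= 3")
    offset = float(np.mean(c.force[-n_win:]))
    return replace(c, force=c.force - offset)


def select_tail(curve: ForceCurve, d_min: float, min_force: float) -> ForceCurve:
    """Select the large-distance repulsive tail used for the log-linear fit.

    Starting at ``d_min`` (nm), points are kept while the force stays above
    ``min_force`` (nN) — the contiguous run over which the log transform is
    well defined and above the noise floor. Requires >= 8 surviving points.
    """
    c = curve.sorted()
    if not (c.distance[0] <= d_min <= c.distance[-1]):
        raise ValueError(
            f"d_min={d_min} nm outside curve range [{c.distance[0]}, {c.distance[-1]}] nm"
        )
    start_candidates = np.nonzero((c.distance >= d_min) & (c.force > min_force))[0]
    if start_candidates.size == 0:
        raise ValueError(
            f"no points with distance >= {d_min} nm and force > {min_force} nN "
            f"(curve has {len(c)} points)"
        )
    start = int(start_candidates[0])
    stop = start
    while stop < len(c) and c.force[stop] > min_force:
        stop += 1
    n_kept = stop - start
    if n_kept < _MIN_POINTS:
        raise ValueError(
            f"tail selection kept {n_kept} of {len(c)} points "
            f"(d_min={d_min} nm, min_force={min_force} nN); need >= {_MIN_POINTS}"
        )
    return replace(c, distance=c.distance[start:stop].copy(), force=c.force[start:stop].copy())
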