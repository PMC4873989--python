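"""Plate statistics flanking the profiling core.

Three stages:

* percent-activity computation from plate control windows (the two-parameter
  reporter scheme: percent inhibition with ligand stimulation, percent
  activation without it);
* the high-content senescence screen's hit filter — fold change of mean
  per-cell cytosolic area, treated over vehicle, with an inclusive >= 2-fold
  threshold;
* four-parameter logistic (4PL) dose-response fitting for confirmation
  assays, reporting IC50 on the concentration scale of the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import ReadoutMode, ValidationError


class DegenerateFitError(ValueError):
    """Raised when a dose-response table carries no fittable signal."""


@dataclass(frozen=True)
class PlateControls:
    """Per-plate control means defining the activity window."""

    background_signal: float
    stimulated_signal: float


def percent_activity(signal: float, controls: PlateControls,
                     mode: ReadoutMode) -> float:
    """Normalize a raw well signal to percent activity.

    inhibition_with_ligand:
        100 * (1 - (signal - background) / (stimulated - background)),
        so the stimulated control reads 0% and the background 100%.
    activation_without_ligand / viability:
        100 * (signal - background) / (stimulated - background), relative to
        the reference-agonist (or vehicle-growth) window.
    """
    window = controls.stimulated_signal - controls.background_signal
    if window == 0:
        raise ValidationError(
            "zero control window: stimulated equals background signal"
        )
    frac = (signal - controls.background_signal) / window
    if mode is ReadoutMode.INHIBITION_WITH_LIGAND:
        return 100.0 * (1.0 - frac)
    if mode in (ReadoutMode.ACTIVATION_WITHOUT_LIGAND, ReadoutMode.VIABILITY):
        return 100.0 * frac
    raise ValidationError(f"unknown readout mode {mode!r}")


def area_fold_change(treated_areas, vehicle_areas) -> float:
    """mean(treated) / mean(vehicle) of per-cell areas.

    Areas must be positive (they come from a segmentation step upstream of
    this package); arm means are used rather than per-cell ratios because
    cells are not paired between arms.
    """
    t = np.asarray(treated_areas, dtype=float)
    v = np.asarray(vehicle_areas, dtype=float)
    if t.size == 0 or v.size == 0:
        raise ValidationError("empty cell-area sample")
    if np.any(t <= 0) or np.any(v <= 0):
        raise ValidationError("cell areas must be positive")
    return float(t.mean() / v.mean())


@dataclass
class ScreenResult:
    """Per-compound fold changes with the hit flag at a given threshold."""

    rows: pd.DataFrame  # compound_id, fold_change, n_cells_treated, n_cells_vehicle, hit
    threshold: float

    def __post_init__(self) -> None:
        required = {"compound_id", "fold_change", "hit"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValidationError(f"screen rows missing columns: {sorted(missing)}")
        if np.any(self.rows["fold_change"].to_numpy(float) <= 0):
            raise ValidationError("fold changes must be positive")
        expected = self.rows["fold_change"] >= self.threshold
        if not (self.rows["hit"].astype(bool) == expected).all():
            raise ValidationError("hit flags inconsistent with threshold")

    @property
    def n_hits(self) -> int:
        return int(self.rows["hit"].sum())

    @property
    def hit_ids(self) -> list[str]:
        return self.rows.loc[self.rows["hit"], "compound_id"].tolist()


def select_hits(fold_changes: pd.DataFrame, threshold: float = 2.0
                ) -> ScreenResult:
    """Flag hits with fold_change >= threshold (inclusive).

    ``fold_changes`` needs at least compound_id and fold_change columns; a
    boundary compound at exactly the threshold is a hit.
    """
    if threshold <= 0:
        raise ValidationError(f"threshold must be positive, got {threshold}")
    rows = fold_changes.copy()
    rows["hit"] = rows["fold_change"] >= threshold
    return ScreenResult(rows=rows, threshold=threshold)


def screen_fold_changes(treated: pd.DataFrame, vehicle: pd.DataFrame,
                        threshold: float = 2.0) -> ScreenResult:
    """Run the area-fold-change filter over a per-cell screening table.

    ``treated``: columns (compound_id, area), one row per segmented cell;
    ``vehicle``: column (area) for the pooled vehicle-control cells.
    """
    v = vehicle["area"].to_numpy(float)
    records = []
    for cid, grp in treated.groupby("compound_id", sort=True):
        t = grp["area"].to_numpy(float)
        records.append({
            "compound_id": str(cid),
            "fold_change": area_fold_change(t, v),
            "n_cells_treated": t.size,
            "n_cells_vehicle": v.size,
        })
    return select_hits(pd.DataFrame.from_records(records), threshold)


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------

@dataclass
class DoseResponseFit:
    """4PL parameters with fit diagnostics.

    ``response = bottom + (top - bottom) / (1 + (conc / ic50)**hill)``; with
    hill > 0 the curve runs from ``top`` at low concentration down to
    ``bottom``.  Fits are canonicalized to hill > 0 (the 4PL is invariant
    under swapping bottom/top and negating hill), so ``ic50`` is always the
    midpoint concentration and ``top >= bottom`` means inhibition.
    """

    bottom: float
    top: float
    ic50: float
    hill: float
    rss: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValidationError("ic50 must be positive")

    def predict(self, conc) -> np.ndarray:
        c = np.asarray(conc, dtype=float)
        return four_pl(c, self.bottom, self.top, self.ic50, self.hill)


def four_pl(conc, bottom: float, top: float, ic50: float, hill: float
            ) -> np.ndarray:
    """Four-parameter logistic evaluated at concentrations ``conc``."""
    c = np.asarray(conc, dtype=float)
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_4pl(concentrations, responses) -> DoseResponseFit:
    """Least-squares 4PL fit with multi-start initialization.

    The model is parameterized internally on log-concentration
    (``log ic50`` is the free midpoint parameter), which makes the problem
    well-scaled across decade-spanning dose grids.  Three starts seed the
    midpoint at the 25/50/75% quantiles of log concentration; the best
    residual sum of squares wins.  A response table whose total range is
    indistinguishable from flat raises :class:`DegenerateFitError`.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if c.ndim != 1 or c.shape != y.shape:
        raise ValidationError("concentrations and responses must be equal-length 1-D")
    if np.any(c <= 0):
        raise ValidationError("concentrations must be positive")
    if not np.all(np.isfinite(y)):
        raise ValidationError("responses must be finite")
    if np.unique(c).size < 5:
        raise ValidationError("need at least 5 distinct concentrations")
    y_range = y.max() - y.min()
    scale = max(1.0, float(np.abs(y).max()))
    if y_range < 1e-9 * scale:
        raise DegenerateFitError("flat response table: no transition to fit")

    logc = np.log(c)
    # slope sign decides the initial hill orientation
    slope = np.corrcoef(logc, y)[0, 1] if np.std(y) > 0 else -1.0
    hill0 = 1.0 if slope < 0 else -1.0

    def residuals(p):
        b, t, log_ic50, h = p
        return b + (t - b) / (1.0 + np.exp(h * (logc - log_ic50))) - y

    best = None
    for q in (0.25, 0.5, 0.75):
        p0 = np.array([y.min(), y.max(), np.quantile(logc, q), hill0])
        sol = least_squares(residuals, p0, method="lm",
                            xtol=1e-14, ftol=1e-14, gtol=1e-14,
                            max_nfev=20000)
        rss = float(np.sum(sol.fun ** 2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    rss, sol = best
    b, t, log_ic50, h = sol.x
    if h < 0:  # canonicalize: swap asymptotes, flip hill
        b, t, h = t, b, -h
    return DoseResponseFit(bottom=float(b), top=float(t),
                           ic50=float(np.exp(log_ic50)), hill=float(h),
                           rss=rss, converged=bool(sol.success),
                           n_points=int(c.size))
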