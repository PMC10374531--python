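"""Hertzian contact fitting of force-indentation curves and Young's-modulus maps.

The spherical (colloidal-probe) Hertz model relates force to indentation as

    F = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2)

with E the Young's modulus, nu the Poisson ratio (0.5 for an incompressible
material) and R the sphere radius. The model is the non-adhesive limit and,
per finite-element evidence for micrometre-scale spherical indenters, stays
accurate for indentations as large as R; fits with delta_max > R are
therefore returned but flagged rather than rejected.

In this one-parameter form the model is linear in the prefactor
c = F / delta^(3/2), so the least-squares fit is closed-form:

    c_hat = sum(F * delta^(3/2)) / sum(delta^3)

which is deterministic (no initialization or convergence tolerances) and is
cross-checked against iterative nonlinear least squares in the test suite.

Fitting is restricted to the 20-80% band of the indentation axis: the first
20% is dominated by superficial non-crosslinked fibres and surface roughness,
the last 20% avoids the maximum-load turnaround.

No finite-thickness (bottom-effect) correction is applied: the intended
specimens (100-200 µm tissue sections) are much thicker than the contact
radius at maximum indentation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import AllCurvesFailedError, ECMechError, FitError, ParameterError
from .forcecurve_io import ForceIndentationCurve, ForceVolume, ProbeCalibration
from .preprocessing import (
    QC_MIN_INDENTATION_NM,
    QC_MIN_R_SQUARED,
    ContactPointResult,
    find_contact_point,
    rescale,
)

logger = logging.getLogger(__name__)

#: Pa per (nN/nm^2): with forces in nN and lengths in nm, the prefactor-to-
#: modulus conversion lands in GPa.
GPA_TO_PA = 1e9


@dataclass
class FitConfig:
    """Settings of the per-curve Hertz fit.

    poisson_ratio
        Poisson ratio nu; 0.5 (incompressible) by default.
    fit_window
        (lower, upper) fractions of the maximum indentation delimiting the
        fitted band on the indentation axis; default (0.20, 0.80).
    min_points
        Minimum number of samples required inside the window.
    """

    poisson_ratio: float = 0.5
    fit_window: tuple[float, float] = (0.20, 0.80)
    min_points: int = 10

    def __post_init__(self) -> None:
        lo, hi = self.fit_window
        if not (0 <= lo < hi <= 1):
            raise ParameterError(f"invalid fit window ({lo}, {hi})")
        if not (0 <= self.poisson_ratio < 0.5 + 1e-9):
            raise ParameterError(f"invalid Poisson ratio {self.poisson_ratio}")
        if self.min_points < 3:
            raise ParameterError("min_points must be >= 3")


@dataclass
class HertzFitResult:
    """Result of fitting one force-indentation curve."""

    E: float  # Pa
    prefactor: float  # nN / nm^(3/2)
    r_squared: float
    delta_max: float  # nm
    n_points_fit: int
    delta_exceeds_radius: bool  # validity flag: delta_max > R (fit kept, flagged)


def hertz_force(
    delta: np.ndarray | float, E: float, R: float, nu: float = 0.5
) -> np.ndarray | float:
    """Hertzian force (nN) for indentation ``delta`` (nm).

    Parameters are the Young's modulus E in Pa, sphere radius R in nm and
    Poisson ratio nu. Negative indentations are a domain error.
    """
    delta_arr = np.asarray(delta, dtype=float)
    if np.any(delta_arr < 0):
        raise ParameterError("indentation must be non-negative")
    if E <= 0 or R <= 0:
        raise ParameterError("E and R must be positive")
    c = modulus_to_prefactor(E, R, nu)
    out = c * delta_arr**1.5
    return out if isinstance(delta, np.ndarray) else float(out)


def modulus_to_prefactor(E_pa: float, R_nm: float, nu: float = 0.5) -> float:
    """Convert a modulus (Pa) to the Hertz prefactor c (nN/nm^(3/2))."""
    return (4.0 / 3.0) * (E_pa / GPA_TO_PA) / (1.0 - nu**2) * np.sqrt(R_nm)


def prefactor_to_modulus(c: float, R_nm: float, nu: float = 0.5) -> float:
    """Convert the fitted prefactor c (nN/nm^(3/2)) to a modulus in Pa."""
    return 0.75 * c * (1.0 - nu**2) / np.sqrt(R_nm) * GPA_TO_PA


def fit_curve(
    curve: ForceIndentationCurve,
    calib: ProbeCalibration,
    cfg: FitConfig | None = None,
) -> HertzFitResult:
    """Fit the Hertz model to one rescaled curve over the indentation window.

    Closed-form least squares on F = c * delta^(3/2) restricted to
    delta in [lower, upper] * delta_max; the modulus follows from c, R and nu.
    R-squared is computed on the same window.

    Raises
    ------
    FitError
        If fewer than ``cfg.min_points`` samples fall in the window, or the
        fitted prefactor is non-positive (non-physical).
    """
    cfg = cfg or FitConfig()
    delta = curve.indentation
    force = curve.force
    if len(delta) == 0:
        raise FitError(f"curve {curve.curve_id}: empty curve")
    delta_max = float(delta.max())
    lo, hi = cfg.fit_window
    mask = (delta >= lo * delta_max) & (delta <= hi * delta_max)
    n_fit = int(mask.sum())
    if n_fit < cfg.min_points:
        raise FitError(
            f"curve {curve.curve_id}: only {n_fit} points in the "
            f"[{lo:.0%}, {hi:.0%}] indentation window (need {cfg.min_points})"
        )
    dw = delta[mask]
    fw = force[mask]
    x = dw**1.5
    sxx = float((x * x).sum())  # = sum(delta^3)
    c = float((fw * x).sum()) / sxx
    if c <= 0:
        raise FitError(f"curve {curve.curve_id}: non-positive Hertz prefactor")
    resid = fw - c * x
    ss_tot = float(((fw - fw.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    flag = delta_max > calib.tip_radius
    if flag:
        logger.debug(
            "curve %s: delta_max %.0f nm exceeds tip radius %.0f nm; "
            "fit kept but flagged",
            curve.curve_id,
            delta_max,
            calib.tip_radius,
        )
    return HertzFitResult(
        E=prefactor_to_modulus(c, calib.tip_radius, cfg.poisson_ratio),
        prefactor=c,
        r_squared=r2,
        delta_max=delta_max,
        n_points_fit=n_fit,
        delta_exceeds_radius=flag,
    )


@dataclass
class YoungModulusMap:
    """Spatial map of fitted moduli over one force volume.

    ``E`` is a (rows, cols) array in Pa with NaN at missing or QC-discarded
    cells; ``fits`` holds the full per-cell fit result and ``qc`` the
    kept/discarded status with a reason for every cell that had a curve.
    Contact points are retained so downstream Monte Carlo error propagation
    can re-run rescaling and fitting without repeating the contact search.
    """

    patient: str
    condition: str
    roi: str
    E: np.ndarray
    fits: dict[tuple[int, int], HertzFitResult] = field(default_factory=dict)
    contact_points: dict[tuple[int, int], ContactPointResult] = field(default_factory=dict)
    qc: dict[tuple[int, int], tuple[str, str]] = field(default_factory=dict)
    force_volume: ForceVolume | None = None

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.E.shape  # type: ignore[return-value]

    def values(self) -> np.ndarray:
        """All fitted moduli (Pa) that passed QC, row-major order."""
        return self.E[np.isfinite(self.E)]

    @property
    def n_fitted(self) -> int:
        return int(np.isfinite(self.E).sum())

    def qc_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for status, _reason in self.qc.values():
            counts[status] = counts.get(status, 0) + 1
        return counts

    def to_table(self):
        """Per-cell TSV-ready table (row, col, E_Pa, r2, delta_max_nm, flag, status)."""
        import pandas as pd

        rows = []
        for (r, c), (status, reason) in sorted(self.qc.items()):
            fit = self.fits.get((r, c))
            rows.append(
                {
                    "row": r,
                    "col": c,
                    "E_Pa": fit.E if fit and status == "kept" else np.nan,
                    "r2": fit.r_squared if fit else np.nan,
                    "delta_max_nm": fit.delta_max if fit else np.nan,
                    "delta_exceeds_radius": bool(fit.delta_exceeds_radius) if fit else False,
                    "status": status,
                    "reason": reason,
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "row",
                "col",
                "E_Pa",
                "r2",
                "delta_max_nm",
                "delta_exceeds_radius",
                "status",
                "reason",
            ],
        )


def fit_volume(
    fv: ForceVolume,
    calib: ProbeCalibration | None = None,
    cfg: FitConfig | None = None,
    qc_min_indentation_nm: float = QC_MIN_INDENTATION_NM,
    qc_min_r_squared: float = QC_MIN_R_SQUARED,
) -> YoungModulusMap:
    """Run contact detection, rescaling and Hertz fitting on every grid cell.

    Cells failing any stage (or the quality controls: maximum indentation
    below ``qc_min_indentation_nm``, or fit R^2 below ``qc_min_r_squared``)
    are left missing in the map, with the reason recorded in ``map.qc``.
    Missing input cells stay missing. Deterministic given its inputs.

    Raises
    ------
    AllCurvesFailedError
        Only if no cell at all could be fitted.
    ParameterError
        If no calibration is supplied and the force volume carries none.
    """
    calib = calib or fv.calibration
    if calib is None:
        raise ParameterError(f"force volume {fv.key}: no probe calibration available")
    cfg = cfg or FitConfig()
    rows, cols = fv.grid_shape
    E = np.full((rows, cols), np.nan)
    out = YoungModulusMap(
        patient=fv.patient, condition=fv.condition, roi=fv.roi, E=E, force_volume=fv
    )
    for (r, c), raw in fv.iter_cells():
        try:
            cp = find_contact_point(raw, calib)
            fic = rescale(raw, calib, cp)
            fit = fit_curve(fic, calib, cfg)
        except ECMechError as exc:
            out.qc[(r, c)] = ("discarded", f"{type(exc).__name__}: {exc}")
            logger.debug("cell (%d,%d) of %s failed: %s", r, c, fv.key, exc)
            continue
        out.contact_points[(r, c)] = cp
        out.fits[(r, c)] = fit
        if fit.delta_max < qc_min_indentation_nm:
            out.qc[(r, c)] = (
                "discarded",
                f"low_indentation: delta_max {fit.delta_max:.0f} nm "
                f"< {qc_min_indentation_nm:.0f} nm",
            )
            continue
        if fit.r_squared < qc_min_r_squared:
            out.qc[(r, c)] = (
                "discarded",
                f"poor_fit: r2 {fit.r_squared:.3f} < {qc_min_r_squared}",
            )
            continue
        out.qc[(r, c)] = ("kept", "")
        E[r, c] = fit.E
    if fv.n_curves and out.n_fitted == 0:
        raise AllCurvesFailedError(
            f"force volume {fv.key}: all {fv.n_curves} curves failed fitting or QC"
        )
    logger.info(
        "force volume %s: %d/%d cells fitted", fv.key, out.n_fitted, fv.n_curves
    )
    return out
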