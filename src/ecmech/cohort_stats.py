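"""Aggregation of Young's-modulus maps into per-condition and per-patient statistics.

The aggregation ladder mirrors the measurement hierarchy:

curve -> force volume (FV)   per-FV median modulus from a Gaussian fit to the
                             log10-modulus histogram (log-normal hypothesis);
FV -> condition              mean of the per-FV medians, with the standard
                             error of that mean (SEM);
condition -> patient         relative stiffening
                             (E_neoplastic - E_normal) / E_normal and a
                             two-tailed Welch t-test on the two sets of FV
                             medians (p < 0.05 called significant);
patient -> cohort            associations of stiffening and normal-tissue
                             modulus with clinical covariates (age, sex,
                             chemotherapy, KRAS/BRAF status, grade,
                             histology).

Calibration uncertainty (10% on the spring constant, 5% on the deflection
sensitivity by default) is propagated by a Monte Carlo re-analysis of a
curve subsample and added in quadrature to the SEM.

Statistical conventions (documented choices):

* Welch (unequal-variance) t-tests on FV medians, never on pooled curves —
  pooled curves within an FV are spatially correlated.
* Zero-variance degenerate comparisons: identical groups give t = 0, p = 1;
  a correlation over a zero-variance covariate is reported as missing.
* The per-FV Gaussian fit carries a multimodality flag (fit R^2 < 0.9): a
  clearly multimodal modulus distribution must not be silently summarized by
  a single-mode fit, so the sample median is used and the flag raised.
* Association contrasts report raw p-values plus a Holm-adjusted column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import InsufficientDataError, ParameterError
from .forcecurve_io import ProbeCalibration
from .hertz import FitConfig, YoungModulusMap, fit_curve
from .preprocessing import rescale

logger = logging.getLogger(__name__)

MIN_VALUES_FOR_MEDIAN = 20
MULTIMODAL_R2_THRESHOLD = 0.9
SIGNIFICANCE_LEVEL = 0.05


# ---------------------------------------------------------------------------
# per-FV median
# ---------------------------------------------------------------------------

@dataclass
class FvMedianResult:
    """Per-force-volume median modulus with fit diagnostics."""

    value: float  # Pa
    method: str  # "gaussian_fit" | "sample_median"
    multimodal: bool
    fit_r_squared: float
    n_values: int

    def __float__(self) -> float:
        return self.value


def _fd_bins(x: np.ndarray, min_bins: int = 8) -> int:
    """Freedman-Diaconis bin count with a floor of ``min_bins``."""
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    if iqr <= 0:
        return min_bins
    h = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    span = float(x.max() - x.min())
    if h <= 0 or span <= 0:
        return min_bins
    return max(int(np.ceil(span / h)), min_bins)


def fv_median(E_values: np.ndarray, min_values: int = MIN_VALUES_FOR_MEDIAN) -> FvMedianResult:
    """Median modulus of one force volume under the log-normal hypothesis.

    A Gaussian is least-squares fitted to the histogram of log10(E)
    (Freedman-Diaconis binning, at least 8 bins), initialized at the sample
    mean and SD; the median is 10**centre. Falls back to the sample median
    (logged) when the fit fails, its centre leaves the data range, or the fit
    R^2 is below the multimodality threshold — in the last case the result is
    flagged multimodal.

    The computation is performed on mean-centred log-values, which makes the
    estimate scale-equivariant: fv_median(a*E) = a*fv_median(E).

    Raises
    ------
    InsufficientDataError
        With fewer than ``min_values`` finite positive values.
    """
    E_values = np.asarray(E_values, dtype=float)
    vals = E_values[np.isfinite(E_values) & (E_values > 0)]
    n = len(vals)
    if n < min_values:
        raise InsufficientDataError(
            f"need >= {min_values} values for a per-FV median, got {n}"
        )
    logv = np.log10(vals)
    centre_shift = float(logv.mean())
    x = logv - centre_shift  # mean-centred => scale shifts drop out exactly
    sd = float(x.std())
    sample_median = float(np.median(vals))
    if sd == 0.0:  # degenerate: all values identical
        return FvMedianResult(
            value=sample_median,
            method="sample_median",
            multimodal=False,
            fit_r_squared=1.0,
            n_values=n,
        )

    nbins = _fd_bins(x)
    counts, edges = np.histogram(x, bins=nbins)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def gauss(t, amp, mu, sigma):
        return amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2)

    p0 = (float(counts.max()), 0.0, sd)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(gauss, centres, counts, p0=p0, maxfev=2000)
    except (RuntimeError, optimize.OptimizeWarning):
        logger.debug("per-FV Gaussian fit failed to converge; sample-median fallback")
        return FvMedianResult(
            value=sample_median,
            method="sample_median",
            multimodal=False,
            fit_r_squared=0.0,
            n_values=n,
        )
    mu = float(popt[1])
    resid = counts - gauss(centres, *popt)
    ss_tot = float(((counts - counts.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    if r2 < MULTIMODAL_R2_THRESHOLD:
        # the headline number must not hide a poorly-described (possibly
        # multimodal) distribution
        return FvMedianResult(
            value=sample_median,
            method="sample_median",
            multimodal=True,
            fit_r_squared=r2,
            n_values=n,
        )
    if not (x.min() <= mu <= x.max()):
        logger.debug("Gaussian centre outside data range; sample-median fallback")
        return FvMedianResult(
            value=sample_median,
            method="sample_median",
            multimodal=False,
            fit_r_squared=r2,
            n_values=n,
        )
    return FvMedianResult(
        value=float(10.0 ** (mu + centre_shift)),
        method="gaussian_fit",
        multimodal=False,
        fit_r_squared=r2,
        n_values=n,
    )


# ---------------------------------------------------------------------------
# Monte Carlo propagation of calibration uncertainty
# ---------------------------------------------------------------------------

def mc_calibration_error(
    maps: list[YoungModulusMap],
    calib: ProbeCalibration,
    n_mc: int = 500,
    seed: int = 0,
    curves_per_fv: int = 9,
    cfg: FitConfig | None = None,
) -> float:
    """Relative error of the condition-level modulus from calibration uncertainty.

    For each of ``n_mc`` replicates, perturbed calibration factors
    k' ~ N(k, rel_unc_k * k) and s' ~ N(s, rel_unc_s * s) are drawn
    (non-positive draws are redrawn; a redraw rate above 1% triggers a
    warning), rescaling and Hertz fitting are re-run on a stratified
    subsample of curves (an even spread of ``curves_per_fv`` fitted cells per
    force volume, reusing the already-identified contact points), and the
    replicate statistic is the mean over FVs of the per-FV median of the
    re-fitted moduli. The returned value is SD/mean of the replicate
    statistics. Seeded and reproducible.

    With both uncertainties zero the result is exactly 0. With only the
    spring-constant uncertainty active the fitted modulus is exactly
    proportional to k', so the result approaches rel_unc_k.
    """
    if n_mc < 100:
        raise ParameterError("n_mc must be >= 100")
    if calib.rel_unc_k == 0 and calib.rel_unc_s == 0:
        return 0.0
    cfg = cfg or FitConfig()

    # stratified subsample: evenly spaced fitted cells of every map
    sample: list[list[tuple]] = []
    for m in maps:
        cells = sorted(m.fits.keys() & m.contact_points.keys())
        cells = [rc for rc in cells if np.isfinite(m.E[rc])]
        if not cells:
            continue
        take = np.linspace(0, len(cells) - 1, min(curves_per_fv, len(cells)))
        chosen = [cells[int(i)] for i in take]
        fv = m.force_volume
        if fv is None:
            raise ParameterError(
                "mc_calibration_error needs maps that retain their force volume"
            )
        sample.append([(fv.curves[rc], m.contact_points[rc]) for rc in chosen])
    if not sample:
        raise ParameterError("no fitted curves available for Monte Carlo propagation")

    rng = np.random.default_rng(seed)
    values = np.empty(n_mc)
    redraws = 0
    for rep in range(n_mc):
        while True:
            kf = rng.normal(1.0, calib.rel_unc_k) if calib.rel_unc_k else 1.0
            sf = rng.normal(1.0, calib.rel_unc_s) if calib.rel_unc_s else 1.0
            if kf > 0 and sf > 0:
                break
            redraws += 1
        calib_rep = calib.scaled(k_factor=kf, s_factor=sf)
        fv_meds = []
        for fv_sample in sample:
            es = []
            for raw, cp in fv_sample:
                fic = rescale(raw, calib_rep, cp)
                es.append(fit_curve(fic, calib_rep, cfg).E)
            fv_meds.append(np.median(es))
        values[rep] = float(np.mean(fv_meds))
    if redraws > 0.01 * n_mc:
        warnings.warn(
            f"Monte Carlo calibration propagation redrew {redraws} non-positive "
            f"factor samples out of {n_mc} replicates",
            stacklevel=2,
        )
    return float(values.std(ddof=1) / values.mean())


# ---------------------------------------------------------------------------
# condition summaries and patient comparisons
# ---------------------------------------------------------------------------

@dataclass
class ConditionSummary:
    """Per-condition summary of one patient: pooled moduli and FV medians."""

    patient: str
    condition: str
    pooled_E: np.ndarray  # Pa, all fitted curves of all FVs
    fv_medians: list[float]  # Pa, one per force volume
    mean_median: float  # Pa
    sem: float | None  # Pa; None with a single FV
    mc_rel_error: float
    combined_error: float  # Pa, quadrature of SEM and MC term
    fv_median_results: list[FvMedianResult] = field(default_factory=list)

    @property
    def n_fv(self) -> int:
        return len(self.fv_medians)

    def violin_summary(self) -> dict[str, float]:
        """Median and quartiles of the pooled distribution (linear-interpolation
        quantiles), the numbers a violin plot annotates."""
        q1, med, q3 = np.quantile(self.pooled_E, [0.25, 0.5, 0.75])
        return {"q1": float(q1), "median": float(med), "q3": float(q3)}


def condition_summary(
    maps: list[YoungModulusMap],
    calib: ProbeCalibration | None = None,
    *,
    mc_rel_error: float | None = None,
    n_mc: int = 0,
    seed: int = 0,
    cfg: FitConfig | None = None,
) -> ConditionSummary:
    """Summarize one condition of one patient from its fitted maps.

    ``mean_median`` is the arithmetic mean of the per-FV medians and ``sem``
    their standard deviation over sqrt(n_FV). The Monte Carlo relative
    calibration error is either supplied (``mc_rel_error``) or computed here
    when ``n_mc`` > 0 and a calibration is available; it is combined with the
    SEM in quadrature::

        combined_error^2 = sem^2 + (mc_rel_error * mean_median)^2

    With a single force volume the SEM is undefined: it is reported as None
    (with a warning) and the combined error carries the MC term alone.
    """
    if not maps:
        raise ParameterError("condition_summary needs at least one map")
    patients = {m.patient for m in maps}
    conditions = {m.condition for m in maps}
    if len(patients) != 1 or len(conditions) != 1:
        raise ParameterError(
            f"maps span multiple patients/conditions: {patients}, {conditions}"
        )
    pooled = np.concatenate([m.values() for m in maps])
    med_results = [fv_median(m.values()) for m in maps]
    fv_medians = [r.value for r in med_results]
    mean_median = float(np.mean(fv_medians))
    if len(fv_medians) >= 2:
        sem: float | None = float(np.std(fv_medians, ddof=1) / np.sqrt(len(fv_medians)))
    else:
        warnings.warn(
            f"patient {maps[0].patient} condition {maps[0].condition}: single "
            "force volume, SEM undefined",
            stacklevel=2,
        )
        sem = None
    if mc_rel_error is None:
        if n_mc > 0:
            if calib is None:
                raise ParameterError("Monte Carlo propagation needs a calibration")
            mc_rel_error = mc_calibration_error(maps, calib, n_mc=n_mc, seed=seed, cfg=cfg)
        else:
            mc_rel_error = 0.0
    combined = float(np.hypot(sem or 0.0, mc_rel_error * mean_median))
    return ConditionSummary(
        patient=maps[0].patient,
        condition=maps[0].condition,
        pooled_E=pooled,
        fv_medians=fv_medians,
        mean_median=mean_median,
        sem=sem,
        mc_rel_error=float(mc_rel_error),
        combined_error=combined,
        fv_median_results=med_results,
    )


@dataclass
class PatientComparison:
    """Normal-vs-neoplastic comparison of one patient."""

    patient_id: str
    E_normal: float  # Pa
    E_normal_err: float  # Pa
    E_neoplastic: float  # Pa
    E_neoplastic_err: float  # Pa
    relative_stiffening: float  # (E_neo - E_norm) / E_norm
    p_value: float | None
    significant: bool | None  # p < 0.05; None when no test was possible


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-tailed Welch t-test with explicit zero-variance conventions."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0  # identical degenerate groups: no evidence either way
        return float(np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def compare_conditions(
    normal: ConditionSummary, neoplastic: ConditionSummary
) -> PatientComparison:
    """Relative stiffening and significance for one patient.

    The Welch two-tailed t-test runs on the two sets of per-FV medians; with
    fewer than two medians on either side the comparison is reported without
    a p-value. Significance threshold p < 0.05.
    """
    if normal.patient != neoplastic.patient:
        raise ParameterError(
            f"comparing different patients: {normal.patient} vs {neoplastic.patient}"
        )
    stiffening = (neoplastic.mean_median - normal.mean_median) / normal.mean_median
    if normal.n_fv >= 2 and neoplastic.n_fv >= 2:
        _t, p = _welch(np.array(normal.fv_medians), np.array(neoplastic.fv_medians))
        significant: bool | None = p < SIGNIFICANCE_LEVEL
    else:
        warnings.warn(
            f"patient {normal.patient}: fewer than 2 FV medians on one side, "
            "comparison reported without p-value",
            stacklevel=2,
        )
        p, significant = None, None
    return PatientComparison(
        patient_id=normal.patient,
        E_normal=normal.mean_median,
        E_normal_err=normal.combined_error,
        E_neoplastic=neoplastic.mean_median,
        E_neoplastic_err=neoplastic.combined_error,
        relative_stiffening=float(stiffening),
        p_value=p,
        significant=significant,
    )


# ---------------------------------------------------------------------------
# cohort-level associations with clinical covariates
# ---------------------------------------------------------------------------

def _holm(pvals: list[float | None]) -> list[float | None]:
    """Holm step-down adjustment, passing None entries through."""
    idx = [i for i, p in enumerate(pvals) if p is not None]
    ps = np.array([pvals[i] for i in idx], dtype=float)
    m = len(ps)
    adj = [None] * len(pvals)
    if m == 0:
        return adj
    order = np.argsort(ps)
    running = 0.0
    adjusted = np.empty(m)
    for rank, j in enumerate(order):
        running = max(running, (m - rank) * ps[j])
        adjusted[j] = min(running, 1.0)
    for i, a in zip(idx, adjusted):
        adj[i] = float(a)
    return adj


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float | None, float | None]:
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return None, None  # correlation undefined on a degenerate covariate
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def metadata_associations(
    comparisons: list[PatientComparison],
    metadata: pd.DataFrame,
    exclude: tuple[str, ...] | list[str] = (),
) -> pd.DataFrame:
    """Associate per-patient mechanics with clinical covariates.

    Continuous covariate (age): Pearson correlation (r, two-sided p) with the
    normal-tissue modulus and with the relative stiffening. Binary contrasts
    (chemotherapy, sex, KRAS/BRAF mutation, grade G2 vs G3): two-tailed Welch
    t-tests on the relative stiffening. Histology is reported descriptively
    (per-group mean stiffening). Patients in ``exclude`` (e.g. a
    non-adenocarcinoma histology outlier) are omitted from every contrast.
    A mutation status of 'ND' (not determined) drops the patient from the
    mutation contrast only.

    Returns a table with columns (contrast, kind, statistic, p_value, p_holm,
    n, note); groups with fewer than two patients skip their contrast with a
    warning and an explanatory note.
    """
    rows = []
    comp_by_id = {c.patient_id: c for c in comparisons if c.patient_id not in set(exclude)}
    meta = metadata[metadata["patient_id"].isin(comp_by_id)].copy()
    if meta.empty:
        raise ParameterError("no overlapping patients between comparisons and metadata")
    meta["age_years"] = pd.to_numeric(meta["age_years"])
    stiff = np.array([comp_by_id[p].relative_stiffening for p in meta["patient_id"]])
    e_norm = np.array([comp_by_id[p].E_normal for p in meta["patient_id"]])
    age = meta["age_years"].to_numpy(dtype=float)

    for label, yvals in (("E_normal_vs_age", e_norm), ("stiffening_vs_age", stiff)):
        r, p = _pearson(age, yvals)
        rows.append(
            {
                "contrast": label,
                "kind": "pearson",
                "statistic": r,
                "p_value": p,
                "n": len(age),
                "note": "" if r is not None else "undefined (degenerate covariate)",
            }
        )

    def group_contrast(label: str, groups: pd.Series, mask: np.ndarray | None = None):
        sel = np.ones(len(meta), dtype=bool) if mask is None else mask
        gvals = groups[sel]
        svals = stiff[sel]
        levels = sorted(gvals.unique())
        if len(levels) != 2:
            warnings.warn(f"contrast {label}: need exactly 2 groups, got {levels}", stacklevel=3)
            rows.append(
                {
                    "contrast": label,
                    "kind": "welch_t",
                    "statistic": None,
                    "p_value": None,
                    "n": int(sel.sum()),
                    "note": f"skipped: groups {levels}",
                }
            )
            return
        a = svals[(gvals == levels[0]).to_numpy()]
        b = svals[(gvals == levels[1]).to_numpy()]
        if len(a) < 2 or len(b) < 2:
            warnings.warn(f"contrast {label}: a group has fewer than 2 patients", stacklevel=3)
            rows.append(
                {
                    "contrast": label,
                    "kind": "welch_t",
                    "statistic": None,
                    "p_value": None,
                    "n": len(a) + len(b),
                    "note": f"skipped: group sizes {len(a)}/{len(b)}",
                }
            )
            return
        t, p = _welch(a, b)
        rows.append(
            {
                "contrast": label,
                "kind": "welch_t",
                "statistic": t,
                "p_value": p,
                "n": len(a) + len(b),
                "note": f"{levels[0]} (n={len(a)}) vs {levels[1]} (n={len(b)})",
            }
        )

    group_contrast("stiffening_vs_chemotherapy", meta["chemotherapy"])
    group_contrast("stiffening_vs_sex", meta["sex"])
    status = meta["kras_braf_status"].str.upper()
    determined = (~status.isin(["ND", ""])).to_numpy()
    mutated = pd.Series(
        np.where(status == "NONE", "wild-type", "mutated"), index=meta.index
    )
    group_contrast("stiffening_vs_kras_braf", mutated, mask=determined)
    grade_mask = meta["grade"].isin(["G2", "G3"]).to_numpy()
    group_contrast("stiffening_vs_grade", meta["grade"], mask=grade_mask)

    # histology: descriptive only
    for histology, grp in meta.groupby("diagnosis"):
        g_stiff = stiff[meta["diagnosis"].eq(histology).to_numpy()]
        rows.append(
            {
                "contrast": f"histology[{histology}]",
                "kind": "descriptive",
                "statistic": float(np.mean(g_stiff)),
                "p_value": None,
                "n": len(grp),
                "note": "mean relative stiffening",
            }
        )

    table = pd.DataFrame(
        rows, columns=["contrast", "kind", "statistic", "p_value", "n", "note"]
    )
    table["p_holm"] = _holm(list(table["p_value"]))
    return table[["contrast", "kind", "statistic", "p_value", "p_holm", "n", "note"]]
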