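"""Synthetic force-curve, force-volume and cohort generation with known ground truth.

The generator emulates the statistical structure of colloidal-probe AFM
measurements on decellularized ECM tissue sections:

* per-cell ground-truth moduli drawn from a (possibly multimodal) log-normal
  mixture, optionally with spatial correlation so stiff and soft patches form;
* the spherical-contact forward model with the finite cantilever stiffness:
  at piezo position z past the contact point, the deflection d solves the
  implicit force balance

      k * d = (4/3) * E / (1 - nu^2) * sqrt(R) * delta^(3/2),
      delta = (z - contact_z) - d,

  solved per point by a guarded Newton iteration on the (monotone, convex)
  residual, to |residual| < 1e-6 nN;
* i.i.d. Gaussian noise on the photodiode voltage channel (the instrument-
  referred channel, so force and indentation are perturbed through the same
  physical path); flat baseline by default, with an optional linear tilt to
  stress-test baseline correction;
* a max-load trigger truncating the ramp when k*d exceeds the set point,
  mirroring the instrument behaviour that yields several-µm indentations;
* paired normal/neoplastic patient cohorts with configurable per-patient
  relative stiffening and clinical covariates.

Only the approach segment is generated: the analysis operates on approach
curves and tip-sample adhesion is treated as negligible, so retraction adds
nothing. Everything is reproducible: one integer seed per object, children
derived through ``numpy.random.SeedSequence`` in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import GenerationError, ParameterError
from .forcecurve_io import (
    CohortDataset,
    ForceVolume,
    ProbeCalibration,
    RawForceCurve,
    write_dataset,
)
from .hertz import modulus_to_prefactor

#: Default within-FV log-normal width (decades). A single region of interest
#: shows a roughly half-decade unimodal spread of moduli; broader, multimodal
#: distributions arise across regions and are modelled with explicit modes.
DEFAULT_SIGMA_LOG10 = 0.15

#: Default probe: 5 N/m lever, 10 µm bead radius, 50 nm/V sensitivity.
DEFAULT_CALIBRATION = dict(spring_constant=5.0, tip_radius=1.0e4, sensitivity=50.0)

NEWTON_TOL_NN = 1e-6  # nN, residual tolerance of the implicit contact balance
_NEWTON_MAX_ITER = 200


@dataclass
class RampConfig:
    """Approach-ramp geometry and noise level.

    Defaults follow the instrument protocol the package targets: 15 µm ramps
    of 8192 points with a 1000 nN load trigger. The 2 mV voltage noise is a
    package default (instrument noise is not specified by the protocol).
    """

    ramp_length: float = 15000.0  # nm
    n_points: int = 8192
    max_load: float = 1000.0  # nN
    noise_sd_volts: float = 0.002
    contact_fraction: float = 0.20  # fraction of the ramp before contact

    def __post_init__(self) -> None:
        if self.n_points < 16:
            raise ParameterError("RampConfig.n_points must be >= 16")
        if self.ramp_length <= 0:
            raise ParameterError("RampConfig.ramp_length must be positive")
        if not (0 < self.contact_fraction < 1):
            raise ParameterError("RampConfig.contact_fraction must be in (0, 1)")
        if self.max_load <= 0 or self.noise_sd_volts < 0:
            raise ParameterError("invalid RampConfig load/noise settings")

    def z_grid(self) -> np.ndarray:
        return np.linspace(0.0, self.ramp_length, self.n_points)


@dataclass
class GroundTruthField:
    """Specification of a ground-truth modulus field over a grid.

    ``modes`` is a list of (median_Pa, sigma_log10, weight) tuples describing
    a log-normal mixture; weights must sum to one. With
    ``spatial_correlation_length`` > 0 (in grid cells) the mode assignment is
    derived by thresholding a Gaussian-smoothed latent field, so cells of the
    same mode cluster into patches.
    """

    modes: list[tuple[float, float, float]]
    grid_shape: tuple[int, int]
    spatial_correlation_length: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.modes:
            raise ParameterError("GroundTruthField needs at least one mode")
        weights = np.array([w for _, _, w in self.modes], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-12:
            raise ParameterError(
                f"mode weights must sum to 1 (got {weights.sum()!r})"
            )
        if np.any(weights < 0):
            raise ParameterError("mode weights must be non-negative")
        for med, sig, _ in self.modes:
            if med <= 0:
                raise ParameterError("mode median moduli must be positive")
            if sig < 0:
                raise ParameterError("mode sigma_log10 must be >= 0")
        if self.spatial_correlation_length < 0:
            raise ParameterError("spatial_correlation_length must be >= 0")

    @classmethod
    def single_mode(
        cls,
        median_pa: float,
        sigma_log10: float = DEFAULT_SIGMA_LOG10,
        grid_shape: tuple[int, int] = (11, 11),
        seed: int = 0,
    ) -> "GroundTruthField":
        return cls(modes=[(median_pa, sigma_log10, 1.0)], grid_shape=grid_shape, seed=seed)


def generate_field(spec: GroundTruthField) -> np.ndarray:
    """Draw a (rows, cols) array of ground-truth moduli (Pa) from the mixture.

    Each cell's modulus is ``median * 10**(sigma_log10 * N(0,1))`` for its
    assigned mode. Identical spec (including seed) gives a bit-identical
    field.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.grid_shape
    weights = np.array([w for _, _, w in spec.modes], dtype=float)
    if spec.spatial_correlation_length > 0 and len(spec.modes) > 1:
        latent = rng.standard_normal((rows, cols))
        latent = gaussian_filter(latent, sigma=spec.spatial_correlation_length, mode="reflect")
        # threshold the latent field at its empirical weight quantiles so the
        # realized mode fractions match the requested weights
        qs = np.cumsum(weights)[:-1]
        thresholds = np.quantile(latent, qs)
        assignment = np.searchsorted(thresholds, latent, side="right")
    else:
        assignment = rng.choice(len(spec.modes), size=(rows, cols), p=weights)
    e_field = np.empty((rows, cols))
    normals = rng.standard_normal((rows, cols))
    for m, (median, sigma, _) in enumerate(spec.modes):
        mask = assignment == m
        # median * 10**(sigma*N): exact at sigma = 0 by construction
        e_field[mask] = median * 10.0 ** (sigma * normals[mask])
    return e_field


def _solve_deflection(s_rel: np.ndarray, prefactor: float, k: float) -> np.ndarray:
    """Solve k*d = c*delta^(3/2), delta = s_rel - d, for every tip-sample
    separation ``s_rel`` > 0 past contact.

    Works on the indentation u = s_rel - d: f(u) = c*u^(3/2) + k*u - k*s_rel
    is strictly increasing and convex on [0, s_rel] with f(0) <= 0 and
    f(s_rel) >= 0, so Newton started at the upper bracket converges
    monotonically. Iterates to |f| < NEWTON_TOL_NN.
    """
    if not np.isfinite(prefactor) or prefactor < 0 or k <= 0:
        raise GenerationError(
            f"non-physical forward-model parameters (c={prefactor!r}, k={k!r})"
        )
    u = s_rel.copy()
    f = prefactor * u**1.5 + k * u - k * s_rel  # = c*u^1.5 at start, >= 0
    for _ in range(_NEWTON_MAX_ITER):
        active = np.abs(f) > NEWTON_TOL_NN
        if not np.any(active):
            break
        ua = u[active]
        fa = f[active]
        step = fa / (1.5 * prefactor * np.sqrt(ua) + k)
        ua = np.clip(ua - step, 0.0, None)
        u[active] = ua
        f[active] = prefactor * ua**1.5 + k * ua - k * s_rel[active]
    else:  # pragma: no cover - convex Newton converges in a few iterations
        raise GenerationError(
            "deflection solve did not reach the residual tolerance; "
            "non-physical forward-model parameters"
        )
    return s_rel - u


def synthesize_curve(
    E_true: float,
    calib: ProbeCalibration,
    ramp: RampConfig,
    contact_z: float,
    seed: int = 0,
    baseline_volts: float = 0.0,
    baseline_tilt_volts_per_nm: float = 0.0,
    poisson_ratio: float = 0.5,
    meta: dict | None = None,
) -> RawForceCurve:
    """Synthesize one raw approach curve for a sample of modulus ``E_true`` (Pa).

    Before contact the voltage is baseline plus noise; past contact the
    cantilever deflection solves the implicit contact balance (see module
    docstring) and the voltage is ``baseline + d / sensitivity + noise``.
    ``E_true = numpy.inf`` gives the rigid (stiff-substrate) limit
    d = z - contact_z, used for sensitivity-calibration curves. The ramp is
    truncated at the max-load trigger (points with k*d > max_load dropped).

    Reproducible: the same arguments and seed give an identical curve.
    """
    if not (E_true > 0):
        raise ParameterError(f"E_true must be positive (got {E_true!r})")
    if not (0 < contact_z < ramp.ramp_length):
        raise ParameterError(
            f"contact_z {contact_z!r} outside ramp (0, {ramp.ramp_length})"
        )
    z = ramp.z_grid()
    s_rel = z - contact_z
    d = np.zeros_like(z)
    post = s_rel > 0
    if np.isinf(E_true):
        d[post] = s_rel[post]
    else:
        c = modulus_to_prefactor(E_true, calib.tip_radius, poisson_ratio)
        d[post] = _solve_deflection(s_rel[post], c, calib.spring_constant)

    # max-load trigger: the instrument stops the ramp once k*d exceeds the
    # set point; keep samples up to the trigger
    force = calib.spring_constant * d
    over = np.nonzero(force > ramp.max_load)[0]
    stop = int(over[0]) if len(over) else len(z)
    stop = max(stop, 16)
    z = z[:stop]
    d = d[:stop]

    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, ramp.noise_sd_volts, size=stop) if ramp.noise_sd_volts else 0.0
    voltage = (
        baseline_volts
        + baseline_tilt_volts_per_nm * z
        + d / calib.sensitivity
        + noise
    )
    return RawForceCurve(z=z, voltage=voltage, **(meta or {}))


def synthesize_stiff_substrate_curve(
    calib: ProbeCalibration,
    ramp: RampConfig,
    contact_z: float | None = None,
    seed: int = 0,
    apply_load_trigger: bool = False,
) -> RawForceCurve:
    """Rigid-contact calibration curve (glass slide): deflection = piezo travel.

    Sensitivity calibration needs a long contact segment to regress the
    voltage-vs-z slope over, so by default the max-load trigger is not
    applied (the rigid-contact force is an idealization anyway); pass
    ``apply_load_trigger=True`` to keep the sample-ramp behaviour.
    """
    if contact_z is None:
        contact_z = ramp.contact_fraction * ramp.ramp_length
    if not apply_load_trigger:
        ramp = replace(ramp, max_load=np.inf)
    return synthesize_curve(np.inf, calib, ramp, contact_z, seed=seed)


@dataclass
class PatientSpec:
    """Ground-truth description of one synthetic patient.

    ``relative_stiffening`` is (E_neoplastic - E_normal) / E_normal, so the
    neoplastic median is ``E_normal_median * (1 + relative_stiffening)``.
    Clinical covariates mirror the metadata table of a typical peritoneal-
    metastasis cohort.
    """

    patient_id: str
    E_normal_median: float = 10e3  # Pa
    relative_stiffening: float = 1.0
    n_rois_per_condition: int = 5
    age: int = 60
    sex: str = "F"
    diagnosis: str = "Adenocarcinoma"
    grade: str = "G2"
    location: str = "Colon"
    chemotherapy: bool = True
    kras_braf_status: str = "NONE"

    def __post_init__(self) -> None:
        if self.relative_stiffening <= -1:
            raise ParameterError("relative_stiffening must be > -1")
        if self.n_rois_per_condition < 1:
            raise ParameterError("n_rois_per_condition must be >= 1")
        if self.E_normal_median <= 0:
            raise ParameterError("E_normal_median must be positive")

    def median_for(self, condition: str) -> float:
        if condition == "normal":
            return self.E_normal_median
        if condition == "neoplastic":
            return self.E_normal_median * (1.0 + self.relative_stiffening)
        raise ParameterError(f"unknown condition {condition!r}")


CONDITIONS = ("normal", "neoplastic")


@dataclass
class CohortSpec:
    """A paired normal/neoplastic cohort with fully known ground truth."""

    patients: list[PatientSpec]
    grid_shape: tuple[int, int] = (11, 11)  # 121 curves per force volume
    sigma_log10: float = DEFAULT_SIGMA_LOG10
    spatial_correlation_length: float = 0.0
    ramp: RampConfig = field(default_factory=RampConfig)
    calibration: ProbeCalibration = field(
        default_factory=lambda: ProbeCalibration(**DEFAULT_CALIBRATION)
    )
    roi_size_um: tuple[float, float] = (50.0, 50.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.patients:
            raise ParameterError("CohortSpec needs at least one patient")
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            raise ParameterError("patient ids must be unique")


def _metadata_table(patients: list[PatientSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "age_years": p.age,
                "sex": p.sex,
                "diagnosis": p.diagnosis,
                "grade": p.grade,
                "location": p.location,
                "chemotherapy": "yes" if p.chemotherapy else "no",
                "kras_braf_status": p.kras_braf_status,
            }
            for p in patients
        ],
        columns=[
            "patient_id",
            "age_years",
            "sex",
            "diagnosis",
            "grade",
            "location",
            "chemotherapy",
            "kras_braf_status",
        ],
    )


def synthesize_cohort(spec: CohortSpec, path: str | Path | None = None) -> CohortDataset:
    """Generate the full cohort; optionally write it to disk.

    For every patient, condition and ROI a force volume is generated: the
    per-cell ground-truth moduli come from :func:`generate_field`, the contact
    point of each cell is jittered around ``ramp.contact_fraction`` of the
    ramp (±5% of the ramp length), and each curve is synthesized with its own
    child seed. The returned dataset carries a ground-truth table with columns
    (patient, condition, roi, row, col, E_true_Pa, contact_z_nm).

    Deterministic: identical spec (including seed) gives an identical dataset
    (and byte-identical files when written).
    """
    root_ss = np.random.SeedSequence(spec.seed)
    volumes: list[ForceVolume] = []
    gt_rows: list[dict] = []
    rows, cols = spec.grid_shape
    for p_idx, patient in enumerate(sorted(spec.patients, key=lambda p: p.patient_id)):
        for c_idx, condition in enumerate(CONDITIONS):
            median = patient.median_for(condition)
            for roi_idx in range(patient.n_rois_per_condition):
                roi = f"roi{roi_idx}"
                fv_ss = np.random.SeedSequence(
                    entropy=spec.seed,
                    spawn_key=(p_idx, c_idx, roi_idx),
                )
                seeds = fv_ss.generate_state(2 + rows * cols)
                field_spec = GroundTruthField(
                    modes=[(median, spec.sigma_log10, 1.0)],
                    grid_shape=spec.grid_shape,
                    spatial_correlation_length=spec.spatial_correlation_length,
                    seed=int(seeds[0]),
                )
                e_field = generate_field(field_spec)
                jitter_rng = np.random.default_rng(int(seeds[1]))
                contact_base = spec.ramp.contact_fraction * spec.ramp.ramp_length
                jitter = jitter_rng.uniform(
                    -0.05 * spec.ramp.ramp_length,
                    0.05 * spec.ramp.ramp_length,
                    size=(rows, cols),
                )
                fv = ForceVolume(
                    patient=patient.patient_id,
                    condition=condition,
                    roi=roi,
                    grid_shape=spec.grid_shape,
                    roi_size_um=spec.roi_size_um,
                    calibration=spec.calibration,
                )
                for r in range(rows):
                    for c in range(cols):
                        contact_z = contact_base + jitter[r, c]
                        curve = synthesize_curve(
                            float(e_field[r, c]),
                            spec.calibration,
                            spec.ramp,
                            contact_z,
                            seed=int(seeds[2 + r * cols + c]),
                            meta=dict(
                                patient=patient.patient_id,
                                condition=condition,
                                roi=roi,
                                row=r,
                                col=c,
                            ),
                        )
                        fv.curves[(r, c)] = curve
                        gt_rows.append(
                            {
                                "patient": patient.patient_id,
                                "condition": condition,
                                "roi": roi,
                                "row": r,
                                "col": c,
                                "E_true_Pa": float(e_field[r, c]),
                                "contact_z_nm": contact_z,
                            }
                        )
                volumes.append(fv)
    cohort = CohortDataset(
        force_volumes=volumes,
        metadata=_metadata_table(spec.patients),
        ground_truth=pd.DataFrame(gt_rows),
    )
    if path is not None:
        write_dataset(cohort, path)
    return cohort
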