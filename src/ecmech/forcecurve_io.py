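"""Data model and serialization for AFM force-volume datasets.

Unit conventions used throughout the package
--------------------------------------------
piezo displacement z, indentation delta, deflection d, tip radius R : nm
photodiode signal                                                   : V
deflection sensitivity s                                            : nm/V
spring constant k                                                   : N/m (= nN/nm)
force F                                                             : nN
Young's modulus E                                                   : Pa

With these units the Hertz prefactor c = F / delta^(3/2) is in nN/nm^(3/2)
and nN/nm^2 = GPa, so modulus conversions carry a single 1e9 factor.

On-disk container
-----------------
AFM vendors ship proprietary binaries; this package defines an open layout
instead (see :func:`write_dataset`):

* ``manifest.json`` — versioned index of force volumes, sorted by
  (patient, condition, roi), each entry carrying its probe calibration.
* ``metadata.tsv`` — one row per patient with the clinical covariates
  (age, sex, diagnosis, grade, location, chemotherapy, KRAS/BRAF status).
* ``fv_<patient>_<condition>_<roi>.h5`` — one HDF5 file per force volume:
  float64 datasets ``z`` and ``voltage`` with shape (rows, cols, n_points),
  an int32 ``n_points`` dataset with the valid length per cell (curves
  truncated by the max-load trigger are NaN-padded; 0 marks a missing cell).
* optional ``ground_truth.tsv`` — synthetic-data sidecar with the generating
  modulus and contact point per cell.

Grid coordinates are row-major with (0, 0) the top-left cell; z increases
toward the sample on approach.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import h5py
import numpy as np
import pandas as pd

from .errors import CurveValidationError, FormatError, ParameterError

FORMAT_VERSION = "1.0"

MANIFEST_NAME = "manifest.json"
METADATA_NAME = "metadata.tsv"
GROUND_TRUTH_NAME = "ground_truth.tsv"

#: Clinical covariate columns of the patient metadata table.
METADATA_COLUMNS = [
    "patient_id",
    "age_years",
    "sex",
    "diagnosis",
    "grade",
    "location",
    "chemotherapy",
    "kras_braf_status",
]

#: Curve-count range typical of the instrument protocol this package targets
#: (force volumes of 100–225 curves); outside it a warning is issued, not an error.
REALISTIC_CURVE_COUNT = (100, 225)

MIN_CURVE_POINTS = 16


@dataclass
class ProbeCalibration:
    """Colloidal-probe calibration factors with their relative uncertainties.

    Parameters
    ----------
    spring_constant : float
        Cantilever spring constant k in N/m (typically 5–6 N/m for the stiff
        levers needed to indent ECM by several µm).
    tip_radius : float
        Colloidal-sphere radius R in nm (9 000–12 500 nm for 18–25 µm beads).
    sensitivity : float
        Deflection sensitivity s in nm/V of the optical-beam-deflection readout.
    rel_unc_k, rel_unc_s : float
        Relative (1-sigma) uncertainties of k and s used by the Monte Carlo
        error propagation. Defaults 10% and 5%.
    """

    spring_constant: float
    tip_radius: float
    sensitivity: float
    rel_unc_k: float = 0.10
    rel_unc_s: float = 0.05

    def __post_init__(self) -> None:
        for name in ("spring_constant", "tip_radius", "sensitivity"):
            if not np.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ParameterError(f"ProbeCalibration.{name} must be positive")
        for name in ("rel_unc_k", "rel_unc_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"ProbeCalibration.{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "spring_constant_N_per_m": self.spring_constant,
            "tip_radius_nm": self.tip_radius,
            "sensitivity_nm_per_V": self.sensitivity,
            "rel_unc_k": self.rel_unc_k,
            "rel_unc_s": self.rel_unc_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProbeCalibration":
        try:
            return cls(
                spring_constant=float(d["spring_constant_N_per_m"]),
                tip_radius=float(d["tip_radius_nm"]),
                sensitivity=float(d["sensitivity_nm_per_V"]),
                rel_unc_k=float(d.get("rel_unc_k", 0.10)),
                rel_unc_s=float(d.get("rel_unc_s", 0.05)),
            )
        except KeyError as exc:  # pragma: no cover - exercised via read_dataset
            raise FormatError(f"calibration entry missing field {exc}") from exc

    def scaled(self, k_factor: float = 1.0, s_factor: float = 1.0) -> "ProbeCalibration":
        """Return a copy with k and/or s multiplied by the given factors."""
        return replace(
            self,
            spring_constant=self.spring_constant * k_factor,
            sensitivity=self.sensitivity * s_factor,
        )


@dataclass
class RawForceCurve:
    """One approach ramp: piezo displacement (nm) vs photodiode voltage (V)."""

    z: np.ndarray
    voltage: np.ndarray
    patient: str | None = None
    condition: str | None = None
    roi: str | None = None
    row: int | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)

    @property
    def curve_id(self) -> str:
        return (
            f"{self.patient or '?'}/{self.condition or '?'}/{self.roi or '?'}"
            f"[{self.row},{self.col}]"
        )

    def __len__(self) -> int:
        return len(self.z)

    def validate(self) -> None:
        """Enforce the raw-curve invariants; raise :class:`CurveValidationError`.

        The reader never repairs a violating curve — errors name the curve so
        the offending file can be inspected.
        """
        if self.z.ndim != 1 or self.voltage.ndim != 1:
            raise CurveValidationError(f"curve {self.curve_id}: arrays must be 1-D")
        if len(self.z) != len(self.voltage):
            raise CurveValidationError(
                f"curve {self.curve_id}: z and voltage lengths differ "
                f"({len(self.z)} vs {len(self.voltage)})"
            )
        if len(self.z) < MIN_CURVE_POINTS:
            raise CurveValidationError(
                f"curve {self.curve_id}: fewer than {MIN_CURVE_POINTS} points"
            )
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.voltage))):
            raise CurveValidationError(f"curve {self.curve_id}: non-finite values")
        if not np.all(np.diff(self.z) > 0):
            raise CurveValidationError(
                f"curve {self.curve_id}: z must be strictly increasing on approach"
            )


@dataclass
class ForceIndentationCurve:
    """Rescaled force (nN) vs indentation (nm), positive-indentation part only."""

    indentation: np.ndarray
    force: np.ndarray
    contact_index: int
    contact_z: float
    baseline_offset: float = 0.0  # V
    baseline_slope: float = 0.0  # V/nm
    curve_id: str = ""

    def __post_init__(self) -> None:
        self.indentation = np.asarray(self.indentation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.indentation) != len(self.force):
            raise ParameterError("indentation and force must have equal length")
        if len(self.indentation) and self.indentation.min() < 0:
            raise ParameterError("indentation must be non-negative")

    @property
    def max_indentation(self) -> float:
        return float(self.indentation.max()) if len(self.indentation) else 0.0


@dataclass
class ForceVolume:
    """Grid of raw force curves acquired over one region of interest."""

    patient: str
    condition: str
    roi: str
    grid_shape: tuple[int, int]
    curves: dict[tuple[int, int], RawForceCurve] = field(default_factory=dict)
    roi_size_um: tuple[float, float] = (50.0, 50.0)
    calibration: ProbeCalibration | None = None

    @property
    def key(self) -> tuple[str, str, str]:
        return (self.patient, self.condition, self.roi)

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def n_cells(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def missing_cells(self) -> list[tuple[int, int]]:
        return [
            (r, c)
            for r in range(self.grid_shape[0])
            for c in range(self.grid_shape[1])
            if (r, c) not in self.curves
        ]

    def iter_cells(self) -> Iterator[tuple[tuple[int, int], RawForceCurve]]:
        """Yield (cell, curve) in row-major order, skipping missing cells."""
        for r in range(self.grid_shape[0]):
            for c in range(self.grid_shape[1]):
                if (r, c) in self.curves:
                    yield (r, c), self.curves[(r, c)]

    def validate(self) -> None:
        rows, cols = self.grid_shape
        if rows <= 0 or cols <= 0:
            raise ParameterError(f"force volume {self.key}: empty grid shape")
        for (r, c), curve in self.curves.items():
            if not (0 <= r < rows and 0 <= c < cols):
                raise ParameterError(
                    f"force volume {self.key}: cell ({r},{c}) outside grid {self.grid_shape}"
                )
            curve.validate()
        lo, hi = REALISTIC_CURVE_COUNT
        if self.n_curves and not (lo <= self.n_curves <= hi):
            warnings.warn(
                f"force volume {self.key}: {self.n_curves} curves is outside the "
                f"typical instrument range {lo}-{hi}",
                stacklevel=2,
            )


@dataclass
class CohortDataset:
    """A cohort of force volumes plus the patient metadata table."""

    force_volumes: list[ForceVolume]
    metadata: pd.DataFrame
    ground_truth: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.force_volumes = sorted(self.force_volumes, key=lambda fv: fv.key)

    def volumes_for(self, patient: str, condition: str | None = None) -> list[ForceVolume]:
        return [
            fv
            for fv in self.force_volumes
            if fv.patient == patient and (condition is None or fv.condition == condition)
        ]

    @property
    def patients(self) -> list[str]:
        return sorted({fv.patient for fv in self.force_volumes})

    @property
    def conditions(self) -> list[str]:
        return sorted({fv.condition for fv in self.force_volumes})

    def validate(self) -> None:
        for fv in self.force_volumes:
            fv.validate()
        missing = set(METADATA_COLUMNS) - set(self.metadata.columns)
        if missing:
            raise FormatError(f"metadata table missing columns: {sorted(missing)}")


def _fv_filename(fv: ForceVolume) -> str:
    def safe(s: str) -> str:
        return "".join(ch if (ch.isalnum() or ch in "-_") else "-" for ch in s)

    return f"fv_{safe(fv.patient)}_{safe(fv.condition)}_{safe(fv.roi)}.h5"


def write_dataset(cohort: CohortDataset, path: str | Path) -> Path:
    """Write a cohort to *path* in the documented container layout.

    Writing is deterministic: manifest entries are sorted by
    (patient, condition, roi) and JSON keys are sorted, so writing the same
    cohort twice yields byte-identical manifests. Curve arrays are stored at
    full float64 precision.
    """
    cohort.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    entries = []
    for fv in cohort.force_volumes:
        fname = _fv_filename(fv)
        rows, cols = fv.grid_shape
        max_pts = max((len(c) for c in fv.curves.values()), default=0)
        z = np.full((rows, cols, max_pts), np.nan)
        v = np.full((rows, cols, max_pts), np.nan)
        npts = np.zeros((rows, cols), dtype=np.int32)
        for (r, c), curve in fv.curves.items():
            n = len(curve)
            z[r, c, :n] = curve.z
            v[r, c, :n] = curve.voltage
            npts[r, c] = n
        try:
            with h5py.File(path / fname, "w") as h5:
                h5.create_dataset("z", data=z, dtype="f8")
                h5.create_dataset("voltage", data=v, dtype="f8")
                h5.create_dataset("n_points", data=npts)
        except OSError as exc:
            raise FormatError(f"failed writing {path / fname}: {exc}") from exc
        entry = {
            "patient": fv.patient,
            "condition": fv.condition,
            "roi": fv.roi,
            "file": fname,
            "rows": rows,
            "cols": cols,
            "roi_size_um": list(fv.roi_size_um),
        }
        if fv.calibration is not None:
            entry["calibration"] = fv.calibration.to_dict()
        entries.append(entry)

    manifest = {
        "format_version": FORMAT_VERSION,
        "n_force_volumes": len(entries),
        "entries": entries,
    }
    (path / MANIFEST_NAME).write_text(
        json.dumps(manifest, indent=2, sort_keys=True, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    cohort.metadata.to_csv(path / METADATA_NAME, sep="\t", index=False, encoding="utf-8")
    if cohort.ground_truth is not None:
        cohort.ground_truth.to_csv(
            path / GROUND_TRUTH_NAME, sep="\t", index=False, encoding="utf-8"
        )
    return path


def read_dataset(path: str | Path) -> CohortDataset:
    """Read a cohort written by :func:`write_dataset`, validating all invariants.

    Raises
    ------
    FormatError
        On a missing or schema-violating manifest/metadata file (the message
        names the file and the field).
    CurveValidationError
        When a stored curve violates a raw-curve invariant (names the curve).
    """
    path = Path(path)
    manifest_path = path / MANIFEST_NAME
    if not manifest_path.exists():
        raise FormatError(f"{manifest_path}: manifest not found")
    try:
        manifest = json.loads(manifest_path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{manifest_path}: invalid JSON ({exc})") from exc

    for fld in ("format_version", "entries"):
        if fld not in manifest:
            raise FormatError(f"{manifest_path}: missing field '{fld}'")
    if str(manifest["format_version"]).split(".")[0] != FORMAT_VERSION.split(".")[0]:
        raise FormatError(
            f"{manifest_path}: unsupported format_version {manifest['format_version']!r}"
        )

    volumes: list[ForceVolume] = []
    for entry in manifest["entries"]:
        for fld in ("patient", "condition", "roi", "file", "rows", "cols"):
            if fld not in entry:
                raise FormatError(f"{manifest_path}: entry missing field '{fld}'")
        fv_path = path / entry["file"]
        if not fv_path.exists():
            raise FormatError(f"{fv_path}: force-volume file listed in manifest not found")
        calib = (
            ProbeCalibration.from_dict(entry["calibration"])
            if "calibration" in entry
            else None
        )
        fv = ForceVolume(
            patient=str(entry["patient"]),
            condition=str(entry["condition"]),
            roi=str(entry["roi"]),
            grid_shape=(int(entry["rows"]), int(entry["cols"])),
            roi_size_um=tuple(entry.get("roi_size_um", (50.0, 50.0))),
            calibration=calib,
        )
        with h5py.File(fv_path, "r") as h5:
            for name in ("z", "voltage", "n_points"):
                if name not in h5:
                    raise FormatError(f"{fv_path}: missing dataset '{name}'")
            z = h5["z"][...]
            v = h5["voltage"][...]
            npts = h5["n_points"][...]
        if z.shape != v.shape or z.shape[:2] != npts.shape:
            raise FormatError(f"{fv_path}: inconsistent dataset shapes")
        if z.shape[:2] != fv.grid_shape:
            raise FormatError(
                f"{fv_path}: grid shape {z.shape[:2]} disagrees with manifest "
                f"{fv.grid_shape}"
            )
        for r in range(fv.grid_shape[0]):
            for c in range(fv.grid_shape[1]):
                n = int(npts[r, c])
                if n == 0:  # explicitly missing cell
                    continue
                curve = RawForceCurve(
                    z=z[r, c, :n].copy(),
                    voltage=v[r, c, :n].copy(),
                    patient=fv.patient,
                    condition=fv.condition,
                    roi=fv.roi,
                    row=r,
                    col=c,
                )
                curve.validate()
                fv.curves[(r, c)] = curve
        volumes.append(fv)

    metadata_path = path / METADATA_NAME
    if not metadata_path.exists():
        raise FormatError(f"{metadata_path}: metadata table not found")
    metadata = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = set(METADATA_COLUMNS) - set(metadata.columns)
    if missing_cols:
        raise FormatError(f"{metadata_path}: missing columns {sorted(missing_cols)}")

    gt_path = path / GROUND_TRUTH_NAME
    ground_truth = (
        pd.read_csv(gt_path, sep="\t") if gt_path.exists() else None
    )
    return CohortDataset(force_volumes=volumes, metadata=metadata, ground_truth=ground_truth)


def import_vendor(path: str | Path):  # pragma: no cover - documented stub
    """Import stub for proprietary instrument files (not implemented).

    Vendor force-volume containers map onto this package's layout as follows:
    the per-pixel height ramp becomes ``z`` (nm, increasing toward the sample
    on approach), the raw vertical-deflection channel in volts becomes
    ``voltage``, and the calibration block (spring constant, deflection
    sensitivity, tip radius) becomes :class:`ProbeCalibration`. Reverse
    engineering of the binary formats themselves is out of scope; export to
    an open format from the vendor software and convert to this layout.
    """
    raise NotImplementedError(
        "vendor force-volume formats are not parsed; convert to the open "
        "container layout described in the ecmech.forcecurve_io docstring"
    )
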