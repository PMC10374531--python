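"""End-to-end pipeline: dataset -> maps -> statistics -> tables and figures.

All outputs are deterministic given the configuration (every random step is
seeded) and every table carries the configuration hash in a header comment,
so a result file can always be traced to the exact settings that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
import yaml

from . import __version__
from .cohort_stats import (
    PatientComparison,
    compare_conditions,
    condition_summary,
    metadata_associations,
)
from .errors import ECMechError, ParameterError
from .forcecurve_io import CohortDataset, read_dataset
from .hertz import FitConfig, YoungModulusMap, fit_volume
from .synthetic import CohortSpec, PatientSpec, RampConfig, synthesize_cohort

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated pipeline settings; defaults reproduce the standard protocol
    (nu = 0.5, 20-80% indentation window, 10%/5% calibration uncertainties)."""

    input: str = ""
    output: str = "results"
    poisson_ratio: float = 0.5
    fit_window: tuple[float, float] = (0.20, 0.80)
    qc_min_indentation_nm: float = 500.0
    qc_min_r_squared: float = 0.8
    n_mc: int = 200
    seed: int = 0
    exclude_patients: list[str] = field(default_factory=list)
    figures: bool = True

    def __post_init__(self) -> None:
        self.fit_window = tuple(self.fit_window)  # type: ignore[assignment]
        # delegate numeric validation to FitConfig
        self.fit_config()

    def fit_config(self) -> FitConfig:
        return FitConfig(poisson_ratio=self.poisson_ratio, fit_window=self.fit_window)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a config file, rejecting unknown keys."""
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ParameterError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fit_window"] = list(self.fit_window)
        return d

    @property
    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (paths excluded), so two
        runs of the same analysis on the same data are identifiable as such
        regardless of where their outputs live."""
        d = {k: v for k, v in self.to_dict().items() if k not in ("input", "output")}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class PipelineResult:
    """Everything the pipeline computed, plus where it was written."""

    config: PipelineConfig
    maps: dict[tuple[str, str, str], YoungModulusMap]
    summaries: dict[tuple[str, str], object]
    comparisons: list[PatientComparison]
    associations: pd.DataFrame | None
    summary_table: pd.DataFrame
    comparison_table: pd.DataFrame
    qc_table: pd.DataFrame
    output_dir: Path


def _write_tsv(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# ecmech {__version__} config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: PipelineConfig, cohort: CohortDataset | None = None) -> PipelineResult:
    """Run the full analysis on a dataset.

    Stages: read (unless an in-memory cohort is passed) -> per-FV Hertz maps
    -> per-condition summaries with Monte Carlo calibration error -> paired
    normal/neoplastic comparisons -> metadata associations (honouring the
    exclusion list) -> TSV tables, figures and a run manifest under
    ``config.output``.

    Per-curve and per-FV failures are logged and skipped; the pipeline raises
    only when nothing at all could be analysed.
    """
    if cohort is None:
        cohort = read_dataset(config.input)
    out = Path(config.output)
    out.mkdir(parents=True, exist_ok=True)
    (out / "maps").mkdir(exist_ok=True)
    cfg = config.fit_config()
    chash = config.config_hash

    maps: dict[tuple[str, str, str], YoungModulusMap] = {}
    qc_rows = []
    for fv in cohort.force_volumes:
        try:
            m = fit_volume(
                fv,
                cfg=cfg,
                qc_min_indentation_nm=config.qc_min_indentation_nm,
                qc_min_r_squared=config.qc_min_r_squared,
            )
        except ECMechError as exc:
            logger.warning("force volume %s skipped: %s", fv.key, exc)
            continue
        maps[fv.key] = m
        table = m.to_table()
        table.insert(0, "roi", fv.roi)
        table.insert(0, "condition", fv.condition)
        table.insert(0, "patient", fv.patient)
        _write_tsv(
            table,
            out / "maps" / f"map_{fv.patient}_{fv.condition}_{fv.roi}.tsv",
            chash,
        )
        for (r, c), (status, reason) in sorted(m.qc.items()):
            qc_rows.append(
                {
                    "curve_id": f"{fv.patient}/{fv.condition}/{fv.roi}[{r},{c}]",
                    "status": status,
                    "reason": reason,
                    "contact_z_nm": (
                        m.contact_points[(r, c)].contact_z
                        if (r, c) in m.contact_points
                        else np.nan
                    ),
                    "max_indentation_nm": (
                        m.fits[(r, c)].delta_max if (r, c) in m.fits else np.nan
                    ),
                }
            )
    if not maps:
        raise ECMechError("no force volume could be analysed")
    qc_table = pd.DataFrame(
        qc_rows,
        columns=["curve_id", "status", "reason", "contact_z_nm", "max_indentation_nm"],
    )
    _write_tsv(qc_table, out / "qc_report.tsv", chash)

    # per-condition summaries with seeded Monte Carlo calibration error
    summaries: dict[tuple[str, str], object] = {}
    summary_rows = []
    for patient in cohort.patients:
        for condition in cohort.conditions:
            cond_maps = [m for m in maps.values() if (m.patient, m.condition) == (patient, condition)]
            if not cond_maps:
                continue
            calib = cond_maps[0].force_volume.calibration if cond_maps[0].force_volume else None
            try:
                summ = condition_summary(
                    cond_maps,
                    calib,
                    n_mc=config.n_mc if calib is not None else 0,
                    seed=config.seed,
                    cfg=cfg,
                )
            except ECMechError as exc:
                logger.warning("summary %s/%s skipped: %s", patient, condition, exc)
                continue
            summaries[(patient, condition)] = summ
            vio = summ.violin_summary()
            summary_rows.append(
                {
                    "patient": patient,
                    "condition": condition,
                    "n_fv": summ.n_fv,
                    "n_curves": len(summ.pooled_E),
                    "mean_median_Pa": summ.mean_median,
                    "sem_Pa": summ.sem if summ.sem is not None else np.nan,
                    "mc_rel_error": summ.mc_rel_error,
                    "combined_error_Pa": summ.combined_error,
                    "pooled_median_Pa": vio["median"],
                    "pooled_q1_Pa": vio["q1"],
                    "pooled_q3_Pa": vio["q3"],
                    "multimodal_fvs": sum(r.multimodal for r in summ.fv_median_results),
                }
            )
    summary_table = pd.DataFrame(summary_rows)
    _write_tsv(summary_table, out / "per_patient_summary.tsv", chash)

    comparisons = []
    comp_rows = []
    for patient in cohort.patients:
        if (patient, "normal") in summaries and (patient, "neoplastic") in summaries:
            comp = compare_conditions(
                summaries[(patient, "normal")], summaries[(patient, "neoplastic")]
            )
            comparisons.append(comp)
            comp_rows.append(
                {
                    "patient": comp.patient_id,
                    "E_normal_Pa": comp.E_normal,
                    "E_normal_err_Pa": comp.E_normal_err,
                    "E_neoplastic_Pa": comp.E_neoplastic,
                    "E_neoplastic_err_Pa": comp.E_neoplastic_err,
                    "relative_stiffening": comp.relative_stiffening,
                    "relative_stiffening_pct": 100.0 * comp.relative_stiffening,
                    "p_value": comp.p_value if comp.p_value is not None else np.nan,
                    "significant": comp.significant,
                }
            )
    comparison_table = pd.DataFrame(comp_rows)
    _write_tsv(comparison_table, out / "comparisons.tsv", chash)

    associations = None
    if comparisons:
        included = [c for c in comparisons if c.patient_id not in config.exclude_patients]
        if len(included) >= 3:
            associations = metadata_associations(
                comparisons, cohort.metadata, exclude=tuple(config.exclude_patients)
            )
            _write_tsv(associations, out / "associations.tsv", chash)
        else:
            logger.info("too few patients for association analysis (%d)", len(included))

    if config.figures:
        _make_figures(cohort, maps, summaries, comparisons, associations, out, chash)

    manifest = {
        "software": f"ecmech {__version__}",
        "config": config.to_dict(),
        "config_hash": chash,
        "n_force_volumes": len(maps),
        "n_curves_fitted": int(sum(m.n_fitted for m in maps.values())),
        "qc_counts": qc_table["status"].value_counts().to_dict() if len(qc_table) else {},
        "n_patients": len(cohort.patients),
    }
    (out / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return PipelineResult(
        config=config,
        maps=maps,
        summaries=summaries,
        comparisons=comparisons,
        associations=associations,
        summary_table=summary_table,
        comparison_table=comparison_table,
        qc_table=qc_table,
        output_dir=out,
    )


def _make_figures(cohort, maps, summaries, comparisons, associations, out: Path, chash: str):
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    footer = f"ecmech {__version__} | config {chash}"

    # pooled-distribution violins per patient/condition
    rows = []
    for (patient, condition), summ in summaries.items():
        for e in summ.pooled_E:
            rows.append({"patient": patient, "condition": condition, "E_kPa": e / 1e3})
    if rows:
        df = pd.DataFrame(rows)
        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * df["patient"].nunique(), 4))
        sns.violinplot(
            data=df,
            x="patient",
            y="E_kPa",
            hue="condition",
            split=df["condition"].nunique() == 2,
            inner="quartile",
            cut=0,
            ax=ax,
        )
        ax.set_yscale("log")
        ax.set_ylabel("Young's modulus (kPa)")
        fig.text(0.99, 0.01, footer, ha="right", fontsize=6, color="grey")
        fig.savefig(figdir / "violins.png", dpi=150, bbox_inches="tight")
        plt.close(fig)

    # modulus heat map per ROI
    for key, m in maps.items():
        fig, ax = plt.subplots(figsize=(4, 3.2))
        im = ax.imshow(m.E / 1e3, origin="upper", cmap="viridis")
        fig.colorbar(im, ax=ax, label="E (kPa)")
        ax.set_title(f"{m.patient} {m.condition} {m.roi}", fontsize=9)
        fig.text(0.99, 0.01, footer, ha="right", fontsize=6, color="grey")
        fig.savefig(
            figdir / f"heatmap_{m.patient}_{m.condition}_{m.roi}.png",
            dpi=150,
            bbox_inches="tight",
        )
        plt.close(fig)

    # per-FV median dot plot with significance asterisks
    if comparisons:
        fig, ax = plt.subplots(figsize=(1.5 + 1.2 * len(comparisons), 4))
        offsets = {"normal": -0.15, "neoplastic": 0.15}
        colors = {"normal": "tab:green", "neoplastic": "tab:red"}
        patients = sorted({c.patient_id for c in comparisons})
        for i, patient in enumerate(patients):
            top = 0.0
            for condition in ("normal", "neoplastic"):
                summ = summaries.get((patient, condition))
                if summ is None:
                    continue
                x = i + offsets[condition]
                meds = np.array(summ.fv_medians) / 1e3
                ax.plot([x] * len(meds), meds, "o", color=colors[condition], alpha=0.6, ms=4)
                ax.errorbar(
                    [x],
                    [summ.mean_median / 1e3],
                    yerr=[summ.combined_error / 1e3],
                    fmt="_",
                    color="black",
                    capsize=4,
                )
                top = max(top, meds.max())
            comp = next(c for c in comparisons if c.patient_id == patient)
            if comp.significant:
                ax.text(i, top * 1.08, "*", ha="center", fontsize=14)
        ax.set_xticks(range(len(patients)))
        ax.set_xticklabels(patients)
        ax.set_ylabel("per-FV median E (kPa)")
        fig.text(0.99, 0.01, footer, ha="right", fontsize=6, color="grey")
        fig.savefig(figdir / "fv_medians.png", dpi=150, bbox_inches="tight")
        plt.close(fig)

    # association panels: stiffening vs age and vs the categorical covariates
    if associations is not None and comparisons:
        meta = cohort.metadata.set_index("patient_id")
        pts = [c.patient_id for c in comparisons if c.patient_id in meta.index]
        stiff = [
            next(c.relative_stiffening for c in comparisons if c.patient_id == p)
            for p in pts
        ]
        fig, axes = plt.subplots(1, 4, figsize=(14, 3.2))
        ages = pd.to_numeric(meta.loc[pts, "age_years"])
        axes[0].plot(ages, stiff, "ko")
        axes[0].set_xlabel("age (years)")
        axes[0].set_ylabel("relative stiffening")
        for ax, column in zip(axes[1:], ("chemotherapy", "sex", "grade")):
            groups = meta.loc[pts, column]
            for j, level in enumerate(sorted(groups.unique())):
                ys = [s for s, g in zip(stiff, groups) if g == level]
                ax.plot([j] * len(ys), ys, "ko", alpha=0.7)
            ax.set_xticks(range(groups.nunique()))
            ax.set_xticklabels(sorted(groups.unique()))
            ax.set_xlabel(column)
        fig.text(0.99, 0.01, footer, ha="right", fontsize=6, color="grey")
        fig.savefig(figdir / "associations.png", dpi=150, bbox_inches="tight")
        plt.close(fig)


def make_demo(path: str | Path, seed: int = 0) -> CohortSpec:
    """Write a desk-scale demo cohort (two patients, 25-curve force volumes).

    Patient DEMO-A is generated with a relative stiffening of 1.0 (the
    neoplastic ECM twice as stiff as the normal), patient DEMO-B with 0.0;
    an end-to-end run should call A significant and B not. Returns the spec
    used, so the ground truth is fully known.
    """
    spec = CohortSpec(
        patients=[
            PatientSpec(
                patient_id="DEMO-A",
                E_normal_median=10e3,
                relative_stiffening=1.0,
                n_rois_per_condition=3,
                age=70,
                sex="F",
                grade="G3",
                chemotherapy=True,
                kras_braf_status="KRAS G12D",
            ),
            PatientSpec(
                patient_id="DEMO-B",
                E_normal_median=8e3,
                relative_stiffening=0.0,
                n_rois_per_condition=3,
                age=50,
                sex="M",
                grade="G2",
                chemotherapy=False,
                kras_braf_status="NONE",
            ),
        ],
        grid_shape=(5, 5),
        seed=seed,
    )
    synthesize_cohort(spec, path)
    return spec
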