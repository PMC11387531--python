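"""End-to-end analysis pipeline: fit -> register -> PRM -> cohort statistics.

The pipeline consumes a cohort directory (see :func:`prmivim.io.write_cohort`)
or in-memory patient records and produces, per patient, fitted IVIM maps, the
SUV volume resampled into the IVIM frame and PRM label maps for the three
metric pairs (SUV x D, SUV x f, D x f), and, per cohort, the population-mean
thresholds, the demographics summary table, the ΔGTV association table,
paired pre/on-treatment tests and voxel-wise correlation summaries.

ΔGTV convention: 100 * (GTV_on - GTV_pre) / GTV_pre, so shrinkage is
negative.  PRM is computed within the pre-treatment GTV using thresholds
frozen from the pre-treatment cohort; on-treatment D x f PRM reuses the same
thresholds inside the on-treatment GTV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_stats import (
    association_table,
    delta_gtv,
    summary_table,
    voxelwise_correlation,
    wilcoxon_paired,
)
from .grids import ImageGrid
from .io import read_dwi, read_manifest, read_mask, read_volume, write_mask, write_volume
from .ivim import DwiSeries, GridSamplerSettings, IvimMaps, IvimPriors, fit_volume
from .prm import PrmThresholds, classify_prm, cohort_thresholds, masked_mean, prm_fractions
from .register import RegistrationSettings, RigidTransform, estimate_rigid, resample

__all__ = [
    "PatientImages",
    "PipelineConfig",
    "CohortResults",
    "analyze_cohort",
    "run_pipeline",
    "render_prm_png",
]


@dataclass
class PatientImages:
    """The per-patient inputs the analysis needs (no ground truth)."""

    patient_id: str
    dwi_pre: DwiSeries
    gtv_pre: np.ndarray
    suv_native: np.ndarray
    suv_grid: ImageGrid
    dwi_on: DwiSeries | None = None  # None: on-treatment scan missing
    gtv_on: np.ndarray | None = None
    transform: RigidTransform | None = None  # supplied PET->MRI transform

    @classmethod
    def from_cohort_patient(cls, p) -> "PatientImages":
        return cls(
            patient_id=p.patient_id,
            dwi_pre=p.dwi_pre,
            gtv_pre=p.truth_pre.gtv_mask,
            suv_native=p.suv_native,
            suv_grid=p.suv_grid,
            dwi_on=p.dwi_on,
            gtv_on=p.truth_on.gtv_mask,
            transform=p.true_transform,
        )


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; hashed into every output table."""

    cohort_dir: str
    out_dir: str
    method: str = "bayesian"
    n_grid_points: int = 33
    use_supplied_transform: bool = False
    write_maps: bool = True
    render_png: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("bayesian", "lsq"):
            raise ValueError(f"unknown fit method {self.method!r}")
        if self.n_grid_points < 5:
            raise ValueError("n_grid_points must be >= 5")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def hash(self) -> str:
        """Digest of the analysis-relevant settings (paths excluded, so the
        same analysis in a different directory hashes identically)."""
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in ("cohort_dir", "out_dir")}
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class CohortResults:
    patient_metrics: pd.DataFrame
    thresholds: PrmThresholds
    summary: pd.DataFrame
    associations: pd.DataFrame
    paired_tests: pd.DataFrame
    voxelwise: pd.DataFrame
    voxelwise_per_patient: pd.DataFrame = field(default_factory=pd.DataFrame)
    maps_pre: dict = field(default_factory=dict)
    maps_on: dict = field(default_factory=dict)
    suv_on_mri: dict = field(default_factory=dict)
    prm_labels: dict = field(default_factory=dict)


PRM_PAIRS = ("SUV_D", "SUV_f", "D_f")

_PRM_COLUMNS = {
    "SUV_D": {1: "PRM_SUVhi_Dhi", 2: "PRM_SUVhi_Dlo", 3: "PRM_SUVlo_Dlo", 4: "PRM_SUVlo_Dhi"},
    "SUV_f": {1: "PRM_SUVhi_fhi", 2: "PRM_SUVhi_flo", 3: "PRM_SUVlo_flo", 4: "PRM_SUVlo_fhi"},
    "D_f": {1: "PRM_Dhi_fhi", 2: "PRM_Dhi_flo", 3: "PRM_Dlo_flo", 4: "PRM_Dlo_fhi"},
}


def _pair_maps(pair: str, suv, ivim: IvimMaps, thresholds: PrmThresholds):
    if pair == "SUV_D":
        return suv, ivim.D_map, thresholds.mu_SUV, thresholds.mu_D
    if pair == "SUV_f":
        return suv, ivim.f_map, thresholds.mu_SUV, thresholds.mu_f
    if pair == "D_f":
        return ivim.D_map, ivim.f_map, thresholds.mu_D, thresholds.mu_f
    raise ValueError(f"unknown metric pair {pair!r}")


def analyze_cohort(
    patients: list[PatientImages],
    method: str = "bayesian",
    priors: IvimPriors | None = None,
    sampler: GridSamplerSettings | None = None,
    reg_settings: RegistrationSettings | None = None,
    use_supplied_transform: bool = False,
    seed: int = 0,
    keep_maps: bool = True,
    log=lambda msg: None,
) -> CohortResults:
    """Run the full analysis on in-memory patient records.

    Stage 1 fits pre-treatment IVIM maps and brings SUV into the IVIM frame;
    population thresholds are then frozen from the per-patient GTV means;
    stage 2 classifies PRM, fits on-treatment maps, and assembles the
    statistics tables.
    """
    priors = priors or IvimPriors()
    sampler = sampler or GridSamplerSettings()

    stage1 = {}
    for p in patients:
        t0 = time.perf_counter()
        maps_pre = fit_volume(p.dwi_pre, p.gtv_pre, method, priors, sampler, seed)
        if use_supplied_transform and p.transform is not None:
            tfm = p.transform
        else:
            tfm = estimate_rigid(
                p.suv_native, p.suv_grid, p.dwi_pre.data[..., 0], p.dwi_pre.grid,
                reg_settings,
            )
        suv_mri = resample(p.suv_native, p.suv_grid, tfm, p.dwi_pre.grid, "trilinear")
        stage1[p.patient_id] = (maps_pre, tfm, suv_mri)
        log(f"{p.patient_id}: pre-fit + registration in {time.perf_counter() - t0:.1f}s "
            f"({maps_pre.flags})")

    means_rows = []
    for p in patients:
        maps_pre, _, suv_mri = stage1[p.patient_id]
        gtv = p.gtv_pre
        means_rows.append(
            dict(
                patient=p.patient_id,
                mean_SUV=masked_mean(suv_mri, gtv),
                mean_D=masked_mean(maps_pre.D_map, gtv),
                mean_f=masked_mean(maps_pre.f_map, gtv),
            )
        )
    thresholds = cohort_thresholds(pd.DataFrame(means_rows))
    log(f"thresholds: mu_SUV={thresholds.mu_SUV:.3f} mu_D={thresholds.mu_D:.3e} "
        f"mu_f={thresholds.mu_f:.3f}")

    results = CohortResults(
        patient_metrics=pd.DataFrame(),
        thresholds=thresholds,
        summary=pd.DataFrame(),
        associations=pd.DataFrame(),
        paired_tests=pd.DataFrame(),
        voxelwise=pd.DataFrame(),
    )

    metric_rows = []
    vox_rows = []
    paired_values: dict[str, dict[str, float]] = {}
    for p in patients:
        t0 = time.perf_counter()
        maps_pre, tfm, suv_mri = stage1[p.patient_id]
        has_on = p.dwi_on is not None and p.gtv_on is not None
        maps_on = fit_volume(p.dwi_on, p.gtv_on, method, priors, sampler, seed) if has_on else None
        gtv = p.gtv_pre
        vv = p.dwi_pre.grid.voxel_volume_cc
        gtv_pre_cc = float(gtv.sum()) * vv
        gtv_on_cc = float(p.gtv_on.sum()) * p.dwi_on.grid.voxel_volume_cc if has_on else np.nan

        row = dict(
            patient=p.patient_id,
            GTV_cc=gtv_pre_cc,
            GTV_on_cc=gtv_on_cc,
            delta_gtv_pct=delta_gtv(gtv_pre_cc, gtv_on_cc) if has_on else np.nan,
            SUV_mean=masked_mean(suv_mri, gtv),
            SUV_max=float(np.nanmax(np.where(gtv, suv_mri, np.nan))),
            D=masked_mean(maps_pre.D_map, gtv),
            f=masked_mean(maps_pre.f_map, gtv),
            Dstar=masked_mean(maps_pre.Dstar_map, gtv),
            D_on=masked_mean(maps_on.D_map, p.gtv_on) if has_on else np.nan,
            f_on=masked_mean(maps_on.f_map, p.gtv_on) if has_on else np.nan,
            Dstar_on=masked_mean(maps_on.Dstar_map, p.gtv_on) if has_on else np.nan,
        )
        if not has_on:
            log(f"{p.patient_id}: no on-treatment data; delta-GTV flagged missing")

        for pair in PRM_PAIRS:
            a, b, mu_a, mu_b = _pair_maps(pair, suv_mri, maps_pre, thresholds)
            labels = classify_prm(a, b, mu_a, mu_b, gtv, metric_pair=pair)
            fracs = prm_fractions(labels)
            for lab, col in _PRM_COLUMNS[pair].items():
                row[col] = fracs[lab]
            results.prm_labels[(p.patient_id, pair)] = labels
        # on-treatment D x f PRM with the frozen pre-treatment thresholds
        if has_on:
            a, b, mu_a, mu_b = _pair_maps("D_f", None, maps_on, thresholds)
            fr_on = prm_fractions(classify_prm(a, b, mu_a, mu_b, p.gtv_on, "D_f_on"))
            for lab, col in _PRM_COLUMNS["D_f"].items():
                row[col + "_on"] = fr_on[lab]
        else:
            for col in _PRM_COLUMNS["D_f"].values():
                row[col + "_on"] = np.nan

        metric_rows.append(row)
        vox_rows.append(
            dict(
                patient=p.patient_id,
                r_SUV_D=voxelwise_correlation(suv_mri, maps_pre.D_map, gtv),
                r_SUV_f=voxelwise_correlation(suv_mri, maps_pre.f_map, gtv),
            )
        )
        if keep_maps:
            results.maps_pre[p.patient_id] = maps_pre
            if has_on:
                results.maps_on[p.patient_id] = maps_on
            results.suv_on_mri[p.patient_id] = suv_mri
        log(f"{p.patient_id}: on-fit + PRM in {time.perf_counter() - t0:.1f}s")

    metrics = pd.DataFrame(metric_rows)
    results.patient_metrics = metrics
    results.summary = summary_table(metrics)
    results.associations = association_table(metrics)

    paired_rows = []
    pairs = [
        ("GTV_cc", "GTV_cc", "GTV_on_cc"),
        ("D", "D", "D_on"),
        ("f", "f", "f_on"),
        ("Dstar", "Dstar", "Dstar_on"),
    ] + [(c, c, c + "_on") for c in _PRM_COLUMNS["D_f"].values()]
    for name, pre_col, on_col in pairs:
        good = metrics[pre_col].notna() & metrics[on_col].notna()
        if good.sum() < 2:
            paired_rows.append(dict(variable=name, statistic=np.nan, p_value=np.nan,
                                    median_change=np.nan, n=int(good.sum()),
                                    significant=False))
            continue
        stat, pval = wilcoxon_paired(metrics.loc[good, pre_col], metrics.loc[good, on_col])
        direction = float(np.median(metrics.loc[good, on_col] - metrics.loc[good, pre_col]))
        paired_rows.append(
            dict(variable=name, statistic=stat, p_value=pval,
                 median_change=direction, n=int(good.sum()),
                 significant=bool(pval < 0.05))
        )
    results.paired_tests = pd.DataFrame(paired_rows)

    vox = pd.DataFrame(vox_rows)
    results.voxelwise = pd.DataFrame(
        dict(
            metric=["r_SUV_D", "r_SUV_f"],
            mean=[vox["r_SUV_D"].mean(), vox["r_SUV_f"].mean()],
            sd=[vox["r_SUV_D"].std(ddof=1), vox["r_SUV_f"].std(ddof=1)],
            n=[vox["r_SUV_D"].notna().sum(), vox["r_SUV_f"].notna().sum()],
        )
    )
    results.voxelwise_per_patient = vox
    return results


def render_prm_png(labels: np.ndarray, background: np.ndarray, path, slice_index=None):
    """Render one axial slice of a PRM label map over a grayscale background
    using the conventional class colors (cyan/magenta/red/green)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if slice_index is None:
        occupancy = (labels > 0).sum(axis=(0, 1))
        slice_index = int(np.argmax(occupancy))
    bg = background[:, :, slice_index].T
    lab = labels[:, :, slice_index].T.astype(float)
    lab[lab == 0] = np.nan

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(bg, cmap="gray", origin="lower")
    cmap = ListedColormap(["cyan", "magenta", "red", "green"])
    ax.imshow(lab, cmap=cmap, vmin=1, vmax=4, origin="lower", alpha=0.7)
    ax.set_axis_off()
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def _load_patients(config: PipelineConfig) -> list[PatientImages]:
    cohort = Path(config.cohort_dir)
    manifest = read_manifest(cohort / "manifest.tsv")
    patients = []
    for _, row in manifest.iterrows():
        dwi_pre = read_dwi(cohort / row["pre_dwi"])
        gtv_pre, _ = read_mask(cohort / row["pre_gtv"])
        suv, suv_grid = read_volume(cohort / row["suv"])
        dwi_on = gtv_on = None
        if pd.notna(row.get("on_dwi")) and (cohort / str(row["on_dwi"])).exists():
            dwi_on = read_dwi(cohort / row["on_dwi"])
            gtv_on, _ = read_mask(cohort / row["on_gtv"])
        tfm = None
        if "true_transform" in row and pd.notna(row.get("true_transform")):
            tfm_path = cohort / row["true_transform"]
            if tfm_path.exists():
                tfm = RigidTransform.from_text(tfm_path)
        patients.append(
            PatientImages(
                patient_id=str(row["patient_id"]),
                dwi_pre=dwi_pre,
                gtv_pre=gtv_pre,
                suv_native=suv,
                suv_grid=suv_grid,
                dwi_on=dwi_on,
                gtv_on=gtv_on,
                transform=tfm,
            )
        )
    return patients


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> CohortResults:
    """Run the full pipeline from a cohort directory and write the report
    bundle under ``config.out_dir``.  Identical config + cohort give
    byte-identical tables and maps (the log carries wall-clock timings)."""
    out = Path(config.out_dir)
    (out / "tables").mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def log(msg: str) -> None:
        log_lines.append(msg)

    t_start = time.perf_counter()
    patients = _load_patients(config)
    log(f"loaded {len(patients)} patients from {config.cohort_dir}")

    sampler = GridSamplerSettings(n_points=config.n_grid_points)
    try:
        results = analyze_cohort(
            patients,
            method=config.method,
            sampler=sampler,
            use_supplied_transform=config.use_supplied_transform,
            seed=config.seed,
            log=log,
        )
    except Exception as exc:
        (out / "run.log").write_text(
            "\n".join(log_lines + [f"FAILED: {exc}"]) + "\n"
        )
        raise

    header = [
        f"prmivim {__version__}",
        f"config_hash {config.hash()}",
        "delta_gtv convention: 100*(on-pre)/pre, shrinkage negative",
    ]
    tables = out / "tables"
    _write_tsv(results.summary, tables / "table1_summary.tsv", header)
    _write_tsv(results.associations, tables / "table2_associations.tsv", header)
    _write_tsv(results.patient_metrics, tables / "patient_metrics.tsv", header)
    _write_tsv(results.paired_tests, tables / "paired_tests.tsv", header)
    _write_tsv(results.voxelwise, tables / "voxelwise_correlations.tsv", header)
    _write_tsv(results.thresholds.to_frame(), tables / "thresholds.tsv", header)

    if config.write_maps:
        maps_dir = out / "maps"
        maps_dir.mkdir(exist_ok=True)
        for p in patients:
            pid = p.patient_id
            m = results.maps_pre[pid]
            grid = p.dwi_pre.grid
            write_volume(m.D_map, grid, maps_dir / f"{pid}_pre_D.nii")
            write_volume(m.f_map, grid, maps_dir / f"{pid}_pre_f.nii")
            write_volume(m.Dstar_map, grid, maps_dir / f"{pid}_pre_Dstar.nii")
            write_volume(results.suv_on_mri[pid], grid, maps_dir / f"{pid}_suv_mri.nii")
            for pair in PRM_PAIRS:
                labels = results.prm_labels[(pid, pair)].labels
                write_volume(labels, grid, maps_dir / f"{pid}_prm_{pair}.nii", dtype=np.uint8)
            if config.render_png:
                render_prm_png(
                    results.prm_labels[(pid, "SUV_D")].labels,
                    p.dwi_pre.data[..., 0],
                    maps_dir / f"{pid}_prm_SUV_D.png",
                )

    log(f"total {time.perf_counter() - t_start:.1f}s")
    (out / "run.log").write_text(
        "\n".join([f"prmivim {__version__}", f"config_hash {config.hash()}"] + log_lines)
        + "\n"
    )
    return results
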