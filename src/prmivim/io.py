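"""File formats: NIfTI volumes, b-value sidecars, transforms, manifests.

Volumes are NIfTI-1 (.nii or .nii.gz) with axis-aligned RAS affines.  A 4D
DWI series carries a JSON sidecar ``{"bvalues": [...]}`` next to it whose
length must match the 4th dimension.  Masks are uint8.  Rigid transforms
are 4x4 row-major text matrices (moving-world -> fixed-world, mm).  A
cohort directory is described by ``manifest.tsv`` with one row per patient
and relative file paths.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .grids import ImageGrid
from .ivim import BValueScheme, DwiSeries
from .register import RigidTransform

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_dwi",
    "write_dwi",
    "write_cohort",
    "read_manifest",
]


def write_volume(volume: np.ndarray, grid: ImageGrid, path, dtype=np.float32) -> None:
    """Write a 3D/4D volume as NIfTI-1; grid metadata goes into the affine."""
    path = Path(path)
    arr = np.asarray(volume).astype(dtype)
    img = nib.Nifti1Image(arr, grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size) + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))


def read_volume(path) -> tuple[np.ndarray, ImageGrid]:
    """Read a NIfTI volume; returns (data, grid). Raises on oblique affines."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    grid = ImageGrid.from_affine(data.shape[:3], img.affine)
    return data, grid


def write_mask(mask: np.ndarray, grid: ImageGrid, path) -> None:
    write_volume(np.asarray(mask, dtype=bool), grid, path, dtype=np.uint8)


def read_mask(path) -> tuple[np.ndarray, ImageGrid]:
    data, grid = read_volume(path)
    return data > 0.5, grid


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def write_dwi(dwi: DwiSeries, path) -> None:
    """Write a 4D DWI series plus its b-value JSON sidecar."""
    path = Path(path)
    write_volume(dwi.data, dwi.grid, path)
    _sidecar_path(path).write_text(
        json.dumps({"bvalues": list(dwi.scheme.bvalues)}) + "\n"
    )


def read_dwi(path) -> DwiSeries:
    """Read a 4D DWI series; the sidecar b-value count must match."""
    path = Path(path)
    data, grid = read_volume(path)
    if data.ndim != 4:
        raise ValueError(f"{path} is not 4D DWI (shape {data.shape})")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing b-value sidecar {sidecar}")
    bvalues = json.loads(sidecar.read_text())["bvalues"]
    if len(bvalues) != data.shape[3]:
        raise ValueError(
            f"sidecar lists {len(bvalues)} b-values but the DWI has "
            f"{data.shape[3]} frames"
        )
    return DwiSeries(data=data, scheme=BValueScheme(tuple(bvalues)), grid=grid)


# ---------------------------------------------------------------------------
# cohort directories
# ---------------------------------------------------------------------------


def write_cohort(dataset, out_dir) -> Path:
    """Write a synthetic cohort to disk and return the manifest path.

    Layout: ``<out>/<patient>/{pre_dwi.nii, pre_gtv.nii, suv.nii,
    true_transform.txt, on_dwi.nii, on_gtv.nii}`` plus sidecars, and a
    ``manifest.tsv`` holding per-patient paths and generator ground truth.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for p in dataset.patients:
        pdir = out / p.patient_id
        pdir.mkdir(exist_ok=True)
        write_dwi(p.dwi_pre, pdir / "pre_dwi.nii")
        write_mask(p.truth_pre.gtv_mask, p.truth_pre.grid, pdir / "pre_gtv.nii")
        write_volume(p.suv_native, p.suv_grid, pdir / "suv.nii")
        p.true_transform.to_text(pdir / "true_transform.txt")
        write_dwi(p.dwi_on, pdir / "on_dwi.nii")
        write_mask(p.truth_on.gtv_mask, p.truth_on.grid, pdir / "on_gtv.nii")
        rows.append(
            dict(
                patient_id=p.patient_id,
                pre_dwi=f"{p.patient_id}/pre_dwi.nii",
                pre_gtv=f"{p.patient_id}/pre_gtv.nii",
                suv=f"{p.patient_id}/suv.nii",
                true_transform=f"{p.patient_id}/true_transform.txt",
                on_dwi=f"{p.patient_id}/on_dwi.nii",
                on_gtv=f"{p.patient_id}/on_gtv.nii",
                true_D=p.true_means["D"],
                true_f=p.true_means["f"],
                true_Dstar=p.true_means["Dstar"],
                true_SUV=p.true_means["SUV"],
                true_GTV_cc=p.true_means["GTV"],
                true_volume_change_frac=p.response.volume_change_frac,
            )
        )
    manifest = out / "manifest.tsv"
    pd.DataFrame(rows).to_csv(manifest, sep="\t", index=False, float_format="%.10g")
    return manifest


def read_manifest(manifest_path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, sep="\t")
    required = {"patient_id", "pre_dwi", "pre_gtv", "suv", "on_dwi", "on_gtv"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest lacks columns: {sorted(missing)}")
    return df
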