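"""Parametric response mapping (PRM) by joint-histogram voxel classification.

Two co-registered parameter maps A and B (e.g. PET SUV and IVIM D) are
thresholded at population means (mu_A, mu_B) derived from the spatially
averaged pre-treatment values across patients.  Each tumor voxel falls in
one quadrant of the joint histogram:

    label 1  A^hi B^hi   (cyan)
    label 2  A^hi B^lo   (magenta)
    label 3  A^lo B^lo   (red)
    label 4  A^lo B^hi   (green)

"hi" means strictly greater than the threshold; a voxel exactly at the
threshold counts as "lo" (the tie rule is measure-zero for continuous maps
but fixed here for reproducibility).  Class volumes are normalized to the
total tumor volume, giving four relative-volume percentages per metric pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PrmThresholds",
    "PrmLabelMap",
    "PrmFractions",
    "PRM_COLORS",
    "masked_mean",
    "cohort_thresholds",
    "classify_prm",
    "prm_fractions",
]

#: label -> display color, kept stable across every rendering
PRM_COLORS = {1: "cyan", 2: "magenta", 3: "red", 4: "green"}

CLASS_NAMES = {1: "hi_hi", 2: "hi_lo", 3: "lo_lo", 4: "lo_hi"}


@dataclass(frozen=True)
class PrmThresholds:
    """Population-mean thresholds with the patient ids they came from."""

    mu_SUV: float
    mu_D: float
    mu_f: float
    provenance: tuple[str, ...]

    def __post_init__(self) -> None:
        for name in ("mu_SUV", "mu_D", "mu_f"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if len(self.provenance) < 2:
            raise ValueError("thresholds must be derived from at least 2 patients")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": ["mu_SUV", "mu_D", "mu_f"],
                "value": [self.mu_SUV, self.mu_D, self.mu_f],
                "n_patients": len(self.provenance),
                "provenance": ",".join(self.provenance),
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PrmThresholds":
        vals = dict(zip(df["threshold"], df["value"]))
        prov = tuple(str(df["provenance"].iloc[0]).split(","))
        return cls(vals["mu_SUV"], vals["mu_D"], vals["mu_f"], prov)


@dataclass
class PrmLabelMap:
    """Per-voxel quadrant labels (0 outside the analysis mask)."""

    labels: np.ndarray
    metric_pair: str
    colors: dict = field(default_factory=lambda: dict(PRM_COLORS))
    n_missing: int = 0


@dataclass(frozen=True)
class PrmFractions:
    """Relative-volume percentages of the four PRM classes."""

    percentages: dict[int, float]
    total_voxels: int
    metric_pair: str

    def __post_init__(self) -> None:
        if set(self.percentages) != {1, 2, 3, 4}:
            raise ValueError("percentages must be keyed by labels 1..4")
        s = float(sum(self.percentages.values()))
        if abs(s - 100.0) > 1e-9:
            raise ValueError(f"percentages must sum to 100, got {s}")

    def __getitem__(self, label: int) -> float:
        return self.percentages[label]


def masked_mean(volume: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``volume`` over ``mask``, ignoring NaN-coded voxels."""
    mask = np.asarray(mask, dtype=bool)
    if volume.shape != mask.shape:
        raise ValueError("map and mask shapes differ")
    vals = np.asarray(volume, dtype=float)[mask]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty effective mask (no finite voxels under the mask)")
    return float(vals.mean())


def cohort_thresholds(per_patient_means: pd.DataFrame) -> PrmThresholds:
    """Unweighted across-patient means of the spatially averaged GTV values.

    ``per_patient_means`` needs columns patient, mean_SUV, mean_D, mean_f —
    one pre-treatment row per patient.
    """
    required = {"patient", "mean_SUV", "mean_D", "mean_f"}
    missing = required - set(per_patient_means.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if per_patient_means["patient"].duplicated().any():
        dupes = per_patient_means.loc[per_patient_means["patient"].duplicated(), "patient"]
        raise ValueError(f"duplicate patient ids: {sorted(set(dupes))}")
    if len(per_patient_means) < 2:
        raise ValueError("need at least 2 patients to form population thresholds")
    return PrmThresholds(
        mu_SUV=float(per_patient_means["mean_SUV"].mean()),
        mu_D=float(per_patient_means["mean_D"].mean()),
        mu_f=float(per_patient_means["mean_f"].mean()),
        provenance=tuple(str(p) for p in per_patient_means["patient"]),
    )


def classify_prm(
    map_A: np.ndarray,
    map_B: np.ndarray,
    mu_A: float,
    mu_B: float,
    mask: np.ndarray,
    metric_pair: str = "",
) -> PrmLabelMap:
    """Quadrant-classify every masked voxel of the co-registered maps.

    Voxels with a missing (NaN) value in either map get label 0 and are
    counted in ``n_missing``.
    """
    map_A = np.asarray(map_A, dtype=float)
    map_B = np.asarray(map_B, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if not (map_A.shape == map_B.shape == mask.shape):
        raise ValueError(
            f"shape mismatch: A {map_A.shape}, B {map_B.shape}, mask {mask.shape}"
        )

    valid = mask & np.isfinite(map_A) & np.isfinite(map_B)
    hi_A = map_A > mu_A
    hi_B = map_B > mu_B
    labels = np.zeros(mask.shape, dtype=np.int8)
    labels[valid & hi_A & hi_B] = 1
    labels[valid & hi_A & ~hi_B] = 2
    labels[valid & ~hi_A & ~hi_B] = 3
    labels[valid & ~hi_A & hi_B] = 4
    return PrmLabelMap(
        labels=labels,
        metric_pair=metric_pair,
        n_missing=int(mask.sum() - valid.sum()),
    )


def prm_fractions(label_map: PrmLabelMap) -> PrmFractions:
    """Relative-volume percentages; exact integer counts, one division each."""
    labels = label_map.labels
    total = int((labels > 0).sum())
    if total == 0:
        raise ValueError("label map has no classified voxels")
    pct = {lab: int((labels == lab).sum()) * 100.0 / total for lab in (1, 2, 3, 4)}
    return PrmFractions(percentages=pct, total_voxels=total, metric_pair=label_map.metric_pair)
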