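"""Cohort-level statistics: tumor-volume change, paired tests, correlations.

Implements the statistical battery applied to the imaging cohort:

* ΔGTV, the signed relative percentage change in gross tumor volume,
  100 * (on - pre) / pre — shrinkage is negative;
* Wilcoxon signed-rank tests for pre- vs on-treatment differences;
* Spearman rank correlations, voxel-wise (within each patient's GTV) and
  global (across patients);
* Shapiro-Wilk normality screening (motivating the non-parametric tests);
* the summary ("mean (SD)" demographics) and association (ΔGTV vs each
  pre-treatment metric) tables.

Exact small-sample p-values: Wilcoxon uses the exact sign-flip null for
n < 26 when there are no zero differences or tied magnitudes (otherwise the
tie-corrected normal approximation); Spearman uses full permutation
enumeration for n <= 9 and the t-approximation above.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "delta_gtv",
    "wilcoxon_paired",
    "spearman",
    "voxelwise_correlation",
    "shapiro_wilk",
    "association_table",
    "summary_table",
]

ALPHA = 0.05  # two-sided significance level used throughout the reports


@dataclass(frozen=True)
class AssociationResult:
    variable: str
    spearman_r: float
    p_value: float
    n: int
    significant: bool


def delta_gtv(gtv_pre_cc: float, gtv_on_cc: float) -> float:
    """Signed relative GTV change in percent: 100*(on - pre)/pre."""
    if gtv_pre_cc <= 0 or gtv_on_cc <= 0:
        raise ValueError("GTV volumes must be positive")
    return 100.0 * (gtv_on_cc - gtv_pre_cc) / gtv_pre_cc


def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped, tied magnitudes get mid-ranks.  Returns
    (statistic, p).  All-zero differences give p = 1 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    d = y - x
    nz = d[d != 0]
    if nz.size == 0:
        warnings.warn("all paired differences are zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    has_ties = len(np.unique(np.abs(nz))) < nz.size
    if nz.size < 26 and not has_ties:
        res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                             alternative="two-sided", method="exact")
        return float(res.statistic), float(res.pvalue)
    if nz.size <= 16:
        # exact sign-flip enumeration; unlike the count-based recursion this
        # handles tied magnitudes (mid-ranks) directly
        ranks = stats.rankdata(np.abs(nz))
        w_pos = float(ranks[nz > 0].sum())
        signs = np.arange(2**nz.size)[:, None] >> np.arange(nz.size) & 1
        w_all = signs @ ranks
        center = ranks.sum() / 2.0
        p = float(np.mean(np.abs(w_all - center) >= abs(w_pos - center) - 1e-12))
        stat = min(w_pos, ranks.sum() - w_pos)
        return stat, p
    res = stats.wilcoxon(x, y, zero_method="wilcox", correction=False,
                         alternative="two-sided", method="approx")
    return float(res.statistic), float(res.pvalue)


def _spearman_exact_p(xr: np.ndarray, yr: np.ndarray, r_obs: float) -> float:
    """Exact permutation two-sided p for Spearman r (ties allowed; n <= 9)."""
    n = len(xr)
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = float(xc @ yc[list(perm)]) / denom
        count += abs(r) >= abs(r_obs) - 1e-12
        total += 1
    return count / total


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Mid-ranks for ties; exact permutation p for n <= 9, t-approximation
    above.  Constant inputs are degenerate (r undefined) and raise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input: Spearman r undefined")
    xr = stats.rankdata(x)
    yr = stats.rankdata(y)
    r = float(np.corrcoef(xr, yr)[0, 1])  # tie-corrected (Pearson on ranks)
    if len(x) <= 9:
        p = _spearman_exact_p(xr, yr, r)
    else:
        p = float(stats.spearmanr(x, y).pvalue)
    return r, p


def voxelwise_correlation(map_A, map_B, mask, min_voxels: int = 10) -> float:
    """Within-mask Spearman r between two co-registered maps.

    NaN-coded voxels in either map are excluded; fewer than ``min_voxels``
    valid pairs returns NaN (flagged missing).  Per-patient values are
    typically summarized as mean +/- SD across the cohort.
    """
    mask = np.asarray(mask, dtype=bool)
    a = np.asarray(map_A, dtype=float)[mask]
    b = np.asarray(map_B, dtype=float)[mask]
    good = np.isfinite(a) & np.isfinite(b)
    if good.sum() < min_voxels:
        return float("nan")
    return float(stats.spearmanr(a[good], b[good]).statistic)


def shapiro_wilk(x) -> tuple[float, float]:
    """Shapiro-Wilk W and p; screens metrics for normality."""
    x = np.asarray(x, dtype=float)
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.all(x == x[0]):
        raise ValueError("constant sample: W undefined")
    res = stats.shapiro(x)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# tables
# ---------------------------------------------------------------------------

#: association rows: ΔGTV against each pre-treatment metric
ASSOCIATION_METRICS = (
    "GTV_cc",
    "SUV_max",
    "SUV_mean",
    "D",
    "f",
    "Dstar",
    "PRM_SUVhi_fhi",
    "PRM_SUVhi_flo",
    "PRM_SUVlo_fhi",
    "PRM_SUVlo_flo",
    "PRM_SUVhi_Dhi",
    "PRM_SUVhi_Dlo",
    "PRM_SUVlo_Dhi",
    "PRM_SUVlo_Dlo",
    "PRM_Dhi_fhi",
    "PRM_Dhi_flo",
    "PRM_Dlo_flo",
    "PRM_Dlo_fhi",
)


def association_table(metrics: pd.DataFrame, min_patients: int = 3) -> pd.DataFrame:
    """Spearman r/p of ΔGTV against each pre-treatment metric.

    ``metrics`` has one row per patient with a ``delta_gtv_pct`` column and
    the pre-treatment columns listed in ``ASSOCIATION_METRICS`` (missing
    columns or patients yield flagged rows, never silent drops).  A
    Benjamini-Hochberg adjusted column is appended as a labelled extension;
    the significance flag uses the raw two-sided p at alpha = 0.05.
    """
    if "delta_gtv_pct" not in metrics.columns:
        raise ValueError("metrics table lacks delta_gtv_pct")
    rows = []
    dg = metrics["delta_gtv_pct"]
    for name in ASSOCIATION_METRICS:
        if name not in metrics.columns:
            rows.append(dict(variable=name, spearman_r=np.nan, p_value=np.nan,
                             n=0, significant=False, flag="missing_column"))
            continue
        col = metrics[name]
        good = col.notna() & dg.notna()
        n = int(good.sum())
        flag = "" if n == len(metrics) else f"missing_{len(metrics) - n}_patients"
        if n < min_patients or len(metrics) < min_patients:
            rows.append(dict(variable=name, spearman_r=np.nan, p_value=np.nan,
                             n=n, significant=False, flag="underpowered"))
            continue
        try:
            r, p = spearman(dg[good].to_numpy(), col[good].to_numpy())
        except ValueError:
            rows.append(dict(variable=name, spearman_r=np.nan, p_value=np.nan,
                             n=n, significant=False, flag="degenerate"))
            continue
        rows.append(dict(variable=name, spearman_r=r, p_value=p, n=n,
                         significant=bool(p < ALPHA), flag=flag))
    out = pd.DataFrame(rows)
    valid = out["p_value"].notna()
    out["p_bh_adjusted"] = np.nan  # supplementary multiple-testing column
    if valid.any():
        out.loc[valid, "p_bh_adjusted"] = stats.false_discovery_control(
            out.loc[valid, "p_value"].to_numpy(), method="bh"
        )
    return out


#: summary rows: metric column -> (display name, scale) on the report scale
SUMMARY_ROWS = (
    ("GTV_cc", "GTV, cc", 1.0),
    ("SUV_max", "PET SUVmax", 1.0),
    ("SUV_mean", "PET SUVmean", 1.0),
    ("D", "IVIM MRI D, 1e-3 mm2/s", 1e3),
    ("f", "IVIM MRI f, %", 1e2),
    ("Dstar", "IVIM MRI D*, 1e-3 mm2/s", 1e3),
    ("PRM_SUVhi_fhi", "PRM SUVhi fhi, %", 1.0),
    ("PRM_SUVhi_flo", "PRM SUVhi flo, %", 1.0),
    ("PRM_SUVlo_fhi", "PRM SUVlo fhi, %", 1.0),
    ("PRM_SUVlo_flo", "PRM SUVlo flo, %", 1.0),
    ("PRM_SUVhi_Dhi", "PRM SUVhi Dhi, %", 1.0),
    ("PRM_SUVhi_Dlo", "PRM SUVhi Dlo, %", 1.0),
    ("PRM_SUVlo_Dhi", "PRM SUVlo Dhi, %", 1.0),
    ("PRM_SUVlo_Dlo", "PRM SUVlo Dlo, %", 1.0),
)


def summary_table(metrics: pd.DataFrame) -> pd.DataFrame:
    """Cohort mean (SD) per pre-treatment metric, on conventional scales."""
    rows = []
    for col, label, scale in SUMMARY_ROWS:
        if col not in metrics.columns or metrics[col].dropna().empty:
            rows.append(dict(variable=label, mean=np.nan, sd=np.nan, n=0,
                             flag="missing"))
            continue
        vals = metrics[col].dropna() * scale
        rows.append(dict(variable=label, mean=float(vals.mean()),
                         sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
                         n=int(len(vals)), flag=""))
    return pd.DataFrame(rows)
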