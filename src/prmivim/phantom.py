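"""Digital phantoms of cervical tumors for IVIM + PET analysis.

No patient imaging is distributed with this package, so every downstream
stage (IVIM fitting, registration, PRM, cohort statistics) is exercised on
synthetic phantoms with known ground truth:

* an ellipsoidal gross tumor volume (GTV) embedded in a pelvic "body"
  ellipsoid, with a two-compartment rim/core structure — the core is more
  cellular (lower D), less perfused (lower f) and more metabolically active
  (higher SUV) than the rim;
* smooth within-tissue heterogeneity from low-pass-filtered Gaussian noise;
* magnitude DWI with Rician noise at a configurable SNR;
* a PET SUV volume on its own (offset, rotated) grid, built so the realized
  voxel-wise Spearman correlation between SUV and D inside the GTV hits a
  requested target;
* an on-treatment follow-up with tumor shrinkage and increased D and f.

Cohorts draw per-patient tumor means from Normal distributions whose
defaults reproduce the demographics of a 20-patient chemoradiation cohort
(tumor-mean D 1.07e-3 mm^2/s (SD 0.2e-3), f 12.7% (3.3), D* 13.7e-3 mm^2/s
(3.5e-3), SUV_mean 3.7 (1.6), GTV 65 cc (48)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.optimize import brentq
from scipy.stats import spearmanr

from .grids import ImageGrid
from .ivim import (
    DEFAULT_BVALUES,
    BValueScheme,
    DwiSeries,
    IvimPriors,
    ivim_signal,
)
from .register import RigidTransform, resample

__all__ = [
    "PhantomTruth",
    "ResponseParams",
    "CohortParams",
    "CohortPatient",
    "CohortDataset",
    "DEFAULT_TISSUE_MEANS",
    "make_phantom",
    "simulate_dwi",
    "simulate_followup",
    "simulate_cohort",
]

LABEL_BACKGROUND, LABEL_NORMAL, LABEL_RIM, LABEL_CORE = 0, 1, 2, 3

#: per-tissue parameter means: D and D* in mm^2/s, f fraction, S0 arbitrary,
#: SUV unitless.  Rim/core split +/-17% around the tumor means so that an
#: equal-volume core+rim tumor averages to D 1.07e-3, f 0.127, D* 13.7e-3;
#: the core is denser (low D, low f) and hotter (high SUV) than the rim.
DEFAULT_TISSUE_MEANS: dict[int, dict[str, float]] = {
    LABEL_NORMAL: dict(D=1.5e-3, f=0.07, Dstar=10e-3, S0=1000.0, SUV=1.5),
    LABEL_RIM: dict(D=1.25e-3, f=0.149, Dstar=16.0e-3, S0=1000.0, SUV=3.0),
    LABEL_CORE: dict(D=0.89e-3, f=0.105, Dstar=11.4e-3, S0=1000.0, SUV=4.5),
}

#: relative SD of the smooth within-tissue heterogeneity per parameter
DEFAULT_NOISE_AMPLITUDE: dict[str, float] = dict(
    D=0.08, f=0.12, Dstar=0.12, S0=0.03, SUV=0.15
)


@dataclass
class PhantomTruth:
    """Latent maps of one phantom: the quantities the pipeline estimates."""

    label_map: np.ndarray
    true_D: np.ndarray
    true_f: np.ndarray
    true_Dstar: np.ndarray
    true_S0: np.ndarray
    true_SUV: np.ndarray
    gtv_mask: np.ndarray
    grid: ImageGrid
    seed: int
    tumor_center_mm: tuple[float, float, float] | None = None
    tumor_radii_mm: tuple[float, float, float] | None = None

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.grid.voxel_size

    @property
    def gtv_cc(self) -> float:
        return float(self.gtv_mask.sum()) * self.grid.voxel_volume_cc

    def tumor_mean(self, which: str) -> float:
        return float({"D": self.true_D, "f": self.true_f, "Dstar": self.true_Dstar,
                      "SUV": self.true_SUV}[which][self.gtv_mask].mean())


@dataclass(frozen=True)
class ResponseParams:
    """On-treatment change applied to a phantom.

    ``volume_change_frac`` is the signed relative GTV change (-0.5 halves
    the tumor); ``delta_D``/``delta_f`` shift the tumor voxels additively;
    ``per_voxel_jitter_sd`` is the relative SD of multiplicative per-voxel
    jitter applied to the shifted D and f maps.
    """

    volume_change_frac: float = -0.5
    delta_D: float = 0.12e-3
    delta_f: float = 0.03
    per_voxel_jitter_sd: float = 0.05

    def __post_init__(self) -> None:
        if self.volume_change_frac <= -1.0:
            raise ValueError("volume_change_frac <= -1 would remove the tumor entirely")
        if self.per_voxel_jitter_sd < 0:
            raise ValueError("jitter SD must be >= 0")


@dataclass(frozen=True)
class CohortParams:
    """Distributional targets for a synthetic multi-patient cohort.

    Per-patient tumor means are drawn from Normal(mean, sd) and clipped to
    physiological ranges; defaults follow the pre-treatment demographics of
    a 20-patient cervical-cancer chemoradiation cohort.
    """

    n_patients: int = 20
    D_mean: float = 1.07e-3
    D_sd: float = 0.2e-3
    f_mean: float = 0.127
    f_sd: float = 0.033
    Dstar_mean: float = 13.7e-3
    Dstar_sd: float = 3.5e-3
    suv_mean: float = 3.7
    suv_sd: float = 1.6
    gtv_cc_mean: float = 65.0
    gtv_cc_sd: float = 48.0
    gtv_cc_range: tuple[float, float] = (15.0, 180.0)
    #: voxel-wise Spearman targets inside the GTV.  SUV-vs-D is calibrated
    #: per patient; SUV-vs-f is emergent through the phantom's spatial D-f
    #: correlation and recorded here for reference only.
    target_r_suv_d: float = -0.15
    target_r_suv_f: float = -0.08
    snr: float = 50.0
    bvalues: tuple[float, ...] = DEFAULT_BVALUES
    grid_shape: tuple[int, int, int] = (40, 40, 40)
    voxel_size: tuple[float, float, float] = (3.0, 3.0, 3.0)
    pet_shape: tuple[int, int, int] = (36, 36, 36)
    pet_voxel_size: tuple[float, float, float] = (4.0, 4.0, 4.0)
    pet_psf_fwhm_mm: float = 5.0
    #: response model: shrink magnitude m = clip(base - w_D z_D + w_SUV z_SUV
    #: + w_GTV z_GTV + noise, lo, hi); volume_change_frac = -m.  Dense,
    #: metabolically active tumors shrink more; high-D tumors shrink less.
    shrink_base: float = 0.5
    shrink_w_D: float = 0.20
    shrink_w_SUV: float = 0.06
    shrink_w_GTV: float = 0.05
    shrink_noise_sd: float = 0.05
    shrink_clip: tuple[float, float] = (0.05, 0.92)
    delta_D_mean: float = 0.12e-3
    delta_D_sd: float = 0.04e-3
    delta_f_mean: float = 0.030
    delta_f_sd: float = 0.010
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("a cohort needs at least 2 patients")
        for name in ("D_sd", "f_sd", "Dstar_sd", "suv_sd", "gtv_cc_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("target_r_suv_d", "target_r_suv_f"):
            if not -1.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (-1, 1)")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class CohortPatient:
    """One synthetic patient: pre/on-treatment truth, raw images, transforms."""

    patient_id: str
    truth_pre: PhantomTruth
    dwi_pre: DwiSeries
    suv_native: np.ndarray
    suv_grid: ImageGrid
    true_transform: RigidTransform
    truth_on: PhantomTruth
    dwi_on: DwiSeries
    response: ResponseParams
    true_means: dict


@dataclass
class CohortDataset:
    patients: list[CohortPatient]
    params: CohortParams

    def __iter__(self):
        return iter(self.patients)

    def __len__(self):
        return len(self.patients)


# ---------------------------------------------------------------------------
# single-phantom construction
# ---------------------------------------------------------------------------


def _ellipsoid_mask(grid: ImageGrid, center_mm, radii_mm) -> np.ndarray:
    coords = [np.arange(n) * v for n, v in zip(grid.shape, grid.voxel_size)]
    coords = [c + o for c, o in zip(coords, grid.origin)]
    xx, yy, zz = np.meshgrid(*coords, indexing="ij")
    cx, cy, cz = center_mm
    rx, ry, rz = radii_mm
    return ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 + ((zz - cz) / rz) ** 2 <= 1.0


def _smooth_field(rng: np.random.Generator, shape, sigma_vox) -> np.ndarray:
    """Low-pass filtered unit-SD Gaussian field."""
    raw = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(raw, sigma_vox)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def make_phantom(
    grid_shape=(64, 64, 64),
    voxel_size=(2.0, 2.0, 2.0),
    tumor_radii_mm=(25.0, 25.0, 25.0),
    tissue_means: dict | None = None,
    seed: int = 0,
    noise_amplitude: dict | float | None = None,
    noise_smoothing_mm: float = 6.0,
    tumor_center_mm=None,
    priors: IvimPriors | None = None,
) -> PhantomTruth:
    """Build an ellipsoidal rim/core tumor phantom with known true maps.

    The core occupies half the tumor volume (radii scaled by 2^(-1/3)).
    ``noise_amplitude`` (scalar or per-parameter dict of relative SDs; 0
    disables heterogeneity) modulates smooth within-tissue variation.
    Deterministic for a given seed.
    """
    grid = ImageGrid(tuple(grid_shape), tuple(voxel_size))
    priors = priors or IvimPriors()
    tissue_means = tissue_means or DEFAULT_TISSUE_MEANS
    if noise_amplitude is None:
        amp = dict(DEFAULT_NOISE_AMPLITUDE)
    elif np.isscalar(noise_amplitude):
        amp = {k: float(noise_amplitude) for k in DEFAULT_NOISE_AMPLITUDE}
    else:
        amp = {**DEFAULT_NOISE_AMPLITUDE, **dict(noise_amplitude)}

    fov = np.asarray(grid.shape) * np.asarray(grid.voxel_size)
    center = np.asarray(tumor_center_mm if tumor_center_mm is not None else fov / 2.0, float)
    radii = np.asarray(tumor_radii_mm, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("tumor radii must be positive")
    if np.any(center - radii < 0) or np.any(center + radii > fov):
        raise ValueError(
            f"tumor (center {tuple(center)} mm, radii {tuple(radii)} mm) exceeds the "
            f"grid field of view {tuple(fov)} mm"
        )

    body = _ellipsoid_mask(grid, fov / 2.0, fov / 2.0 * 0.95)
    rim = _ellipsoid_mask(grid, center, radii)
    core = _ellipsoid_mask(grid, center, radii * 2.0 ** (-1.0 / 3.0))

    label = np.zeros(grid.shape, dtype=np.int8)
    label[body] = LABEL_NORMAL
    label[rim] = LABEL_RIM
    label[core] = LABEL_CORE

    rng = np.random.default_rng(seed)
    sigma_vox = noise_smoothing_mm / np.asarray(grid.voxel_size)
    maps = {}
    for name in ("D", "f", "Dstar", "S0", "SUV"):
        vol = np.zeros(grid.shape)
        for lab, means in tissue_means.items():
            vol[label == lab] = means[name]
        if amp[name] > 0:
            vol = vol * (1.0 + amp[name] * _smooth_field(rng, grid.shape, sigma_vox))
        vol[label == LABEL_BACKGROUND] = 0.0
        maps[name] = vol

    lo, hi = priors.D_bounds
    maps["D"] = np.clip(maps["D"], lo, hi)
    maps["f"] = np.clip(maps["f"], *priors.f_bounds)
    maps["Dstar"] = np.clip(maps["Dstar"], *priors.Dstar_bounds)
    maps["S0"] = np.clip(maps["S0"], 0.0, None)
    maps["SUV"] = np.clip(maps["SUV"], 0.0, None)
    # the pseudo-diffusion pool must be strictly faster everywhere
    maps["D"] = np.minimum(maps["D"], 0.99 * maps["Dstar"])

    return PhantomTruth(
        label_map=label,
        true_D=maps["D"],
        true_f=maps["f"],
        true_Dstar=maps["Dstar"],
        true_S0=maps["S0"],
        true_SUV=maps["SUV"],
        gtv_mask=label >= LABEL_RIM,
        grid=grid,
        seed=seed,
        tumor_center_mm=tuple(center),
        tumor_radii_mm=tuple(radii),
    )


def simulate_dwi(
    truth: PhantomTruth,
    bvalues=DEFAULT_BVALUES,
    sigma: float = 20.0,
    seed: int = 0,
) -> DwiSeries:
    """Forward-simulate magnitude DWI with Rician noise.

    The noiseless signal is the IVIM forward model per voxel; the magnitude
    is sqrt((s + n1)^2 + n2^2) with n1, n2 ~ Normal(0, sigma^2), so
    background voxels (S0 = 0) carry Rayleigh noise.  sigma = S0/SNR links
    the noise level to a b=0 signal-to-noise ratio.
    """
    scheme = BValueScheme(tuple(bvalues))  # validates b=0 presence, ordering
    if sigma < 0:
        raise ValueError("noise sigma must be >= 0")
    b = scheme.array
    clean = ivim_signal(
        b,
        truth.true_S0[..., None],
        truth.true_D[..., None],
        truth.true_f[..., None],
        truth.true_Dstar[..., None],
    )
    if sigma == 0:
        data = clean
    else:
        rng = np.random.default_rng(seed)
        n1 = rng.normal(0.0, sigma, clean.shape)
        n2 = rng.normal(0.0, sigma, clean.shape)
        data = np.sqrt((clean + n1) ** 2 + n2**2)
    return DwiSeries(data=data, scheme=scheme, grid=truth.grid)


# ---------------------------------------------------------------------------
# follow-up
# ---------------------------------------------------------------------------


def simulate_followup(
    truth: PhantomTruth,
    resp: ResponseParams,
    seed: int = 0,
    priors: IvimPriors | None = None,
) -> PhantomTruth:
    """Apply treatment response: GTV volume change plus D/f shifts.

    The new mask keeps the ``k`` voxels deepest inside (shrinkage) or closest
    to (growth, within the body) the current GTV, measured by the signed
    Euclidean distance to the tumor surface, with a deterministic index
    tie-break — the discrete analogue of eroding/scaling the ellipsoid.
    Voxels leaving the GTV revert to normal-tissue parameters.
    """
    priors = priors or IvimPriors()
    rng = np.random.default_rng(seed)
    mask = truth.gtv_mask
    n_vox = int(mask.sum())
    k = int(round(n_vox * (1.0 + resp.volume_change_frac)))
    if k <= 0:
        raise ValueError("volume change shrinks the GTV to zero voxels")

    sampling = truth.grid.voxel_size
    d_in = ndimage.distance_transform_edt(mask, sampling=sampling)
    d_out = ndimage.distance_transform_edt(~mask, sampling=sampling)
    signed = np.where(mask, d_in, -d_out)

    body = truth.label_map >= LABEL_NORMAL
    candidates = np.flatnonzero(body.ravel())
    depth = signed.ravel()[candidates]
    order = np.lexsort((candidates, -depth))  # deepest first, index tie-break
    keep = candidates[order[:k]]
    new_mask = np.zeros(truth.label_map.size, dtype=bool)
    new_mask[keep] = True
    new_mask = new_mask.reshape(truth.label_map.shape)

    label = truth.label_map.copy()
    # voxels that left the tumor become normal tissue; new voxels (growth) rim
    label[(label >= LABEL_RIM) & ~new_mask] = LABEL_NORMAL
    label[new_mask & (label < LABEL_RIM)] = LABEL_RIM

    jit = resp.per_voxel_jitter_sd
    nD = int(new_mask.sum())
    normal = DEFAULT_TISSUE_MEANS[LABEL_NORMAL]

    def shifted(vals: np.ndarray, delta: float, normal_value: float) -> np.ndarray:
        """Tumor map after response: the surviving region's mean moves by
        ``delta`` relative to the pre-treatment tumor mean.

        Shrinkage preferentially keeps the tumor core, whose baseline D/f
        differ from the rim; re-centering on the pre-treatment mean makes
        ``delta`` the change a tumor-mean measurement actually sees, for any
        shrinkage fraction, instead of being confounded by composition.
        """
        out = vals.copy()
        out[mask & ~new_mask] = normal_value
        base = vals[mask].mean()
        out[new_mask] = vals[new_mask] - vals[new_mask].mean() + base + delta
        if jit > 0:
            out[new_mask] *= 1.0 + rng.normal(0.0, jit, nD)
        return out

    D = shifted(truth.true_D, resp.delta_D, normal["D"])
    f = shifted(truth.true_f, resp.delta_f, normal["f"])
    Dstar = shifted(truth.true_Dstar, 0.0, normal["Dstar"])  # D* unchanged on average
    D = np.clip(D, *priors.D_bounds)
    f = np.clip(f, *priors.f_bounds)
    Dstar = np.clip(Dstar, *priors.Dstar_bounds)
    D = np.minimum(D, 0.99 * Dstar)

    return PhantomTruth(
        label_map=label,
        true_D=D,
        true_f=f,
        true_Dstar=Dstar,
        true_S0=truth.true_S0.copy(),
        true_SUV=truth.true_SUV.copy(),
        gtv_mask=new_mask,
        grid=truth.grid,
        seed=truth.seed,
        tumor_center_mm=truth.tumor_center_mm,
        tumor_radii_mm=truth.tumor_radii_mm,
    )


# ---------------------------------------------------------------------------
# SUV construction with a calibrated voxel-wise correlation
# ---------------------------------------------------------------------------


def _couple_suv(
    truth: PhantomTruth,
    suv_mean: float,
    target_r: float,
    rng: np.random.Generator,
    psf_sigma_vox,
    background_suv: float | None = None,
    measurement_op=None,
    clamp: bool = False,
) -> np.ndarray:
    """SUV map on the IVIM grid whose within-GTV Spearman r against true D
    hits ``target_r``.

    The latent field is -w * z(D) + sqrt(1-w^2) * eps with smooth unit noise
    eps; a monotone exponential maps it to positive SUV, so the rank
    correlation is set entirely by w, which is solved by 1-D root finding on
    the realized (PSF-smoothed) correlation.  Raises if the target is
    unreachable with the configured noise.
    """
    gtv = truth.gtv_mask
    D = truth.true_D
    Dz = np.zeros_like(D)
    mu, sd = D[gtv].mean(), D[gtv].std()
    if sd == 0:
        raise ValueError("degenerate phantom: constant D inside the GTV")
    Dz[gtv] = (D[gtv] - mu) / sd
    Dz = ndimage.gaussian_filter(Dz * gtv, 1.0)  # mild spatial regularity
    eps = _smooth_field(rng, D.shape, 1.5)
    body = truth.label_map >= LABEL_NORMAL
    if background_suv is None:
        # moderate tumor/background contrast: keeps the PSF edge-darkening
        # from dominating the within-GTV ranks on small tumors
        background_suv = max(0.8, 0.5 * suv_mean)
    bg = np.clip(background_suv * (1.0 + 0.15 * _smooth_field(rng, D.shape, 2.0)), 0.1, None)

    d_vals = D[gtv]

    def build(w):
        """Final composite SUV map (monotone transform + background + PSF)."""
        latent = -w * Dz + math.sqrt(max(0.0, 1.0 - w * w)) * eps
        suv = np.zeros_like(D)
        inside = np.exp(0.6 * latent[gtv])
        suv[gtv] = suv_mean * inside / inside.mean()
        suv[body & ~gtv] = bg[body & ~gtv]
        return ndimage.gaussian_filter(suv, psf_sigma_vox)

    def realized(w):
        suv = build(w)
        if measurement_op is not None:
            suv = measurement_op(suv)
        good = np.isfinite(suv[gtv])
        return spearmanr(suv[gtv][good], d_vals[good]).statistic

    # calibrate on the *measured* map: the PSF (and, when supplied, the
    # PET-grid resampling round trip) couples GTV-edge voxels to the cooler
    # background, which by itself skews the within-GTV correlation
    lo_r, hi_r = realized(0.999), realized(-0.999)
    if not (min(lo_r, hi_r) - 0.02 <= target_r <= max(lo_r, hi_r) + 0.02):
        if not clamp:
            raise ValueError(
                f"voxel-wise correlation target {target_r:+.2f} is infeasible: "
                f"achievable range [{lo_r:+.2f}, {hi_r:+.2f}] with the configured noise"
            )
        # small tumors under a wide PSF cannot always reach a weak target;
        # take the nearest achievable coupling instead of aborting the cohort
        return build(0.999 if abs(target_r - lo_r) < abs(target_r - hi_r) else -0.999)
    w_opt = brentq(lambda w: realized(w) - target_r, -0.999, 0.999, xtol=1e-3)
    return build(w_opt)


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def _radii_for_volume(volume_cc: float, anisotropy=(1.12, 1.0, 0.8929)) -> np.ndarray:
    """Ellipsoid radii (mm) with product matching a sphere of ``volume_cc``."""
    r_eq = (3.0 * volume_cc * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    an = np.asarray(anisotropy)
    return r_eq * an / np.prod(an) ** (1.0 / 3.0)


def simulate_cohort(params: CohortParams) -> CohortDataset:
    """Generate a full synthetic cohort with pre/on-treatment imaging.

    Each patient gets: a pre-treatment phantom and Rician-noise DWI; a PET
    SUV volume on an offset/rotated native grid together with the true rigid
    transform into the IVIM frame; an on-treatment phantom and DWI with
    shrinkage and D/f increases.  Shrinkage is coupled to patient-level
    pre-treatment properties (dense high-SUV tumors shrink most), giving the
    cohort a built-in association between PRM sub-volumes and volume change.
    """
    ss = np.random.SeedSequence(params.seed)
    patient_seeds = ss.spawn(params.n_patients)
    rng_cohort = np.random.default_rng(ss.spawn(1)[0])

    n = params.n_patients
    draws = {
        "D": np.clip(rng_cohort.normal(params.D_mean, params.D_sd, n), 0.5e-3, 2.4e-3),
        "f": np.clip(rng_cohort.normal(params.f_mean, params.f_sd, n), 0.04, 0.30),
        "Dstar": np.clip(
            rng_cohort.normal(params.Dstar_mean, params.Dstar_sd, n), 6e-3, 28e-3
        ),
        "SUV": np.clip(rng_cohort.normal(params.suv_mean, params.suv_sd, n), 1.2, 12.0),
        "GTV": np.clip(
            rng_cohort.normal(params.gtv_cc_mean, params.gtv_cc_sd, n),
            *params.gtv_cc_range,
        ),
    }

    def z(x):
        s = x.std()
        return (x - x.mean()) / s if s > 0 else np.zeros_like(x)

    zD, zSUV, zGTV = z(draws["D"]), z(draws["SUV"]), z(draws["GTV"])
    shrink_mag = np.clip(
        params.shrink_base
        - params.shrink_w_D * zD
        + params.shrink_w_SUV * zSUV
        + params.shrink_w_GTV * zGTV
        + rng_cohort.normal(0.0, params.shrink_noise_sd, n),
        *params.shrink_clip,
    )
    delta_D = np.clip(rng_cohort.normal(params.delta_D_mean, params.delta_D_sd, n), 0.02e-3, None)
    delta_f = np.clip(rng_cohort.normal(params.delta_f_mean, params.delta_f_sd, n), 0.008, None)

    patients: list[CohortPatient] = []
    for i in range(n):
        rng = np.random.default_rng(patient_seeds[i])
        sub = rng.integers(0, 2**31 - 1, size=8)

        tissue = {LABEL_NORMAL: dict(DEFAULT_TISSUE_MEANS[LABEL_NORMAL])}
        for lab, sign in ((LABEL_RIM, +1.0), (LABEL_CORE, -1.0)):
            tissue[lab] = dict(
                D=draws["D"][i] * (1.0 + sign * 0.17),
                f=draws["f"][i] * (1.0 + sign * 0.17),
                Dstar=draws["Dstar"][i] * (1.0 + sign * 0.17),
                S0=1000.0,
                SUV=draws["SUV"][i],  # replaced by the coupled SUV below
            )

        radii = _radii_for_volume(draws["GTV"][i])
        truth = make_phantom(
            grid_shape=params.grid_shape,
            voxel_size=params.voxel_size,
            tumor_radii_mm=tuple(radii),
            tissue_means=tissue,
            seed=int(sub[0]),
        )

        sigma = 1000.0 / params.snr
        dwi_pre = simulate_dwi(truth, params.bvalues, sigma, seed=int(sub[1]))

        # PET native grid: offset origin, known rigid transform into MRI frame
        rng_t = np.random.default_rng(int(sub[3]))
        angles = np.radians(rng_t.uniform(-3.0, 3.0, 3))
        shift = rng_t.uniform(-6.0, 6.0, 3)
        center = truth.grid.center_world()
        true_tfm = RigidTransform.from_params(angles, shift, center)

        fov_mri = np.asarray(params.grid_shape) * np.asarray(params.voxel_size)
        fov_pet = np.asarray(params.pet_shape) * np.asarray(params.pet_voxel_size)
        pet_grid = ImageGrid(
            params.pet_shape, params.pet_voxel_size, tuple((fov_mri - fov_pet) / 2.0)
        )

        def roundtrip(suv, _g=truth.grid, _pg=pet_grid, _t=true_tfm):
            """What the pipeline measures: SUV after the PET-grid round trip."""
            native = resample(suv, _g, _t.inverse(), _pg)
            return resample(np.nan_to_num(native, nan=0.0), _pg, _t, _g)

        psf_sigma_vox = (
            params.pet_psf_fwhm_mm / 2.3548 / np.asarray(params.voxel_size)
        )
        suv_ivim = _couple_suv(
            truth,
            draws["SUV"][i],
            params.target_r_suv_d,
            np.random.default_rng(int(sub[2])),
            psf_sigma_vox,
            measurement_op=roundtrip,
            clamp=True,
        )
        truth.true_SUV = suv_ivim

        # PET shows, at native location x_p, the object at T(x_p) in MRI world
        suv_native = resample(suv_ivim, truth.grid, true_tfm.inverse(), pet_grid)
        noise = np.random.default_rng(int(sub[4])).normal(
            0.0, 0.02 * np.nanmax(suv_native), pet_grid.shape
        )
        suv_native = np.clip(np.nan_to_num(suv_native, nan=0.0) + noise, 0.0, None)

        resp = ResponseParams(
            volume_change_frac=float(-shrink_mag[i]),
            delta_D=float(delta_D[i]),
            delta_f=float(delta_f[i]),
            per_voxel_jitter_sd=0.05,
        )
        truth_on = simulate_followup(truth, resp, seed=int(sub[5]))
        dwi_on = simulate_dwi(truth_on, params.bvalues, sigma, seed=int(sub[6]))

        patients.append(
            CohortPatient(
                patient_id=f"P{i + 1:03d}",
                truth_pre=truth,
                dwi_pre=dwi_pre,
                suv_native=suv_native,
                suv_grid=pet_grid,
                true_transform=true_tfm,
                truth_on=truth_on,
                dwi_on=dwi_on,
                response=resp,
                true_means={k: float(v[i]) for k, v in draws.items()},
            )
        )

    return CohortDataset(patients=patients, params=params)
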