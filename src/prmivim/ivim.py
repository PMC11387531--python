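"""Intravoxel incoherent motion (IVIM) signal model and voxel-wise fitting.

The bi-exponential IVIM model decomposes the diffusion-weighted signal decay
into a tissue-water diffusion compartment (diffusion coefficient ``D``) and a
capillary pseudo-diffusion compartment (pseudo-diffusion coefficient ``D*``,
signal fraction ``f``):

    S(b) = S0 * [ f * exp(-b * D*) + (1 - f) * exp(-b * D) ]

Two estimators are provided:

``fit_voxel_lsq`` / the lsq path of ``fit_volume``
    Segmented least squares: log-linear regression on the high-b tail
    (b >= ``b_split``) for D and the extrapolated intercept, f from the
    intercept deficit at b=0, then a bounded Gauss-Newton polish of all four
    parameters.  Fast, and the initializer/reference for the Bayesian fit.

``fit_voxel_bayesian`` / the bayesian path of ``fit_volume``
    Posterior mean under a Gaussian likelihood with the noise scale
    marginalized analytically (Jeffreys prior) and S0 marginalized with a flat
    prior, evaluated by dense marginalization on a per-voxel adaptive grid over
    (D, f, D*) centered on the least-squares initializer.  Uniform box priors.
    Deterministic, so identical inputs always give identical estimates.

Units: b-values in s/mm^2, D and D* in mm^2/s, f a unitless fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid

__all__ = [
    "BValueScheme",
    "IvimPriors",
    "GridSamplerSettings",
    "IvimEstimate",
    "IvimMaps",
    "DwiSeries",
    "ivim_signal",
    "fit_signals",
    "fit_voxel_lsq",
    "fit_voxel_bayesian",
    "fit_volume",
]

# conventional IVIM split between perfusion- and diffusion-dominated regimes
DEFAULT_B_SPLIT = 200.0

FLAG_OK = "ok"
FLAG_CLIPPED = "clipped"
FLAG_EDGE = "edge"
FLAG_UNIDENTIFIABLE = "unidentifiable"
FLAG_FAILED = "failed"


@dataclass(frozen=True)
class BValueScheme:
    """Ordered diffusion-weighting scheme in s/mm^2."""

    bvalues: tuple[float, ...]
    b_split: float = DEFAULT_B_SPLIT

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.bvalues)
        if len(b) < 4:
            raise ValueError("at least 4 b-values are needed to identify S0, D, f, D*")
        if any(x < 0 for x in b):
            raise ValueError("b-values must be non-negative")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])):
            raise ValueError("b-values must be strictly increasing")
        if b[0] != 0.0:
            raise ValueError("the scheme must contain b=0 (signal normalization anchor)")
        object.__setattr__(self, "bvalues", b)

    def __len__(self) -> int:
        return len(self.bvalues)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.bvalues, dtype=float)

    @property
    def perfusion_identifiable(self) -> bool:
        """True when the scheme samples the perfusion-dominated regime.

        With no b-value strictly between 0 and ``b_split`` the fast
        compartment has decayed everywhere it is measured, so f and D* are
        flagged unidentifiable rather than silently returned.
        """
        b = self.array
        return bool(np.any((b > 0) & (b < self.b_split)))


#: default 11-b-value scheme (dense low-b sampling separates f and D*)
DEFAULT_BVALUES = (0.0, 10.0, 20.0, 30.0, 50.0, 80.0, 100.0, 150.0, 200.0, 500.0, 800.0)


@dataclass(frozen=True)
class IvimPriors:
    """Uniform box priors / hard bounds for the IVIM parameters.

    The D upper bound sits at the D* lower bound, which enforces compartment
    identifiability (the pseudo-diffusion pool is always the faster one).
    """

    D_bounds: tuple[float, float] = (1e-5, 3e-3)
    f_bounds: tuple[float, float] = (0.0, 0.5)
    Dstar_bounds: tuple[float, float] = (3e-3, 0.3)
    S0_scale: float = 2.0  # S0 prior upper bound = S0_scale * max(signal)
    family: str = "uniform"

    def __post_init__(self) -> None:
        for name in ("D_bounds", "f_bounds", "Dstar_bounds"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: lower bound must be < upper bound")
        if self.D_bounds[1] > self.Dstar_bounds[0]:
            raise ValueError("D upper bound must not exceed D* lower bound")
        if self.S0_scale <= 0:
            raise ValueError("S0_scale must be positive")


@dataclass(frozen=True)
class GridSamplerSettings:
    """Settings for the dense-grid posterior marginalization.

    ``n_points`` grid points per axis; the grid is centered on the
    least-squares initializer with multiplicative half-span ``span_D`` /
    ``span_Dstar`` (geometric spacing) and additive half-span ``span_f``
    (linear spacing), intersected with the prior box.
    """

    n_points: int = 33
    span_D: float = 2.0
    span_f: float = 0.2
    span_Dstar: float = 8.0
    chunk_size: int = 64
    edge_mass_warn: float = 0.2
    #: "empirical" = lognormal D* shrinkage prior learned from the stage-1
    #: LSQ fits across voxels (batch fits only); "uniform" = flat box prior.
    dstar_prior: str = "empirical"

    def __post_init__(self) -> None:
        if self.n_points < 5:
            raise ValueError("need at least 5 grid points per axis")
        if min(self.span_D, self.span_Dstar) <= 1 or self.span_f <= 0:
            raise ValueError("grid spans must exceed 1 (geometric) / 0 (linear)")


@dataclass(frozen=True)
class IvimEstimate:
    """Point estimates (posterior means for the Bayesian fitter) and spreads."""

    D: float
    f: float
    Dstar: float
    S0: float
    sd_D: float = 0.0
    sd_f: float = 0.0
    sd_Dstar: float = 0.0
    sd_S0: float = 0.0
    flag: str = FLAG_OK
    method: str = "lsq"


@dataclass
class IvimMaps:
    """Voxel-wise parameter maps on the DWI grid; NaN outside ``fit_mask``."""

    D_map: np.ndarray
    f_map: np.ndarray
    Dstar_map: np.ndarray
    S0_map: np.ndarray
    fit_mask: np.ndarray
    flags: dict = field(default_factory=dict)
    grid: ImageGrid | None = None


@dataclass
class DwiSeries:
    """A 4D multi-b-value DWI acquisition: spatial axes then the b axis."""

    data: np.ndarray
    scheme: BValueScheme
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("DWI data must be 4D (x, y, z, b)")
        if self.data.shape[-1] != len(self.scheme):
            raise ValueError(
                f"DWI has {self.data.shape[-1]} frames but the scheme has "
                f"{len(self.scheme)} b-values"
            )
        if tuple(self.data.shape[:3]) != tuple(self.grid.shape):
            raise ValueError("DWI spatial shape does not match its grid")


def ivim_signal(b, S0, D, f, Dstar):
    """Noiseless bi-exponential IVIM signal. Broadcasts over all arguments."""
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    S0, D, f, Dstar = (np.asarray(x, dtype=float) for x in (S0, D, f, Dstar))
    out = S0 * (f * np.exp(-b * Dstar) + (1.0 - f) * np.exp(-b * D))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# segmented least squares (batched over voxels)
# ---------------------------------------------------------------------------


def _model_and_jac(theta, b):
    """Model signal and Jacobian for theta = (S0, D, f, Dstar), batched."""
    S0, D, f, Ds = (theta[..., i, None] for i in range(4))
    eD = np.exp(-b * D)
    eS = np.exp(-b * Ds)
    g = f * eS + (1.0 - f) * eD
    model = S0 * g
    jac = np.stack(
        [g, -S0 * (1.0 - f) * b * eD, S0 * (eS - eD), -S0 * f * b * eS], axis=-1
    )
    return model, jac


def _project(theta, lo, hi):
    return np.clip(theta, lo, hi)


def _lsq_batch(signals: np.ndarray, scheme: BValueScheme, priors: IvimPriors):
    """Segmented init + projected Gauss-Newton polish for a (N, nb) batch.

    Returns (theta (N,4), flags (N,) str array) with theta columns
    (S0, D, f, Dstar).
    """
    b = scheme.array
    signals = np.asarray(signals, dtype=float)
    n, nb = signals.shape
    if nb != len(b):
        raise ValueError("signal length does not match the b-value scheme")

    Dlo, Dhi = priors.D_bounds
    flo, fhi = priors.f_bounds
    Slo, Shi_scale = 0.0, priors.S0_scale
    dslo, dshi = priors.Dstar_bounds

    ok = np.isfinite(signals).all(axis=1) & (signals[:, 0] > 0)
    flags = np.full(n, FLAG_OK, dtype=object)
    flags[~ok] = FLAG_FAILED

    theta = np.zeros((n, 4))
    if not ok.any():
        return theta, flags

    s = signals[ok]
    s0_meas = s[:, 0]
    s0_hi = Shi_scale * s.max(axis=1)

    # high-b tail: ln S = ln(S0 (1-f)) - b D
    hi_b = b >= scheme.b_split
    if hi_b.sum() < 2:  # degenerate scheme: fall back to all b > 0
        hi_b = b > 0
    X = np.stack([np.ones(hi_b.sum()), -b[hi_b]], axis=1)
    logs = np.log(np.clip(s[:, hi_b], 1e-12, None))
    coef, *_ = np.linalg.lstsq(X, logs.T, rcond=None)
    icpt, D0 = np.exp(coef[0]), coef[1]
    D0 = np.clip(D0, Dlo, Dhi)
    f0 = np.clip(1.0 - icpt / s0_meas, flo, fhi)

    # coarse bounded search for D* with (D, f) held, then GN polish of all four
    ds_cand = np.geomspace(dslo, dshi, 48)
    model = s0_meas[:, None, None] * (
        f0[:, None, None] * np.exp(-b * ds_cand[None, :, None])
        + (1.0 - f0)[:, None, None] * np.exp(-b * D0[:, None, None])
    )  # (m, 48, nb)
    sse = ((model - s[:, None, :]) ** 2).sum(axis=2)
    ds0 = ds_cand[np.argmin(sse, axis=1)]

    th = np.stack([s0_meas, D0, f0, ds0], axis=1)
    lo = np.array([Slo, Dlo, flo, dslo])
    hi_arr = np.stack(
        [s0_hi, np.full_like(s0_hi, Dhi), np.full_like(s0_hi, fhi), np.full_like(s0_hi, dshi)],
        axis=1,
    )
    th = np.clip(th, lo, hi_arr)

    model, _ = _model_and_jac(th, b)
    sse = ((model - s) ** 2).sum(axis=1)
    lam = np.full(len(th), 1e-3)
    for _ in range(40):  # damped Gauss-Newton with box projection
        model, J = _model_and_jac(th, b)
        r = s - model
        JtJ = np.einsum("vbi,vbj->vij", J, J)
        Jtr = np.einsum("vbi,vb->vi", J, r)
        A = JtJ + lam[:, None, None] * np.eye(4) * np.maximum(
            np.einsum("vii->v", JtJ)[:, None, None] / 4.0, 1e-30
        )
        try:
            step = np.linalg.solve(A, Jtr[..., None])[..., 0]
        except np.linalg.LinAlgError:
            step = np.einsum("vij,vj->vi", np.linalg.pinv(A), Jtr)
        th_new = np.clip(th + step, lo, hi_arr)
        model_new, _ = _model_and_jac(th_new, b)
        sse_new = ((model_new - s) ** 2).sum(axis=1)
        better = sse_new <= sse
        th = np.where(better[:, None], th_new, th)
        lam = np.where(better, lam * 0.5, lam * 4.0)
        sse = np.where(better, sse_new, sse)

    theta[ok] = th

    at_bound = (
        (np.abs(th[:, 1] - Dlo) < 1e-12)
        | (np.abs(th[:, 1] - Dhi) < 1e-12)
        | (np.abs(th[:, 3] - dslo) < 1e-15)
        | (np.abs(th[:, 3] - dshi) < 1e-12)
    )
    sub = flags[ok]
    sub[at_bound] = FLAG_CLIPPED
    if not scheme.perfusion_identifiable:
        sub[:] = FLAG_UNIDENTIFIABLE
    flags[ok] = sub
    return theta, flags


def fit_voxel_lsq(signal, scheme: BValueScheme, priors: IvimPriors | None = None) -> IvimEstimate:
    """Segmented least-squares fit of a single voxel (the reference fitter)."""
    priors = priors or IvimPriors()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) != len(scheme):
        raise ValueError("signal must be 1D with one sample per b-value")
    order = np.argsort(scheme.array)  # order invariance; scheme is sorted already
    theta, flags = _lsq_batch(signal[None, order], scheme, priors)
    S0, D, f, Ds = theta[0]
    return IvimEstimate(D=D, f=f, Dstar=Ds, S0=S0, flag=str(flags[0]), method="lsq")


# ---------------------------------------------------------------------------
# Bayesian dense-grid marginalization (batched over voxels)
# ---------------------------------------------------------------------------


def _axis_grid_geometric(center, lo_b, hi_b, span, m):
    """Per-voxel geometric grid through ``center`` covering [center/span, center*span]
    intersected with [lo_b, hi_b]; shape (N, 2m-1)."""
    center = np.clip(center, lo_b * 1.0000001, hi_b * 0.9999999)
    lo = np.maximum(lo_b, center / span)
    hi = np.minimum(hi_b, center * span)
    t = np.linspace(0.0, 1.0, m)
    left = lo[:, None] * (center / lo)[:, None] ** t  # lo -> center
    right = center[:, None] * (hi / center)[:, None] ** t  # center -> hi
    return np.concatenate([left, right[:, 1:]], axis=1)


def _axis_grid_linear(center, lo_b, hi_b, span, m):
    center = np.clip(center, lo_b, hi_b)
    lo = np.maximum(lo_b, center - span)
    hi = np.minimum(hi_b, center + span)
    t = np.linspace(0.0, 1.0, m)
    left = lo[:, None] + (center - lo)[:, None] * t
    right = center[:, None] + (hi - center)[:, None] * t
    return np.concatenate([left, right[:, 1:]], axis=1)


def _trapezoid_weights(grid):
    """Quadrature weights (cell widths) for a (N, k) monotone grid."""
    w = np.empty_like(grid)
    w[:, 1:-1] = (grid[:, 2:] - grid[:, :-2]) / 2.0
    w[:, 0] = (grid[:, 1] - grid[:, 0]) / 2.0
    w[:, -1] = (grid[:, -1] - grid[:, -2]) / 2.0
    return np.maximum(w, 1e-300)


def _empirical_hyperpriors(theta_lsq: np.ndarray, flags):
    """Shrinkage hyperpriors for (f, D*) from stage-1 LSQ fits across voxels.

    Robust location/scale (median, scaled MAD): lognormal for the scale
    parameter D*, normal for f.  Widths are floored so a homogeneous region
    never collapses the prior to a spike, and the D* width is capped so the
    weakly identified upper tail is always shrunk.  Returns
    ``(f_prior, dstar_log_prior)`` as (center, width) pairs.
    """
    ok = np.array([fl in (FLAG_OK, FLAG_CLIPPED) for fl in flags])
    vals = theta_lsq[ok]
    vals = vals[vals[:, 3] > 0]
    if len(vals) < 10:  # too few voxels to learn from: weak defaults
        return (0.15, 0.2), (float(np.log(2e-2)), 1.5)
    lds = np.log(vals[:, 3])
    mu = float(np.median(lds))
    sigma = float(np.clip(1.4826 * np.median(np.abs(lds - mu)), 0.3, 1.5))
    fm = float(np.median(vals[:, 2]))
    fw = float(max(0.04, 1.4826 * np.median(np.abs(vals[:, 2] - fm))))
    return (fm, fw), (mu, sigma)


def _bayes_batch(
    signals: np.ndarray,
    scheme: BValueScheme,
    priors: IvimPriors,
    settings: GridSamplerSettings,
    f_prior: tuple[float, float] | None = None,
    dstar_log_prior: tuple[float, float] | None = None,
):
    """Grid-marginalized posterior means/SDs for a (N, nb) signal batch.

    S0 enters linearly, so for each grid node theta=(D, f, D*) the amplitude
    and the noise scale are marginalized in closed form (flat prior on the
    amplitude, Jeffreys on sigma), giving the marginal likelihood

        p(s | theta)  propto  (g.g)^(-1/2) * rss(theta)^(-(nb-1)/2)

    with g the unit-amplitude model vector and rss the profiled residual sum
    of squares.  Posterior moments are trapezoid sums over the grid.

    ``dstar_log_prior``: optional lognormal (mu, sigma) shrinkage prior on D*
    (empirical-Bayes hyperprior learned from stage-1 LSQ fits across voxels).
    With a flat box prior the weakly identified D* posterior mean is strongly
    biased upward; hierarchical shrinkage is the standard remedy and is why
    Bayesian IVIM fitting beats plain least squares on repeatability.  D and f
    keep flat box priors.
    """
    b = scheme.array
    nb = len(b)
    n = signals.shape[0]
    theta0, flags = _lsq_batch(signals, scheme, priors)
    if dstar_log_prior is None and settings.dstar_prior == "empirical" and n >= 10:
        f_prior, dstar_log_prior = _empirical_hyperpriors(theta0, flags)

    est = np.zeros((n, 4))  # S0, D, f, Dstar
    sds = np.zeros((n, 4))
    ok = np.array([fl in (FLAG_OK, FLAG_CLIPPED, FLAG_UNIDENTIFIABLE) for fl in flags])
    est[~ok] = 0.0
    if not ok.any():
        return est, sds, flags

    m = (settings.n_points + 1) // 2
    idx = np.flatnonzero(ok)
    for start in range(0, len(idx), settings.chunk_size):
        sel = idx[start : start + settings.chunk_size]
        s = signals[sel]
        C = len(sel)
        ss = (s**2).sum(axis=1)

        Dg = _axis_grid_geometric(theta0[sel, 1], *priors.D_bounds, settings.span_D, m)
        fg = _axis_grid_linear(theta0[sel, 2], *priors.f_bounds, settings.span_f, m)
        Sg = _axis_grid_geometric(theta0[sel, 3], *priors.Dstar_bounds, settings.span_Dstar, m)
        wD, wf, wS = (_trapezoid_weights(g) for g in (Dg, fg, Sg))
        if dstar_log_prior is not None:
            mu0, s0_ = dstar_log_prior
            wS = wS * np.exp(-((np.log(Sg) - mu0) ** 2) / (2.0 * s0_**2)) / Sg
        if f_prior is not None:
            fm, fw = f_prior
            wf = wf * np.exp(-((fg - fm) ** 2) / (2.0 * fw**2))

        eD = np.exp(-Dg[:, :, None] * b)  # (C, nD, nb)
        eS = np.exp(-Sg[:, :, None] * b)  # (C, nS, nb)
        aD = np.einsum("cdb,cb->cd", eD, s)
        aS = np.einsum("csb,cb->cs", eS, s)
        cDD = (eD**2).sum(axis=2)
        cSS = (eS**2).sum(axis=2)
        cX = np.einsum("cdb,csb->cds", eD, eS)

        f_ = fg[:, None, :, None]  # (C, 1, nf, 1)
        omf = 1.0 - f_
        gs = omf * aD[:, :, None, None] + f_ * aS[:, None, None, :]
        gg = (
            omf**2 * cDD[:, :, None, None]
            + 2.0 * f_ * omf * cX[:, :, None, :]
            + f_**2 * cSS[:, None, None, :]
        )
        amp = gs / gg
        rss = ss[:, None, None, None] - gs * amp
        rss = np.maximum(rss, 1e-30 * ss[:, None, None, None])

        ll = -0.5 * np.log(gg) - 0.5 * (nb - 1) * np.log(rss)
        ll -= ll.max(axis=(1, 2, 3), keepdims=True)
        w = np.exp(ll)
        w *= wD[:, :, None, None] * wf[:, None, :, None] * wS[:, None, None, :]
        norm = w.sum(axis=(1, 2, 3))
        w /= norm[:, None, None, None]

        mD = np.einsum("cdfs,cd->c", w, Dg)
        mf = np.einsum("cdfs,cf->c", w, fg)
        mS = np.einsum("cdfs,cs->c", w, Sg)
        m2D = np.einsum("cdfs,cd->c", w, Dg**2)
        m2f = np.einsum("cdfs,cf->c", w, fg**2)
        m2S = np.einsum("cdfs,cs->c", w, Sg**2)
        mA = (w * amp).sum(axis=(1, 2, 3))
        # conditional amplitude variance sigma^2/gg with sigma^2 ~ rss/(nb-3)
        varA_cond = (w * rss / np.maximum(nb - 3, 1) / gg).sum(axis=(1, 2, 3))
        m2A = (w * amp**2).sum(axis=(1, 2, 3)) + varA_cond

        est[sel, 0] = mA
        est[sel, 1] = mD
        est[sel, 2] = mf
        est[sel, 3] = mS
        sds[sel, 0] = np.sqrt(np.maximum(m2A - mA**2, 0.0))
        sds[sel, 1] = np.sqrt(np.maximum(m2D - mD**2, 0.0))
        sds[sel, 2] = np.sqrt(np.maximum(m2f - mf**2, 0.0))
        sds[sel, 3] = np.sqrt(np.maximum(m2S - mS**2, 0.0))

        # posterior mass piled on a grid edge that coincides with a prior bound
        edge = np.zeros(C, dtype=bool)
        for g_ax, ax, bounds in ((Dg, 1, priors.D_bounds), (Sg, 3, priors.Dstar_bounds)):
            mass_lo = w.take(0, axis=ax).sum(axis=(1, 2))
            mass_hi = w.take(-1, axis=ax).sum(axis=(1, 2))
            at_lo = np.isclose(g_ax[:, 0], bounds[0], rtol=1e-6)
            at_hi = np.isclose(g_ax[:, -1], bounds[1], rtol=1e-6)
            edge |= (mass_lo > settings.edge_mass_warn) & at_lo
            edge |= (mass_hi > settings.edge_mass_warn) & at_hi
        for i, e in zip(sel, edge):
            if e and flags[i] == FLAG_OK:
                flags[i] = FLAG_EDGE

    return est, sds, flags


def fit_signals(
    signals: np.ndarray,
    scheme: BValueScheme,
    method: str = "bayesian",
    priors: IvimPriors | None = None,
    sampler: GridSamplerSettings | None = None,
    seed: int | None = None,
):
    """Batch-fit an (N, n_b) array of voxel signals.

    Returns ``(theta, sds, flags)`` with theta columns (S0, D, f, Dstar).
    The Bayesian path learns its empirical D* hyperprior from this batch
    (disable with ``sampler.dstar_prior == "uniform"``).
    """
    priors = priors or IvimPriors()
    sampler = sampler or GridSamplerSettings()
    signals = np.atleast_2d(np.asarray(signals, dtype=float))
    if method == "lsq":
        theta, flags = _lsq_batch(signals, scheme, priors)
        return theta, np.zeros_like(theta), flags
    if method != "bayesian":
        raise ValueError(f"unknown method {method!r}")
    return _bayes_batch(signals, scheme, priors, sampler)


def fit_voxel_bayesian(
    signal,
    scheme: BValueScheme,
    priors: IvimPriors | None = None,
    sampler: GridSamplerSettings | None = None,
    seed: int | None = None,
) -> IvimEstimate:
    """Bayesian fit of a single voxel by dense-grid marginalization.

    ``seed`` is accepted for interface symmetry with stochastic samplers; the
    grid marginalization is deterministic and does not consume randomness.
    """
    priors = priors or IvimPriors()
    sampler = sampler or GridSamplerSettings()
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or len(signal) != len(scheme):
        raise ValueError("signal must be 1D with one sample per b-value")
    est, sds, flags = _bayes_batch(signal[None, :], scheme, priors, sampler)
    S0, D, f, Ds = est[0]
    sS0, sD, sf, sDs = sds[0]
    return IvimEstimate(
        D=D, f=f, Dstar=Ds, S0=S0, sd_D=sD, sd_f=sf, sd_Dstar=sDs, sd_S0=sS0,
        flag=str(flags[0]), method="bayesian",
    )


def fit_volume(
    dwi: DwiSeries,
    mask: np.ndarray,
    method: str = "bayesian",
    priors: IvimPriors | None = None,
    sampler: GridSamplerSettings | None = None,
    seed: int | None = None,
) -> IvimMaps:
    """Fit every voxel of ``dwi`` inside ``mask``; NaN elsewhere.

    Voxels with non-positive b=0 signal are excluded from ``fit_mask``.  The
    per-voxel fits are independent, so the result does not depend on the order
    in which voxels are visited.
    """
    priors = priors or IvimPriors()
    sampler = sampler or GridSamplerSettings()
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dwi.data.shape[:3]:
        raise ValueError("mask shape does not match the DWI spatial shape")
    if not mask.any():
        raise ValueError("empty mask: nothing to fit")
    if method not in ("bayesian", "lsq"):
        raise ValueError(f"unknown method {method!r}")

    fit_mask = mask & (dwi.data[..., 0] > 0) & np.isfinite(dwi.data).all(axis=-1)
    signals = dwi.data[fit_mask]

    theta, sds, flags = fit_signals(signals, dwi.scheme, method, priors, sampler, seed)

    shape = dwi.data.shape[:3]
    maps = [np.full(shape, np.nan) for _ in range(4)]
    for i, mp in enumerate(maps):
        mp[fit_mask] = theta[:, [1, 2, 3, 0][i]]  # D, f, Dstar, S0

    flag_counts: dict[str, int] = {}
    for fl in flags:
        flag_counts[str(fl)] = flag_counts.get(str(fl), 0) + 1
    flag_counts["excluded_nonpositive_b0"] = int(mask.sum() - fit_mask.sum())

    return IvimMaps(
        D_map=maps[0],
        f_map=maps[1],
        Dstar_map=maps[2],
        S0_map=maps[3],
        fit_mask=fit_mask,
        flags=flag_counts,
        grid=dwi.grid,
    )
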