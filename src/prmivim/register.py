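"""Rigid PET -> MRI registration and grid resampling.

A :class:`RigidTransform` maps *moving*-image world coordinates (mm) into
*fixed*-image world coordinates: ``x_fixed = R (x_moving - c) + c + t`` with
rotation matrix R, rotation center c and translation t.  In this package the
fixed frame is always the IVIM DWI grid and the moving image is the PET SUV
volume, which is resampled once onto the IVIM grid for all voxel-wise
analysis.

Registration is 6-degree-of-freedom, driven by a histogram-based mutual
information metric on a multi-resolution pyramid (SimpleITK).  An externally
supplied transform (4x4 row-major text matrix) is equally accepted, so a
manually registered dataset can enter the pipeline unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .grids import ImageGrid

__all__ = [
    "RigidTransform",
    "RegistrationSettings",
    "RegistrationError",
    "resample",
    "resample_mask",
    "estimate_rigid",
    "transform_difference",
]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid (rotation + translation) world-coordinate mapping.

    ``matrix`` is the homogeneous 4x4 matrix acting on column vectors of
    moving-world mm coordinates; ``convention`` records the direction of the
    mapping for files on disk.
    """

    matrix: np.ndarray
    convention: str = "moving-world->fixed-world,mm"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("rigid transform matrix must be 4x4")
        R = m[:3, :3]
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation block is not orthonormal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation block must have determinant +1 (no reflection)")
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError("last row must be [0, 0, 0, 1]")
        object.__setattr__(self, "matrix", m)

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(4))

    @classmethod
    def from_params(cls, angles_rad, translation_mm, center_mm=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from three extrinsic x-y-z Euler angles, translation and a
        rotation center (all in world mm)."""
        R = Rotation.from_euler("xyz", np.asarray(angles_rad, dtype=float)).as_matrix()
        c = np.asarray(center_mm, dtype=float)
        t = np.asarray(translation_mm, dtype=float)
        m = np.eye(4)
        m[:3, :3] = R
        m[:3, 3] = c + t - R @ c
        return cls(m)

    @classmethod
    def from_text(cls, path) -> "RigidTransform":
        m = np.loadtxt(path)
        return cls(m.reshape(4, 4))

    def to_text(self, path) -> None:
        header = f"rigid transform, row-major homogeneous matrix; {self.convention}"
        np.savetxt(path, self.matrix, fmt="%.17g", header=header)

    # -- algebra ------------------------------------------------------------
    @property
    def rotation(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        """Translation of the origin (t + c - R c folded in)."""
        return self.matrix[:3, 3]

    @property
    def angles(self) -> np.ndarray:
        """Extrinsic x-y-z Euler angles (radians) of the rotation block."""
        return Rotation.from_matrix(self.rotation).as_euler("xyz")

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map (..., 3) world points through the transform."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.matrix[:3, 3]

    def inverse(self) -> "RigidTransform":
        return RigidTransform(np.linalg.inv(self.matrix), convention=self.convention)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Returns the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.matrix @ other.matrix, convention=self.convention)


def transform_difference(a: RigidTransform, b: RigidTransform, point=(0.0, 0.0, 0.0)):
    """(rotation angle in degrees, displacement in mm at ``point``) between
    two rigid transforms — the registration-error measure used in tests."""
    rel = a.compose(b.inverse())
    angle = np.degrees(np.linalg.norm(Rotation.from_matrix(rel.rotation).as_rotvec()))
    disp = np.linalg.norm(a.apply(np.asarray(point, float)) - b.apply(np.asarray(point, float)))
    return float(angle), float(disp)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------


def resample(
    volume: np.ndarray,
    source_grid: ImageGrid,
    transform: RigidTransform,
    target_grid: ImageGrid,
    interpolation: str = "trilinear",
) -> np.ndarray:
    """Resample ``volume`` (on ``source_grid``) onto ``target_grid``.

    ``transform`` maps source-world -> target-world; each target voxel center
    is pulled back through its inverse.  Target voxels that land outside the
    source domain are NaN (the missing code excluded downstream).
    """
    if interpolation not in ("trilinear", "nearest"):
        raise ValueError(f"unknown interpolation {interpolation!r}")
    volume = np.asarray(volume, dtype=float)
    if volume.shape != tuple(source_grid.shape):
        raise ValueError("volume shape does not match source grid")
    if abs(np.linalg.det(transform.rotation)) < 1e-12:
        raise ValueError("singular transform")

    nx, ny, nz = target_grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij"
    )
    tgt_world = target_grid.voxel_to_world(np.stack([ii, jj, kk], axis=-1).reshape(-1, 3))
    src_world = transform.inverse().apply(tgt_world)
    src_vox = source_grid.world_to_voxel(src_world)

    order = 1 if interpolation == "trilinear" else 0
    out = ndimage.map_coordinates(
        volume, src_vox.T, order=order, mode="constant", cval=np.nan
    )
    return out.reshape(target_grid.shape)


def resample_mask(
    mask: np.ndarray,
    source_grid: ImageGrid,
    transform: RigidTransform,
    target_grid: ImageGrid,
) -> np.ndarray:
    """Nearest-neighbour mask resampling; out-of-domain voxels are False."""
    out = resample(
        np.asarray(mask, dtype=float), source_grid, transform, target_grid, "nearest"
    )
    return np.nan_to_num(out, nan=0.0) > 0.5


# ---------------------------------------------------------------------------
# rigid registration (SimpleITK)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegistrationSettings:
    """Mutual-information rigid registration settings.

    Full (non-stochastic) metric sampling keeps the optimization
    deterministic given a fixed initialization.
    """

    histogram_bins: int = 32
    shrink_factors: tuple[int, ...] = (2, 1)
    smoothing_sigmas: tuple[float, ...] = (1.0, 0.0)
    learning_rate: float = 1.0
    min_step: float = 1e-5
    iterations: int = 300


class RegistrationError(RuntimeError):
    """Raised on optimizer failure; carries the best transform seen so far."""

    def __init__(self, message, best_transform=None, metric_trace=None):
        super().__init__(message)
        self.best_transform = best_transform
        self.metric_trace = metric_trace or []


def _to_sitk(volume: np.ndarray, grid: ImageGrid):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume, (2, 1, 0))).astype(np.float64))
    img.SetSpacing(tuple(grid.voxel_size))
    img.SetOrigin(tuple(grid.origin))
    return img


def estimate_rigid(
    moving: np.ndarray,
    moving_grid: ImageGrid,
    fixed: np.ndarray,
    fixed_grid: ImageGrid,
    settings: RegistrationSettings | None = None,
    initial: RigidTransform | None = None,
    moving_mask: np.ndarray | None = None,
) -> RigidTransform:
    """Estimate the 6-DOF transform mapping moving-world -> fixed-world.

    Histogram-based Mattes mutual information (suited to the PET/MRI
    cross-modality problem), multi-resolution coarse-to-fine, geometry-
    centered initialization unless ``initial`` is given.  NaNs in the moving
    image (out-of-FOV padding) are excluded from the metric automatically;
    ``moving_mask`` restricts it further.
    """
    import SimpleITK as sitk

    settings = settings or RegistrationSettings()
    if not np.isfinite(fixed).all():
        raise ValueError("fixed image must be finite")

    valid = np.isfinite(moving)
    if moving_mask is not None:
        valid &= np.asarray(moving_mask, dtype=bool)
    if not valid.any():
        raise ValueError("no valid voxels in the moving image")
    moving = np.nan_to_num(moving, nan=0.0)

    f_img = _to_sitk(fixed, fixed_grid)
    m_img = _to_sitk(moving, moving_grid)

    if initial is None:
        init = sitk.CenteredTransformInitializer(
            f_img, m_img, sitk.Euler3DTransform(),
            sitk.CenteredTransformInitializerFilter.GEOMETRY,
        )
    else:
        # sitk transforms map fixed-world -> moving-world: pass the inverse
        inv = initial.inverse()
        init = sitk.Euler3DTransform()
        init.SetMatrix(tuple(inv.rotation.ravel()))
        init.SetTranslation(tuple(inv.matrix[:3, 3]))

    reg = sitk.ImageRegistrationMethod()
    reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=settings.histogram_bins)
    reg.SetMetricSamplingStrategy(reg.NONE)  # full sampling: deterministic
    if not valid.all():
        # erode so partially interpolated border voxels do not enter the metric
        core = ndimage.binary_erosion(valid, iterations=2)
        mask_img = sitk.Cast(_to_sitk(core.astype(float), moving_grid), sitk.sitkUInt8)
        reg.SetMetricMovingMask(mask_img)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=settings.learning_rate,
        minStep=settings.min_step,
        numberOfIterations=settings.iterations,
        gradientMagnitudeTolerance=1e-8,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    reg.SetShrinkFactorsPerLevel(list(settings.shrink_factors))
    reg.SetSmoothingSigmasPerLevel(list(settings.smoothing_sigmas))
    reg.SmoothingSigmasAreSpecifiedInPhysicalUnitsOn()
    reg.SetInitialTransform(init, inPlace=False)

    trace: list[float] = []
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))

    try:
        result = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # optimizer divergence
        raise RegistrationError(f"registration failed: {exc}", metric_trace=trace) from exc

    if result.GetTransformEnum() == sitk.sitkComposite:
        result = sitk.CompositeTransform(result).GetNthTransform(0)
    euler = sitk.Euler3DTransform(result)
    # build the homogeneous fixed->moving matrix, then invert to our convention
    R = np.asarray(euler.GetMatrix(), dtype=float).reshape(3, 3)
    c = np.asarray(euler.GetCenter(), dtype=float)
    t = np.asarray(euler.GetTranslation(), dtype=float)
    m_f2m = np.eye(4)
    m_f2m[:3, :3] = R
    m_f2m[:3, 3] = c + t - R @ c
    return RigidTransform(np.linalg.inv(m_f2m))
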