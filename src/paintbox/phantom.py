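"""Synthetic digital phantoms and PET reconstruction emulation.

The generator produces the ground truth the planning pipeline is exercised
on: a CT-like relative-density volume (air 0, soft tissue 1, optional bone
1.6), an activity ("SUV") truth map with lesions of known analytic volume,
and emulated reconstructions of that truth under two protocols that differ
in voxel size, effective point-spread blurring and post-filter width —
an EARL-harmonized low-resolution protocol and a high-resolution
scanner-native protocol.

Reconstruction emulation is *effect-level*, not physics-level: Gaussian
blur with FWHM ``sqrt(psf^2 + post_filter^2)`` in world units, resampling
to the protocol grid, then voxel-wise multiplicative Gaussian noise at a
configurable coefficient of variation.  This reproduces the features that
matter downstream — partial-volume dilution of small lesions and
non-scalable SUV differences between protocols — without simulating
sinograms or iterative OSEM.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError
from .grids import GridSpec, ImageVolume, resample

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Shape:
    """An analytic solid: sphere / cylinder (axis z) / ellipsoid.

    ``dims`` is (radius,) for a sphere, (radius, height) for a cylinder and
    (a, b, c) semi-axes for an ellipsoid, all in mm.
    """

    kind: str
    center: tuple[float, float, float]
    dims: tuple[float, ...]

    def __post_init__(self):
        if self.kind not in ("sphere", "cylinder", "ellipsoid"):
            raise ConfigurationError(f"unknown shape kind {self.kind!r}")
        if any(d <= 0 for d in self.dims):
            raise ConfigurationError(f"shape dimensions must be positive, got {self.dims}")
        n = {"sphere": 1, "cylinder": 2, "ellipsoid": 3}[self.kind]
        if len(self.dims) != n:
            raise ConfigurationError(f"{self.kind} takes {n} dimension(s), got {self.dims}")

    @property
    def volume_ml(self) -> float:
        if self.kind == "sphere":
            return 4.0 / 3.0 * math.pi * self.dims[0] ** 3 / 1000.0
        if self.kind == "cylinder":
            r, h = self.dims
            return math.pi * r * r * h / 1000.0
        a, b, c = self.dims
        return 4.0 / 3.0 * math.pi * a * b * c / 1000.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean membership for world points of shape (..., 3)."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        if self.kind == "sphere":
            return (p ** 2).sum(axis=-1) <= self.dims[0] ** 2
        if self.kind == "cylinder":
            r, h = self.dims
            return (p[..., 0] ** 2 + p[..., 1] ** 2 <= r * r) & (np.abs(p[..., 2]) <= h / 2.0)
        a, b, c = self.dims
        return (p[..., 0] / a) ** 2 + (p[..., 1] / b) ** 2 + (p[..., 2] / c) ** 2 <= 1.0

    def rasterize(self, grid: GridSpec) -> np.ndarray:
        """Binary array on ``grid``: voxels whose center lies inside."""
        ax = grid.voxel_centers()
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return self.contains(np.stack([gx, gy, gz], axis=-1))


def sphere_radius_for_ml(volume_ml: float) -> float:
    """Radius (mm) of a sphere with the given volume in ml."""
    return (volume_ml * 1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0)


@dataclass(frozen=True)
class LesionSpec:
    """A lesion: an analytic shape with a uniform activity level (SUV units).

    Heterogeneous uptake is modeled by nesting: ``children`` override the
    host's activity inside their own (smaller) shapes and must lie inside
    the host.
    """

    shape: Shape
    activity: float
    children: tuple["LesionSpec", ...] = ()
    name: str = ""

    def __post_init__(self):
        if self.activity < 0:
            raise ConfigurationError("lesion activity must be >= 0")

    @property
    def volume_ml(self) -> float:
        return self.shape.volume_ml


@dataclass(frozen=True)
class ReconstructionProtocol:
    """PET reconstruction protocol emulated as blur + regrid + noise.

    ``psf_fwhm`` is the effective residual point-spread FWHM after
    reconstruction (larger for OSEM without resolution modeling, smaller for
    PSF reconstruction); ``post_filter_fwhm`` the post-processing Gaussian
    filter width.  ``noise_cv`` is the voxel-wise multiplicative noise
    coefficient of variation.
    """

    name: str
    voxel_size: tuple[float, float, float]
    grid_pixels: int
    psf_fwhm: float
    post_filter_fwhm: float
    noise_cv: float = 0.05

    def __post_init__(self):
        if self.psf_fwhm < 0 or self.post_filter_fwhm < 0:
            raise ConfigurationError("FWHM values must be >= 0")
        if self.noise_cv < 0:
            raise ConfigurationError("noise CV must be >= 0")
        if any(v <= 0 for v in self.voxel_size):
            raise ConfigurationError("voxel size must be positive")

    @property
    def total_fwhm(self) -> float:
        return math.hypot(self.psf_fwhm, self.post_filter_fwhm)


#: EARL-accreditation-style protocol: OSEM3D, 3.2 x 3.2 x 5 mm voxels on a
#: 256 x 256 slice grid, 6 mm post filter; effective residual PSF ~5 mm.
EARL = ReconstructionProtocol("EARL", (3.2, 3.2, 5.0), 256, 5.0, 6.0)

#: Scanner-native high-resolution protocol: PSF reconstruction,
#: 1.6 x 1.6 x 1.5 mm voxels on a 512 x 512 slice grid, 3 mm post filter;
#: residual PSF ~2 mm after resolution modeling.
BIOGRAPH = ReconstructionProtocol("BIOGRAPH", (1.6, 1.6, 1.5), 512, 2.0, 3.0)

PROTOCOLS = {"earl": EARL, "biograph": BIOGRAPH}


@dataclass(frozen=True)
class ResponseModel:
    """Metabolic response applied to a baseline SUV map for follow-up.

    ``factors`` multiplies activity inside each region; ``cleared`` lists
    regions whose activity drops to the background level entirely.
    """

    factors: tuple[tuple[Shape, float], ...] = ()
    cleared: tuple[Shape, ...] = ()
    background: float = 0.0

    def __post_init__(self):
        for _, f in self.factors:
            if f < 0:
                raise ConfigurationError("response factors must be >= 0")


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def make_ct(
    lesions: list[LesionSpec],
    body: Shape,
    grid: GridSpec,
    bones: list[Shape] | None = None,
    tissue_density: float = 1.0,
    bone_density: float = 1.6,
) -> ImageVolume:
    """CT-like relative density: air 0 outside the body outline, soft tissue
    inside, optional bone regions.  Lesions do not alter density (soft
    tissue), but must lie inside the body outline."""
    body_mask = body.rasterize(grid)
    values = np.where(body_mask, tissue_density, 0.0)
    for bone in bones or []:
        values[bone.rasterize(grid)] = bone_density
    for les in lesions:
        inside = les.shape.rasterize(grid)
        if not inside.any() or np.any(inside & ~body_mask):
            raise ConfigurationError(
                f"lesion {les.name or les.shape} extends outside the body outline"
            )
    return ImageVolume(grid=grid, values=values, kind="ct-density")


def make_activity_truth(
    lesions: list[LesionSpec],
    grid: GridSpec,
    background: float = 0.0,
) -> ImageVolume:
    """Ground-truth activity map: background everywhere, lesion activity on
    each lesion's voxels, nested children overriding their hosts.

    Overlapping top-level lesions are a configuration error (ambiguous
    activity); nesting is the supported way to build heterogeneous uptake.
    """
    values = np.full(grid.shape, float(background))
    occupied = np.zeros(grid.shape, dtype=bool)
    for les in lesions:
        mask = les.shape.rasterize(grid)
        if np.any(mask & occupied):
            raise ConfigurationError(
                f"lesion {les.name or les.shape} overlaps a previous non-nested lesion"
            )
        occupied |= mask
        _paint_lesion(values, grid, les, mask)
    return ImageVolume(grid=grid, values=values, kind="suv")


def _paint_lesion(values, grid, les: LesionSpec, mask: np.ndarray | None = None):
    if mask is None:
        mask = les.shape.rasterize(grid)
    values[mask] = les.activity
    for child in les.children:
        child_mask = child.shape.rasterize(grid)
        if np.any(child_mask & ~mask):
            raise ConfigurationError(
                f"nested lesion {child.name or child.shape} extends outside its host"
            )
        _paint_lesion(values, grid, child, child_mask)


# ---------------------------------------------------------------------------
# Reconstruction emulation and follow-up
# ---------------------------------------------------------------------------

def protocol_grid(protocol: ReconstructionProtocol, like: GridSpec) -> GridSpec:
    """Protocol-voxel grid covering the same physical extent as ``like``."""
    lo, hi = like.extent
    sp = np.asarray(protocol.voxel_size)
    shape = np.maximum(1, np.ceil((hi - lo) / sp).astype(int))
    origin = lo + 0.5 * sp
    return GridSpec(shape=tuple(shape), spacing=tuple(sp), origin=tuple(origin))


def emulate_reconstruction(
    truth: ImageVolume,
    protocol: ReconstructionProtocol,
    seed: int | None = None,
    target_grid: GridSpec | None = None,
) -> ImageVolume:
    """Emulate a PET reconstruction of an activity truth map.

    Pipeline, in the order of an actual reconstruction chain: Gaussian blur
    of the residual PSF FWHM applied in world units on the truth grid,
    linear resampling onto the protocol grid (same physical extent as the
    truth unless ``target_grid`` is given), voxel-wise multiplicative
    Gaussian noise ``1 + cv * N(0, 1)`` with the given seed (clipped at 0),
    then the post-processing Gaussian filter — applied last, to the noisy
    image, which is what a reconstruction post-filter does; the surviving
    image noise is therefore correlated at the filter scale.  The total
    resolution blur is FWHM ``sqrt(psf^2 + post_filter^2)``, and noiseless
    emulation conserves total activity for lesions well inside the field of
    view.
    """
    if protocol.psf_fwhm > 0:
        sigma_vox = [protocol.psf_fwhm * _FWHM_TO_SIGMA / s for s in truth.grid.spacing]
        blurred = ndimage.gaussian_filter(truth.values, sigma=sigma_vox, mode="constant")
    else:
        blurred = truth.values.copy()
    vol = ImageVolume(grid=truth.grid, values=blurred, kind="suv")
    grid = target_grid or protocol_grid(protocol, truth.grid)
    if grid != truth.grid:
        vol = resample(vol, grid, "linear")
    values = vol.values
    if protocol.noise_cv > 0:
        rng = np.random.default_rng(seed)
        values = values * (1.0 + protocol.noise_cv * rng.standard_normal(values.shape))
        values = np.clip(values, 0.0, None)
    if protocol.post_filter_fwhm > 0:
        sigma_vox = [protocol.post_filter_fwhm * _FWHM_TO_SIGMA / s for s in grid.spacing]
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="constant")
    return ImageVolume(grid=grid, values=values, kind="suv")


def follow_up_suv(
    baseline: ImageVolume,
    response: ResponseModel,
    seed: int | None = None,
    noise_cv: float = 0.0,
) -> ImageVolume:
    """Apply a metabolic response model to a baseline SUV map.

    The grid is unchanged (no morphological changes are modeled).  Regions
    in ``response.cleared`` drop to the background level; ``factors``
    multiply the activity inside their regions.  Optional fresh
    multiplicative noise (``noise_cv`` > 0) uses ``seed``.
    """
    values = baseline.values.copy()
    for shape, factor in response.factors:
        values[shape.rasterize(baseline.grid)] *= factor
    for shape in response.cleared:
        values[shape.rasterize(baseline.grid)] = response.background
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        values = np.clip(values * (1.0 + noise_cv * rng.standard_normal(values.shape)), 0, None)
    return ImageVolume(grid=baseline.grid, values=values, kind="suv")


def world_integral(vol: ImageVolume) -> float:
    """Integral of the field over world volume (value x mm^3)."""
    return float(vol.values.sum() * vol.grid.voxel_volume_mm3)


# ---------------------------------------------------------------------------
# Stock phantoms
# ---------------------------------------------------------------------------

def tube_phantom(grid: GridSpec | None = None):
    """Known-volume tube phantom for the co-registration study.

    Three references: a 0.3 ml sphere (V1), a second 0.3 ml sphere (V2)
    nested inside a 2.0 ml cylinder (V3) to mimic a heterogeneous-uptake
    lesion.  Returns ``(truth_suv, truth_masks, lesions)`` where the mask
    list is [V1, V2, V3, V2+V3] with V3 measured as the full host cylinder.
    """
    if grid is None:
        grid = GridSpec(shape=(90, 90, 60), spacing=(1.0, 1.0, 1.0), origin=(-44.5, -44.5, -29.5))
    r03 = sphere_radius_for_ml(0.3)  # ~4.153 mm
    v1 = LesionSpec(Shape("sphere", (-20.0, -15.0, 5.0), (r03,)), activity=8.0, name="V1")
    v2_shape = Shape("sphere", (18.0, 12.0, 0.0), (r03,))
    # cylinder r=7 mm, h=13 mm -> pi*49*13 = 2.001 ml
    v3_shape = Shape("cylinder", (18.0, 12.0, 0.0), (7.0, 13.0))
    v3 = LesionSpec(
        v3_shape, activity=2.0, children=(LesionSpec(v2_shape, activity=8.0, name="V2"),),
        name="V3",
    )
    truth = make_activity_truth([v1, v3], grid)
    masks = [
        ImageVolume(grid, v1.shape.rasterize(grid).astype(float), "mask"),
        ImageVolume(grid, v2_shape.rasterize(grid).astype(float), "mask"),
        ImageVolume(grid, v3_shape.rasterize(grid).astype(float), "mask"),
        ImageVolume(grid, v3_shape.rasterize(grid).astype(float), "mask"),  # V2+V3 union = host
    ]
    return truth, masks, [v1, v3]


def hn_phantom():
    """Default head-and-neck-like planning phantom.

    Three separate lesions with heterogeneous uptake (higher-activity cores)
    inside a cylindrical soft-tissue body, plus a posterior cord-like OAR.
    Returns a dict with the truth grid/activity, body and OAR shapes, lesion
    specs and the default dose grid.
    """
    truth_grid = GridSpec(shape=(120, 120, 90), spacing=(1.0, 1.0, 1.0),
                          origin=(-59.5, -59.5, -44.5))
    body = Shape("cylinder", (0.0, 0.0, 0.0), (52.0, 86.0))
    cord = Shape("cylinder", (0.0, 38.0, 0.0), (5.0, 86.0))
    lesions = [
        LesionSpec(
            Shape("sphere", (-16.0, 8.0, 6.0), (11.0,)), activity=6.0,
            children=(LesionSpec(Shape("sphere", (-14.0, 10.0, 8.0), (5.5,)), activity=10.0),),
            name="L1",
        ),
        LesionSpec(
            Shape("sphere", (18.0, 14.0, -8.0), (9.0,)), activity=5.5,
            children=(LesionSpec(Shape("sphere", (19.0, 13.0, -7.0), (4.0,)), activity=9.0),),
            name="L2",
        ),
        LesionSpec(
            Shape("ellipsoid", (0.0, -18.0, -4.0), (8.0, 7.0, 10.0)), activity=7.0,
            children=(LesionSpec(Shape("sphere", (0.0, -18.0, -4.0), (3.5,)), activity=11.0),),
            name="L3",
        ),
    ]
    ct_grid = GridSpec(shape=(79, 79, 60), spacing=(1.52, 1.52, 1.5),
                       origin=(-59.28, -59.28, -44.25))
    dose_grid = GridSpec(shape=(60, 60, 45), spacing=(2.0, 2.0, 2.0),
                         origin=(-59.0, -59.0, -44.0))
    truth = make_activity_truth(lesions, truth_grid)
    return {
        "truth": truth,
        "truth_grid": truth_grid,
        "body": body,
        "oar_shapes": {"cord": cord},
        "lesions": lesions,
        "ct_grid": ct_grid,
        "dose_grid": dose_grid,
    }
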