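"""SUV segmentation and voxel-wise dose prescription maps.

Dose painting by numbers (DPBN) prescribes a dose to every target voxel as
a linear function of its SUV; dose painting by contour (DPBC) thresholds
the target into nested subvolumes (BTVs) and prescribes a uniform dose per
subvolume.  Both produce a :class:`PrescriptionMap` — per-voxel prescribed
dose with floor/ceiling bounds and multiplicative similarity factors — and
any number of maps can be stacked into a :class:`RobustPrescription` whose
constraints are enforced simultaneously by the LP optimizer, which is how
a single plan is made robust to two reconstruction protocols or to the
DPBN/DPBC discretization choice.

The linear DPBN mapping uses min-max normalization of SUV over the target
mask with configurable endpoints, default 70 Gy at the minimum-SUV voxel
rising to 82 Gy at the maximum-SUV voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, EmptySegmentationError
from .grids import GridSpec, ImageVolume, resample

#: default multiplicative similarity factors (Delta_min, Delta_max): a
#: +/-3% robust band around each per-voxel prescription
DEFAULT_DELTA = (0.97, 1.03)

#: default DPBN endpoints (Gy): base prescription and escalation ceiling
DEFAULT_D_LOW = 70.0
DEFAULT_D_HIGH = 82.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class SegmentationResult:
    """Threshold segmentation of an SUV map."""

    mask: ImageVolume
    threshold: float  # absolute SUV units
    component_count: int


@dataclass
class PrescriptionMap:
    """Per-voxel dose prescription on a grid.

    ``dose``/``d_min``/``d_max`` are full-grid arrays, zero off-target.
    ``delta`` = (Delta_min, Delta_max) multiplicative similarity factors; in
    the LP the enforced band is [d_min * Delta_min, d_max * Delta_max].
    ``btv_masks`` (DPBC only) keeps the nested subvolume masks for CI/DVH
    evaluation.
    """

    grid: GridSpec
    target_mask: ImageVolume
    dose: ImageVolume
    d_min: np.ndarray
    d_max: np.ndarray
    delta: tuple[float, float] = DEFAULT_DELTA
    label: str = "dpbn"
    source: str = ""
    btv_masks: list[ImageVolume] = field(default_factory=list)

    def __post_init__(self):
        if self.label not in ("dpbn", "dpbc"):
            raise ConfigurationError(f"prescription label must be dpbn|dpbc, got {self.label!r}")
        dmin, dmax = self.delta
        if not (0 < dmin < 2 and 0 < dmax < 2):
            raise ConfigurationError(f"similarity factors must lie in (0, 2), got {self.delta}")
        m = self.target_mask.values > 0
        if np.any(self.d_min[m] > self.dose.values[m]) or np.any(
            self.dose.values[m] > self.d_max[m]
        ):
            raise ConfigurationError("require d_min <= dose <= d_max on target voxels")

    @property
    def target_indices(self) -> np.ndarray:
        return self.target_mask.mask_indices


@dataclass
class OARConstraint:
    """Organ-at-risk maximum-dose cap."""

    mask: ImageVolume
    cap_gy: float
    name: str = "oar"

    def __post_init__(self):
        if self.cap_gy <= 0:
            raise ConfigurationError("OAR dose cap must be positive")


@dataclass
class RobustPrescription:
    """One or more prescription maps plus OAR caps, all on the dose grid.

    A voxel belonging to k maps' targets carries k (floor, ceiling)
    constraint pairs, enforced simultaneously.  ``n_target`` is the
    union-of-targets voxel count, ``n_total`` the total constrained voxel
    count (union plus OAR voxels outside the union).
    """

    grid: GridSpec
    maps: list[PrescriptionMap]
    oars: list[OARConstraint] = field(default_factory=list)

    def __post_init__(self):
        if not self.maps:
            raise ConfigurationError("a RobustPrescription needs at least one map")
        union = np.zeros(self.grid.shape, dtype=bool)
        for m in self.maps:
            if m.grid != self.grid:
                raise ConfigurationError("all maps must live on the dose grid")
            union |= m.target_mask.values > 0
        if not union.any():
            raise ConfigurationError("union of target masks is empty")
        self._union = union

    @property
    def target_union(self) -> ImageVolume:
        return ImageVolume(self.grid, self._union.astype(float), "mask")

    @property
    def n_target(self) -> int:
        return int(self._union.sum())

    @property
    def n_total(self) -> int:
        extra = np.zeros(self.grid.shape, dtype=bool)
        for oar in self.oars:
            extra |= oar.mask.values > 0
        return int((self._union | extra).sum())


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def segment_suv(
    suv: ImageVolume,
    threshold_fraction: float = 0.4,
    min_component_voxels: int = 1,
) -> SegmentationResult:
    """Threshold segmentation at a fraction of the maximum SUV.

    Voxels with SUV >= fraction * max(SUV) are kept; 26-connected components
    smaller than ``min_component_voxels`` are removed.  This is a declared
    simplification of cluster-based semi-automatic segmentation: it keeps
    the multifocal structure (every component above threshold survives) but
    not the diffuse-boundary handling.
    """
    if not (0 < threshold_fraction < 1):
        raise ConfigurationError("threshold fraction must lie in (0, 1)")
    vmax = float(suv.values.max())
    if vmax <= 0:
        raise EmptySegmentationError("SUV map is all zero; nothing to segment")
    thr = threshold_fraction * vmax
    mask = suv.values >= thr
    labels, nlab = ndimage.label(mask, structure=_CONN26)
    if min_component_voxels > 1 and nlab:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_component_voxels)
        mask &= ~np.isin(labels, small[small > 0])
        labels, nlab = ndimage.label(mask, structure=_CONN26)
    return SegmentationResult(
        mask=ImageVolume(suv.grid, mask.astype(float), "mask"),
        threshold=thr,
        component_count=int(nlab),
    )


def dpbn_map(
    suv: ImageVolume,
    mask: ImageVolume,
    d_low: float = DEFAULT_D_LOW,
    d_high: float = DEFAULT_D_HIGH,
    delta: tuple[float, float] = DEFAULT_DELTA,
    source: str = "",
) -> PrescriptionMap:
    """Linear SUV -> dose prescription over the target mask.

    ``D_i = d_low + (SUV_i - SUV_min) / (SUV_max - SUV_min) * (d_high -
    d_low)`` with SUV extrema taken over the mask; a constant-SUV target
    receives ``d_low`` everywhere.  Floors and ceilings equal the
    prescription itself (the robust band comes from the similarity factors).
    """
    if d_high < d_low:
        raise ConfigurationError(f"d_high ({d_high}) must be >= d_low ({d_low})")
    if d_low <= 0:
        raise ConfigurationError("d_low must be positive")
    m = mask.values > 0
    if not m.any():
        raise ConfigurationError("target mask is empty")
    s = suv.values[m]
    smin, smax = float(s.min()), float(s.max())
    dose = np.zeros(suv.grid.shape)
    if smax > smin:
        dose[m] = d_low + (suv.values[m] - smin) / (smax - smin) * (d_high - d_low)
    else:
        dose[m] = d_low
    return PrescriptionMap(
        grid=suv.grid,
        target_mask=mask,
        dose=ImageVolume(suv.grid, dose, "dose-Gy"),
        d_min=dose.copy(),
        d_max=dose.copy(),
        delta=tuple(delta),
        label="dpbn",
        source=source,
    )


def dpbc_map(
    suv: ImageVolume,
    mask: ImageVolume,
    level_fractions: list[float],
    level_doses: list[float] | None = None,
    delta: tuple[float, float] = DEFAULT_DELTA,
    d_low: float = DEFAULT_D_LOW,
    d_high: float = DEFAULT_D_HIGH,
    source: str = "",
) -> PrescriptionMap:
    """Contour-based (piecewise-constant) prescription over nested BTVs.

    ``BTV_k`` = target voxels with SUV >= fraction_k * max SUV (fractions
    ascending, so the BTVs are nested by construction); each voxel receives
    the dose of the innermost subvolume containing it.  When ``level_doses``
    is omitted, each level's dose defaults to the DPBN dose at its threshold
    SUV, which makes DPBN/DPBC/hybrid comparisons internally consistent.
    """
    fr = list(level_fractions)
    if any(not 0 < f <= 1 for f in fr) or sorted(fr) != fr:
        raise ConfigurationError("level fractions must be ascending within (0, 1]")
    m = mask.values > 0
    if not m.any():
        raise ConfigurationError("target mask is empty")
    s = suv.values[m]
    smin, smax = float(s.min()), float(s.max())
    if level_doses is None:
        if smax > smin:
            level_doses = [
                max(d_low, d_low + (f * smax - smin) / (smax - smin) * (d_high - d_low))
                for f in fr
            ]
        else:
            level_doses = [d_low for _ in fr]
    if len(level_doses) != len(fr):
        raise ConfigurationError("level_doses and level_fractions must have equal length")
    if sorted(level_doses) != list(level_doses):
        raise ConfigurationError("level doses must ascend with level fractions")

    dose = np.zeros(suv.grid.shape)
    btvs = []
    for f, d in zip(fr, level_doses):  # ascending: inner levels overwrite
        btv = m & (suv.values >= f * smax)
        dose[btv] = d
        btvs.append(ImageVolume(suv.grid, btv.astype(float), "mask"))
    covered = dose > 0
    target = ImageVolume(suv.grid, covered.astype(float), "mask")
    return PrescriptionMap(
        grid=suv.grid,
        target_mask=target,
        dose=ImageVolume(suv.grid, dose, "dose-Gy"),
        d_min=dose.copy(),
        d_max=dose.copy(),
        delta=tuple(delta),
        label="dpbc",
        source=source,
        btv_masks=btvs,
    )


def combine_robust(
    maps: list[PrescriptionMap],
    oars: list[OARConstraint],
    dose_grid: GridSpec,
    method: str = "nearest",
) -> RobustPrescription:
    """Stack prescription maps (and OAR caps) onto the dose grid.

    Every map is resampled to the dose grid — nearest-neighbor by default,
    the interpolation the co-registration study selects for the final
    regridding stage — and its constraints are kept as an independent
    (floor, ceiling) pair per voxel.  OAR voxels overlapping the target
    union are excluded from the OAR cap set (target priority).
    """
    if not maps:
        raise ConfigurationError("need at least one prescription map")
    remapped = [resample_prescription(m, dose_grid, method) for m in maps]
    rp = RobustPrescription(grid=dose_grid, maps=remapped, oars=[])
    union = rp._union
    kept_oars = []
    for oar in oars:
        mask = oar.mask
        if mask.grid != dose_grid:
            mask = resample(mask, dose_grid, "nearest")
        vals = (mask.values > 0) & ~union
        if vals.any():
            kept_oars.append(
                OARConstraint(ImageVolume(dose_grid, vals.astype(float), "mask"),
                              oar.cap_gy, oar.name)
            )
    rp.oars = kept_oars
    return rp


def resample_prescription(
    pmap: PrescriptionMap, dose_grid: GridSpec, method: str = "nearest"
) -> PrescriptionMap:
    """Move a prescription map onto another grid (mask always nearest)."""
    if pmap.grid == dose_grid:
        return pmap
    mask = resample(pmap.target_mask, dose_grid, "nearest")
    if not (mask.values > 0).any():
        raise ConfigurationError("target mask vanished when resampled to the dose grid")

    def _re(arr):
        vol = ImageVolume(pmap.grid, arr, "dose-Gy")
        out = resample(vol, dose_grid, method).values
        return np.where(mask.values > 0, out, 0.0)

    dose = _re(pmap.dose.values)
    d_min = _re(pmap.d_min)
    d_max = _re(pmap.d_max)
    m = mask.values > 0
    if np.any(dose[m] <= 0):  # off-target fill leaked in: tighten mask
        keep = m & (dose > 0)
        if not keep.any():
            raise ConfigurationError("resampled prescription has no positive dose")
        mask = ImageVolume(dose_grid, keep.astype(float), "mask")
        dose = np.where(keep, dose, 0.0)
        d_min = np.where(keep, d_min, 0.0)
        d_max = np.where(keep, d_max, 0.0)
    btvs = [resample(b, dose_grid, "nearest") for b in pmap.btv_masks]
    return PrescriptionMap(
        grid=dose_grid,
        target_mask=mask,
        dose=ImageVolume(dose_grid, dose, "dose-Gy"),
        d_min=d_min,
        d_max=d_max,
        delta=pmap.delta,
        label=pmap.label,
        source=pmap.source,
        btv_masks=btvs,
    )
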