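"""Voxel grids, image volumes, I/O and resampling.

The data model is deliberately minimal: a :class:`GridSpec` describes an
axis-aligned voxel lattice in world (mm) coordinates and an
:class:`ImageVolume` attaches a scalar field to it.  The same container
carries CT density, SUV, dose, binary masks and Q-index maps; ``kind``
records which, and a couple of invariants (non-negative dose/SUV, binary
masks) are enforced at construction.

Coordinate convention
---------------------
Voxel indices are 0-based with axis order ``(x, y, z)``; the world
coordinate of the *center* of voxel ``(i, j, k)`` is
``origin + (i, j, k) * spacing``.  All resampling is performed in world
space through this mapping, so volumes on different grids (PET, CT, dose
calculation) can be moved onto a common lattice without any registration
step — the synthetic phantoms are intrinsically co-registered, mirroring
hardware-fused PET/CT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, MetadataError, PaintboxError

logger = logging.getLogger("paintbox.grids")

#: scalar-field kinds an ImageVolume may carry
KINDS = ("ct-density", "suv", "dose-Gy", "mask", "q-index")

#: interpolation methods accepted by :func:`resample`
INTERP_ORDERS = {"nearest": 0, "linear": 1, "cubic-spline": 3}


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned voxel lattice: shape, spacing (mm) and origin (mm).

    ``origin`` is the world position of the center of voxel ``(0, 0, 0)``.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(s) for s in self.origin))
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise MetadataError(f"grid shape must be 3 positive integers, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise MetadataError(f"grid spacing must be 3 positive reals, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def extent(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical extent (mm) as ``(lower, upper)`` corners including the
        half-voxel margin around edge voxel centers."""
        o = np.asarray(self.origin)
        sp = np.asarray(self.spacing)
        n = np.asarray(self.shape)
        return o - 0.5 * sp, o + (n - 0.5) * sp

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis 1-D arrays of voxel-center world coordinates."""
        return tuple(
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)
        )

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world points ``(..., 3)`` to fractional voxel indices."""
        pts = np.asarray(points, dtype=float)
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        idx = np.asarray(indices, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)


@dataclass
class ImageVolume:
    """A scalar field on a :class:`GridSpec`.

    ``kind`` tags the physical meaning; masks must be binary and dose/SUV
    non-negative (checked at construction).
    """

    grid: GridSpec
    values: np.ndarray
    kind: str = "suv"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise MetadataError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )
        if self.kind not in KINDS:
            raise MetadataError(f"unknown volume kind {self.kind!r}; expected one of {KINDS}")
        if self.kind == "mask":
            if not np.isin(self.values, (0.0, 1.0)).all():
                raise MetadataError("mask volumes must contain only 0/1 values")
        elif self.kind in ("suv", "dose-Gy"):
            if np.any(self.values < 0):
                raise MetadataError(f"{self.kind} volumes must be non-negative")

    def copy_with(self, **changes) -> "ImageVolume":
        return replace(self, **changes)

    @property
    def mask_indices(self) -> np.ndarray:
        """Flat indices (C order) of non-zero voxels — handy for masks."""
        return np.flatnonzero(self.values)


# ---------------------------------------------------------------------------
# I/O — NIfTI-1 via nibabel, plus a native .npz container
# ---------------------------------------------------------------------------

def write_volume(vol: ImageVolume, path, format: str | None = None) -> None:
    """Write a volume as NIfTI-1 (``.nii``/``.nii.gz``) or the native ``.npz``
    container (values + spacing + origin + kind, bit-exact round trip)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "container":
        np.savez_compressed(
            path,
            values=vol.values,
            spacing=np.asarray(vol.grid.spacing),
            origin=np.asarray(vol.grid.origin),
            kind=np.asarray(vol.kind),
        )
    elif fmt == "nifti":
        import nibabel as nib

        affine = np.diag(list(vol.grid.spacing) + [1.0])
        affine[:3, 3] = vol.grid.origin
        img = nib.Nifti1Image(vol.values.astype(np.float64), affine)
        img.header["descrip"] = vol.kind.encode()
        nib.save(img, str(path))
    else:
        raise FormatError(f"unknown volume format {fmt!r}")


def read_volume(path, format: str | None = None, kind: str | None = None) -> ImageVolume:
    """Read a volume written by :func:`write_volume`.

    ``kind`` overrides the kind recorded in the file (NIfTI keeps it in the
    ``descrip`` header field, the container stores it explicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    fmt = format or _infer_format(path)
    if fmt == "container":
        try:
            with np.load(path, allow_pickle=False) as z:
                values = z["values"]
                spacing = tuple(z["spacing"])
                origin = tuple(z["origin"])
                file_kind = str(z["kind"])
        except Exception as exc:  # zipfile/keys errors
            raise FormatError(f"cannot parse container {path}: {exc}") from exc
    elif fmt == "nifti":
        import nibabel as nib

        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise FormatError(f"cannot parse NIfTI {path}: {exc}") from exc
        affine = img.affine
        # NIfTI-1 stores the affine in float32; strip representation noise
        spacing = tuple(round(float(affine[a, a]), 6) for a in range(3))
        origin = tuple(round(float(affine[a, 3]), 6) for a in range(3))
        values = np.asanyarray(img.dataobj, dtype=float)
        descrip = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="ignore")
        file_kind = descrip if descrip in KINDS else "suv"
    else:
        raise FormatError(f"unknown volume format {fmt!r}")
    if any(s <= 0 for s in spacing):
        raise MetadataError(f"{path}: non-positive spacing {spacing}")
    grid = GridSpec(shape=values.shape, spacing=spacing, origin=origin)
    return ImageVolume(grid=grid, values=values, kind=kind or file_kind)


def _infer_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith(".npz"):
        return "container"
    raise FormatError(f"cannot infer volume format from {path.name!r}")


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

def resample(vol: ImageVolume, target: GridSpec, method: str = "linear") -> ImageVolume:
    """Resample a volume onto ``target`` by sampling at the world coordinates
    of the target voxel centers.

    Methods: ``nearest``, ``linear``, ``cubic-spline`` (mirror boundary for
    the spline prefilter).  Points outside the source voxel-center hull take
    the fill value 0.  Masks must use ``nearest`` so the output stays binary.
    """
    if method not in INTERP_ORDERS:
        raise PaintboxError(
            f"unknown interpolation method {method!r}; expected one of {sorted(INTERP_ORDERS)}"
        )
    lo_s, hi_s = vol.grid.extent
    lo_t, hi_t = target.extent
    if np.any(hi_t <= lo_s) or np.any(lo_t >= hi_s):
        raise PaintboxError("source and target grids have disjoint physical extents")
    if vol.kind == "mask" and method != "nearest":
        raise PaintboxError("masks must be resampled with method='nearest' to stay binary")

    axes = target.voxel_centers()
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1)
    idx = vol.grid.world_to_index(pts)  # fractional source indices, (..., 3)
    # snap indices that are integer up to round-off so interpolants stay
    # exact at the nodes even for spacings with no exact binary form
    nearest_int = np.round(idx)
    idx = np.where(np.abs(idx - nearest_int) < 1e-9, nearest_int, idx)

    order = INTERP_ORDERS[method]
    coords = np.moveaxis(idx, -1, 0)
    out = ndimage.map_coordinates(vol.values, coords, order=order, mode="mirror")
    # outside the source voxel-center hull: declared fill value 0
    n = np.asarray(vol.grid.shape)
    inside = np.all((idx >= 0) & (idx <= n - 1), axis=-1)
    out = np.where(inside, out, 0.0)
    if vol.kind in ("suv", "dose-Gy"):
        out = np.clip(out, 0.0, None)  # spline overshoot must not break invariants
    return ImageVolume(grid=target, values=out, kind=vol.kind)


def measure_volume(mask: ImageVolume) -> float:
    """Volume of a binary mask in milliliters: 1-voxel count x voxel volume."""
    if mask.kind != "mask":
        raise PaintboxError(f"measure_volume expects a mask, got kind {mask.kind!r}")
    return float(mask.values.sum() * mask.grid.voxel_volume_mm3 / 1000.0)


# ---------------------------------------------------------------------------
# Co-registration interpolation-chain study
# ---------------------------------------------------------------------------

_STAGE1 = "PET->CT"
_STAGE2 = "CT->Dose"


def coregistration_chain_study(
    truth_masks: Sequence[ImageVolume],
    suv: ImageVolume,
    ct_grid: GridSpec,
    dose_grid: GridSpec,
    segment_fn: Callable[[ImageVolume, int], ImageVolume],
    methods: Sequence[str] = ("linear", "nearest", "cubic-spline"),
    lesion_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Two-stage interpolation study: PET grid -> CT grid -> dose grid.

    For every first-stage method the SUV map is resampled to the CT grid and
    segmented (``segment_fn(suv_volume, lesion_index) -> mask``, one call per
    reference lesion); measured volumes and percent deviations from the known
    truth volumes are recorded.  The CT-grid SUV is then resampled to the dose
    grid with every second-stage method and re-measured, yielding
    ``len(methods)**2`` second-stage rows.

    An empty segmentation at any stage is reported as a -100% deviation,
    never raised.  Segmentation operates on the resampled SUV itself (not on
    interpolated binary masks).
    """
    names = list(lesion_names or [f"L{i + 1}" for i in range(len(truth_masks))])
    truths = [measure_volume(m) for m in truth_masks]
    rows = []
    for m1 in methods:
        suv_ct = resample(suv, ct_grid, m1)
        vols1 = _measure_lesions(suv_ct, truth_masks, segment_fn)
        rows.append(_study_row(_STAGE1, m1, "", names, vols1, truths))
        for m2 in methods:
            suv_dose = resample(suv_ct, dose_grid, m2)
            vols2 = _measure_lesions(suv_dose, truth_masks, segment_fn)
            rows.append(_study_row(_STAGE2, m1, m2, names, vols2, truths))
    return pd.DataFrame(rows)


def _measure_lesions(suv_stage, truth_masks, segment_fn) -> list[float]:
    """Per-lesion measured volume: the connected components of the lesion's
    segmentation that overlap the (nearest-resampled) truth mask."""
    struct = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    vols = []
    for k, truth in enumerate(truth_masks):
        seg = segment_fn(suv_stage, k)
        labels, nlab = ndimage.label(seg.values > 0, structure=struct)
        if nlab == 0:
            vols.append(0.0)
            continue
        truth_here = resample(truth, suv_stage.grid, "nearest")
        hit = np.unique(labels[(truth_here.values > 0) & (labels > 0)])
        if hit.size == 0:
            vols.append(0.0)
            continue
        count = int(np.isin(labels, hit).sum())
        vols.append(count * suv_stage.grid.voxel_volume_mm3 / 1000.0)
    return vols


def _study_row(stage, m1, m2, names, measured, truths) -> dict:
    row = {"stage": stage, "method1": m1, "method2": m2}
    for name, v, t in zip(names, measured, truths):
        row[f"{name}_ml"] = v
        row[f"{name}_truth_ml"] = t
        row[f"{name}_pct"] = 100.0 * (v / t - 1.0) if t > 0 else np.nan
    return row


def deviation_table_consistent(table: pd.DataFrame, atol: float = 1e-9) -> bool:
    """Check that every percent column recomputes from its measured/truth
    columns: pct = 100 * (measured - truth) / truth."""
    names = sorted({c[:-3] for c in table.columns if c.endswith("_ml") and "truth" not in c})
    for name in names:
        expect = 100.0 * (table[f"{name}_ml"] / table[f"{name}_truth_ml"] - 1.0)
        if not np.allclose(table[f"{name}_pct"], expect, atol=atol, equal_nan=True):
            return False
    return True
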