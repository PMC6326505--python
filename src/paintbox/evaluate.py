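"""Plan-quality evaluation and adaptive replanning.

Voxel-wise prescriptions have no single target dose, so plan quality is
judged through the quality index Q — planned dose divided by prescribed
dose per voxel, ideal value 1 — summarized as a cumulative histogram
(QVH), a quality factor QF (mean absolute deviation of Q from 1 over
target voxels, in percent) and the fraction of target voxels with Q
strictly inside a tolerance band around 1 (the usual clinical criterion is
90% within 5%).  Volume-based evaluation (DVH, conformity index, isodose
masks) is kept alongside so contour-style plans can be judged the
traditional way.

Adaptive replanning re-runs the weight LP over the prior aperture pool
extended with a few new shapes generated from the follow-up prescription;
total-course dose is accumulated voxel-by-voxel with fraction weights
(rigid geometry — no deformable registration is modeled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import (Aperture, BeamGeometry, DoseInfluenceMatrix, PencilBeamEngine,
                    apertures_close, biomap_apertures, build_influence_matrix,
                    prescription_bands)
from .errors import ConfigurationError, PaintboxError
from .grids import ImageVolume
from .optimize import LPConfig, LPSolution, plan as lp_plan
from .prescription import PrescriptionMap, RobustPrescription

import scipy.sparse as sparse


# ---------------------------------------------------------------------------
# Quality index machinery
# ---------------------------------------------------------------------------

def q_map(dose: ImageVolume, rx: PrescriptionMap) -> ImageVolume:
    """Quality index Q_i = dose_i / D_i on target voxels, NaN elsewhere."""
    if dose.grid != rx.grid:
        raise PaintboxError("dose and prescription must share a grid")
    m = rx.target_mask.values > 0
    d_rx = rx.dose.values
    if np.any(d_rx[m] <= 0):
        raise PaintboxError("prescribed dose must be positive on every target voxel")
    q = np.full(dose.grid.shape, np.nan)
    q[m] = dose.values[m] / d_rx[m]
    return ImageVolume(dose.grid, q, "q-index")


def _q_values(qmap: ImageVolume, mask: ImageVolume) -> np.ndarray:
    m = mask.values > 0
    if not m.any():
        raise PaintboxError("empty mask")
    q = qmap.values[m]
    q = q[~np.isnan(q)]
    if q.size == 0:
        raise PaintboxError("no defined Q values inside the mask")
    return q


def qvh(qmap: ImageVolume, mask: ImageVolume, bin_width: float = 0.01
        ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative Q histogram: percent of target voxels with Q >= q per bin.
    Starts at 100%."""
    q = _q_values(qmap, mask)
    edges = np.arange(0.0, q.max() + 2 * bin_width, bin_width)
    pct = 100.0 * (q[None, :] >= edges[:, None]).mean(axis=1)
    return edges, pct


def qf(qmap: ImageVolume, mask: ImageVolume) -> float:
    """Quality factor: 100 x mean |Q - 1| over target voxels (percent)."""
    q = _q_values(qmap, mask)
    return float(100.0 * np.abs(q - 1.0).mean())


def fraction_within(qmap: ImageVolume, mask: ImageVolume, tol: float) -> float:
    """Percent of target voxels with 1 - tol < Q < 1 + tol (strict)."""
    q = _q_values(qmap, mask)
    return float(100.0 * ((q > 1.0 - tol) & (q < 1.0 + tol)).mean())


def dvh(dose: ImageVolume, mask: ImageVolume, bin_width: float = 0.1
        ) -> tuple[np.ndarray, np.ndarray]:
    """Cumulative DVH: percent of structure volume receiving >= d per bin."""
    m = mask.values > 0
    if not m.any():
        raise PaintboxError("empty mask")
    d = dose.values[m]
    edges = np.arange(0.0, d.max() + 2 * bin_width, bin_width)
    pct = 100.0 * (d[None, :] >= edges[:, None]).mean(axis=1)
    return edges, pct


def conformity_index(dose: ImageVolume, rx: PrescriptionMap,
                     structure_mask: ImageVolume, ref_fraction: float = 0.95) -> float:
    """Target coverage by the reference isodose, in percent: the fraction of
    structure voxels receiving at least ``ref_fraction`` of their own
    prescribed dose.  For heterogeneous prescriptions the threshold is
    applied per voxel."""
    m = structure_mask.values > 0
    if not m.any():
        raise PaintboxError("empty structure mask")
    d_rx = rx.dose.values[m]
    if np.any(d_rx <= 0):
        raise PaintboxError("structure extends outside the prescribed target")
    covered = dose.values[m] >= ref_fraction * d_rx
    return float(100.0 * covered.mean())


def isodose_mask(dose: ImageVolume, level_percent: float,
                 reference_dose: float) -> ImageVolume:
    """Voxels receiving at least ``level_percent`` % of ``reference_dose``
    (conventionally the minimum prescription, 70 Gy)."""
    mask = dose.values >= level_percent / 100.0 * reference_dose
    return ImageVolume(dose.grid, mask.astype(float), "mask")


@dataclass
class QualityReport:
    """Bundle of the plan-quality metrics for one prescription map."""

    qmap: ImageVolume
    qvh_bins: np.ndarray
    qvh_pct: np.ndarray
    qf_pct: float
    within: dict[int, float]            # {3: %, 4: %, 5: %}
    dvh_curves: dict[str, tuple[np.ndarray, np.ndarray]]
    ci: dict[str, float]

    def summary(self) -> dict:
        out = {"QF_pct": self.qf_pct}
        out.update({f"within_{k}pct": v for k, v in self.within.items()})
        out.update({f"CI_{name}": v for name, v in self.ci.items()})
        return out


def quality_report(dose: ImageVolume, rx: PrescriptionMap,
                   structures: dict[str, ImageVolume] | None = None,
                   qvh_bin: float = 0.01, dvh_bin: float = 0.1) -> QualityReport:
    """Full evaluation of a dose against one prescription map.

    ``structures`` adds DVH curves and conformity indices for named masks
    (defaults to the map's own BTV masks when present, else the target)."""
    qm = q_map(dose, rx)
    bins, pct = qvh(qm, rx.target_mask, qvh_bin)
    within = {t: fraction_within(qm, rx.target_mask, t / 100.0) for t in (3, 4, 5)}
    if structures is None:
        structures = {f"BTV{k + 1}": b for k, b in enumerate(rx.btv_masks)}
        if not structures:
            structures = {"target": rx.target_mask}
    dvhs = {name: dvh(dose, m, dvh_bin) for name, m in structures.items()}
    cis = {name: conformity_index(dose, rx, m) for name, m in structures.items()}
    return QualityReport(qmap=qm, qvh_bins=bins, qvh_pct=pct,
                         qf_pct=qf(qm, rx.target_mask), within=within,
                         dvh_curves=dvhs, ci=cis)


# ---------------------------------------------------------------------------
# Adaptive replanning and dose accumulation
# ---------------------------------------------------------------------------

@dataclass
class TreatmentPhase:
    """One planning phase of a fractionated course.

    The phase plan is optimized against the full-course prescription; at
    accumulation each phase contributes its dose weighted by its share of
    fractions."""

    first_fraction: int
    last_fraction: int
    prescription: RobustPrescription
    apertures: list[Aperture]
    solution: LPSolution
    influence: DoseInfluenceMatrix
    n_new_apertures: int = 0

    @property
    def n_fractions(self) -> int:
        return self.last_fraction - self.first_fraction + 1

    @property
    def dose(self) -> ImageVolume:
        return self.solution.dose


def replan(prior: TreatmentPhase, new_rx: RobustPrescription,
           beams: list[BeamGeometry], engine: PencilBeamEngine,
           cfg: LPConfig | None = None, n_bands: int = 4,
           fractions: tuple[int, int] | None = None,
           rules: tuple[str, ...] = ("split-components",)) -> TreatmentPhase:
    """Adaptive replan: extend the prior aperture pool with shapes generated
    from the new prescription, compute influence columns only for the new
    apertures, and re-solve the weight LP against the new prescription.

    Apertures that duplicate a prior shape (same beam, edges within half a
    fluence pixel) are not added, so an unchanged prescription re-solves
    over essentially the prior pool and cannot do worse than the prior
    objective."""
    if new_rx.n_target == 0:
        raise ConfigurationError("new prescription is empty")
    bands = prescription_bands(new_rx.maps[0], n_bands)
    candidates = biomap_apertures(bands, [o.mask for o in new_rx.oars], beams,
                                  rules=rules, tag_prefix="adapt:")
    fresh = [ap for ap in candidates
             if not any(apertures_close(ap, old) for old in prior.apertures)]
    pool = list(prior.apertures) + fresh
    if fresh:
        new_dim = build_influence_matrix(fresh, engine.ct, engine.grid, engine=engine)
        mat = sparse.hstack([prior.influence.matrix, new_dim.matrix], format="csr")
        pool = list(prior.apertures) + new_dim.apertures
    else:
        mat = prior.influence.matrix
    dim = DoseInfluenceMatrix(matrix=mat, grid=engine.grid, apertures=pool,
                              kernel=engine.kernel)
    sol = lp_plan(dim, new_rx, cfg)
    first, last = fractions if fractions else (prior.last_fraction + 1,
                                               prior.last_fraction + 1)
    return TreatmentPhase(first_fraction=first, last_fraction=last,
                          prescription=new_rx, apertures=pool, solution=sol,
                          influence=dim, n_new_apertures=len(fresh))


def accumulate(phases: list[TreatmentPhase], total_fractions: int,
               structures: dict[str, ImageVolume] | None = None
               ) -> tuple[ImageVolume, QualityReport]:
    """Fraction-weighted voxel-wise dose accumulation over the course.

    Total dose_i = sum_p (fractions_p / total) * dose_p,i on the shared
    rigid dose grid; quality is evaluated against the identically weighted
    per-voxel prescription over the voxels prescribed in *every* phase.
    Voxels a later phase stopped prescribing (response regions with no
    residual activity) have no full-course prescription and are excluded
    from the total-treatment Q evaluation."""
    if not phases:
        raise ConfigurationError("no phases to accumulate")
    grid = phases[0].dose.grid
    covered = np.zeros(total_fractions + 1, dtype=bool)
    for ph in phases:
        if ph.dose.grid != grid:
            raise ConfigurationError("all phase doses must share one grid")
        if ph.first_fraction < 1 or ph.last_fraction > total_fractions:
            raise ConfigurationError("phase fraction range outside the course")
        span = np.arange(ph.first_fraction, ph.last_fraction + 1)
        if covered[span].any():
            raise ConfigurationError("overlapping phase fraction ranges")
        covered[span] = True
    if not covered[1:].all():
        raise ConfigurationError("phases do not partition 1..total_fractions")

    total = np.zeros(grid.shape)
    rx_total = np.zeros(grid.shape)
    common = np.ones(grid.shape, dtype=bool)
    for ph in phases:
        w = ph.n_fractions / total_fractions
        total += w * ph.dose.values
        pmap = ph.prescription.maps[0]
        rx_total += w * pmap.dose.values
        common &= pmap.target_mask.values > 0
    if not common.any():
        raise ConfigurationError("phase targets share no voxels; no course-long "
                                 "prescription to evaluate against")
    dose = ImageVolume(grid, total, "dose-Gy")
    mask = ImageVolume(grid, common.astype(float), "mask")
    blended = PrescriptionMap(
        grid=grid, target_mask=mask,
        dose=ImageVolume(grid, np.where(common, rx_total, 0.0), "dose-Gy"),
        d_min=np.where(common, rx_total, 0.0), d_max=np.where(common, rx_total, 0.0),
        delta=phases[0].prescription.maps[0].delta, label="dpbn",
        source="accumulated",
    )
    report = quality_report(dose, blended, structures=structures or {"target": mask})
    return dose, report
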