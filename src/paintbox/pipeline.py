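"""End-to-end planning studies on the stock head-and-neck-like phantom.

These functions wire the whole chain together — phantom generation,
reconstruction emulation, segmentation, DPBN prescription, BIOMAP-style
aperture generation, pencil-beam influence and the weight LP — under the
default study conditions: 70->82 Gy linear prescription, 7 equispaced
coplanar beams, 4 prescription bands, penalties (1, 1, 0.5), a posterior
cord-like OAR capped at 50 Gy, and segmentation at 40% of the maximum SUV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .beams import (BeamGeometry, DoseInfluenceMatrix, PencilBeamEngine, PencilKernel,
                    biomap_apertures, build_influence_matrix, default_beams,
                    prescription_bands)
from .evaluate import QualityReport, TreatmentPhase, quality_report
from .grids import GridSpec, ImageVolume
from .optimize import LPConfig, LPSolution, plan as lp_plan
from .phantom import (PROTOCOLS, ReconstructionProtocol, emulate_reconstruction,
                      hn_phantom, make_ct)
from .prescription import (OARConstraint, PrescriptionMap, combine_robust, dpbn_map,
                           segment_suv)

#: default study conditions
SEGMENT_FRACTION = 0.4
OAR_CAP_GY = 50.0
N_BEAMS = 7
N_BANDS = 4


@dataclass
class PlanStudy:
    """Everything produced by one planning run."""

    phantom: dict
    ct: ImageVolume
    reconstructions: dict[str, ImageVolume]
    fused: dict[str, ImageVolume]         # CT-grid SUV the maps were built on
    maps: list[PrescriptionMap]
    prescription: "object"                # RobustPrescription
    beams: list[BeamGeometry]
    engine: PencilBeamEngine
    influence: DoseInfluenceMatrix
    solution: LPSolution
    reports: dict[str, QualityReport]

    def phase(self, first: int, last: int) -> TreatmentPhase:
        return TreatmentPhase(first_fraction=first, last_fraction=last,
                              prescription=self.prescription,
                              apertures=self.influence.apertures,
                              solution=self.solution, influence=self.influence)


def _child_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), k]).generate_state(1)[0] % (2 ** 31))


def run_plan_study(
    seed: int = 0,
    protocols: tuple[str, ...] = ("biograph",),
    n_beams: int = N_BEAMS,
    n_bands: int = N_BANDS,
    segment_fraction: float = SEGMENT_FRACTION,
    oar_cap: float = OAR_CAP_GY,
    cfg: LPConfig | None = None,
    kernel: PencilKernel | None = None,
    phantom: dict | None = None,
) -> PlanStudy:
    """Run the default DPBN planning study.

    With one protocol this is the single-map plan; with two protocols the
    two emulated reconstructions each yield a prescription map and the LP
    enforces both constraint stacks simultaneously (the robust plan).
    Quality is reported separately against every map.
    """
    ph = phantom or hn_phantom()
    dose_grid: GridSpec = ph["dose_grid"]
    ct = make_ct(ph["lesions"], ph["body"], dose_grid)

    # PET -> CT-grid fusion with cubic spline, segmentation and prescription
    # on the CT grid, then nearest-neighbor onto the dose grid: the
    # interpolation chain the co-registration study selects
    from .grids import resample
    ct_grid = ph.get("ct_grid", dose_grid)
    recons, fused_maps, maps = {}, {}, []
    for k, name in enumerate(protocols):
        proto: ReconstructionProtocol = PROTOCOLS[name.lower()]
        recon = emulate_reconstruction(ph["truth"], proto, seed=_child_seed(seed, k))
        fused = resample(recon, ct_grid, "cubic-spline")
        seg = segment_suv(fused, segment_fraction)
        maps.append(dpbn_map(fused, seg.mask, source=proto.name))
        recons[name.lower()] = recon
        fused_maps[name.lower()] = fused

    oar_mask = ImageVolume(dose_grid,
                           ph["oar_shapes"]["cord"].rasterize(dose_grid).astype(float),
                           "mask")
    rp = combine_robust(maps, [OARConstraint(oar_mask, oar_cap, "cord")], dose_grid)

    beams = default_beams(n_beams)
    # aperture shapes from every stacked map: a robust plan must be able to
    # reach voxels that belong to only one map's target
    apertures = []
    from .beams import apertures_close
    for pmap in rp.maps:
        bands = prescription_bands(pmap, n_bands)
        for ap in biomap_apertures(bands, [o.mask for o in rp.oars], beams,
                                   tag_prefix=f"{pmap.source.lower()}:"):
            if not any(apertures_close(ap, old) for old in apertures):
                apertures.append(ap)
    engine = PencilBeamEngine(ct, dose_grid, kernel)
    dim = build_influence_matrix(apertures, ct, dose_grid, engine=engine)
    sol = lp_plan(dim, rp, cfg)

    reports = {m.source.lower() or f"map{i}": quality_report(sol.dose, m)
               for i, m in enumerate(rp.maps)}
    return PlanStudy(phantom=ph, ct=ct, reconstructions=recons, fused=fused_maps,
                     maps=maps, prescription=rp, beams=beams, engine=engine,
                     influence=dim, solution=sol, reports=reports)


#: default course fractionation: 70 Gy base prescription over 30 sessions,
#: replanned after fraction 17
TOTAL_FRACTIONS = 30
PHASE_SPLIT = 17


def default_response():
    """Stock metabolic response for the follow-up study: one lesion clears
    completely and the remaining two lose part of their activity."""
    from .phantom import ResponseModel, Shape

    return ResponseModel(
        factors=(
            (Shape("sphere", (-16.0, 8.0, 6.0), (13.0,)), 0.65),
            (Shape("ellipsoid", (0.0, -18.0, -4.0), (10.0, 9.0, 12.0)), 0.8),
        ),
        cleared=(Shape("sphere", (18.0, 14.0, -8.0), (12.0,)),),
    )


def run_adaptive_study(seed: int = 0, response=None, cfg: LPConfig | None = None):
    """Two-phase adaptive course on the default phantom.

    Phase I plans the baseline DPBN prescription (fractions 1-17); a
    follow-up SUV map with reduced/cleared activity defines a new
    prescription, and Phase II (fractions 18-30) is replanned over the
    prior aperture pool plus the few new shapes the follow-up map
    generates.  Returns (phase1, phase2, total_dose, total_report).
    """
    from .evaluate import accumulate, replan
    from .grids import resample
    from .phantom import follow_up_suv

    study = run_plan_study(seed=seed, cfg=cfg)
    phase1 = study.phase(1, PHASE_SPLIT)

    followup = follow_up_suv(study.reconstructions["biograph"],
                             response or default_response())
    ct_grid = study.phantom.get("ct_grid", study.prescription.grid)
    fused = resample(followup, ct_grid, "cubic-spline")
    seg = segment_suv(fused, SEGMENT_FRACTION)
    new_map = dpbn_map(fused, seg.mask, source="followup")
    oar_mask = ImageVolume(
        study.prescription.grid,
        study.phantom["oar_shapes"]["cord"].rasterize(study.prescription.grid
                                                      ).astype(float), "mask")
    new_rp = combine_robust([new_map], [OARConstraint(oar_mask, OAR_CAP_GY, "cord")],
                            study.prescription.grid)
    phase2 = replan(phase1, new_rp, study.beams, study.engine, cfg=cfg,
                    fractions=(PHASE_SPLIT + 1, TOTAL_FRACTIONS))
    total_dose, report = accumulate([phase1, phase2], TOTAL_FRACTIONS)
    return phase1, phase2, total_dose, report
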