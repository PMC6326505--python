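"""Linear-programming aperture-weight optimization.

The plan is the solution of a pure LP over non-negative aperture weights
``w_j`` and per-constraint slack variables: every target voxel i (under
every stacked prescription map m) must satisfy

    sum_j w_j d_ij - x_im <= D_max(i,m) * Delta_max(m)
    sum_j w_j d_ij + y_im >= D_min(i,m) * Delta_min(m)

and every OAR voxel  sum_j w_j d_ij - x_i <= D_OAR_max, with all variables
>= 0.  The objective penalizes the slacks,

    OF = P_Tmax * sum x_target + P_Tmin * sum y_target + P_OARmax * sum x_oar,

so a plan whose dose lies inside every robust band has OF = 0.  Because the
slacks are free to absorb any violation the LP is always feasible, and a
conflicting stack of maps (floors above ceilings after Delta) simply
resolves to the compromise that minimizes the weighted violation — which is
exactly the intended behavior when one plan must serve several prescription
maps at once.

Slack recovery (the analytic optimum of the slacks for a fixed w) provides
an independent oracle for the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .beams import DoseInfluenceMatrix
from .errors import AssemblyError, SolverError
from .grids import ImageVolume
from .prescription import RobustPrescription

#: default penalties (P_T,max, P_T,min, P_OAR,max)
DEFAULT_PENALTIES = (1.0, 1.0, 0.5)


@dataclass(frozen=True)
class LPConfig:
    """Penalty weights and solver tolerances for the plan LP."""

    p_t_max: float = DEFAULT_PENALTIES[0]
    p_t_min: float = DEFAULT_PENALTIES[1]
    p_oar_max: float = DEFAULT_PENALTIES[2]
    tolerance: float = 1e-7
    weight_upper: float | None = None  # optional upper bound on aperture weights
    #: lexicographic tie-break: among objective-optimal plans, prefer the one
    #: with minimal total |dose - prescription| over target voxels.  The
    #: similarity-factor band makes the optimum degenerate; this picks the
    #: centered vertex without changing the reported objective.
    center_tiebreak: bool = True

    def __post_init__(self):
        if self.p_t_max < 0 or self.p_t_min < 0 or self.p_oar_max < 0:
            raise AssemblyError("penalties must be >= 0")
        if self.p_t_max == self.p_t_min == self.p_oar_max == 0:
            raise AssemblyError("at least one penalty must be positive")


@dataclass
class LPProblem:
    """Assembled LP: ``minimize c @ z`` s.t. ``A_ub @ z <= b_ub``, ``z >= 0``.

    Variable blocks: z = [w (M), x_target (K), y_target (K), x_oar (K_o)],
    one (x, y) pair per (target voxel, map) combination.  ``rows`` maps each
    constraint row to (flat voxel index, map index, bound type).
    """

    c: np.ndarray
    a_ub: sparse.csr_matrix
    b_ub: np.ndarray
    n_weights: int
    n_target_pairs: int
    n_oar: int
    rows: list[tuple[int, int, str]]
    target_idx: list[np.ndarray]      # per map, flat voxel indices
    target_rx: np.ndarray             # prescribed dose per (voxel, map) pair
    oar_idx: np.ndarray               # flat voxel indices of OAR constraints
    oar_caps: np.ndarray
    config: LPConfig


@dataclass
class LPSolution:
    """Solver output: aperture weights, slacks, objective and planned dose."""

    weights: np.ndarray
    x_target: np.ndarray
    y_target: np.ndarray
    x_oar: np.ndarray
    objective: float
    status: str
    dose: ImageVolume


def assemble(d: DoseInfluenceMatrix, rp: RobustPrescription, cfg: LPConfig | None = None
             ) -> LPProblem:
    """Build the LP from the influence matrix and a robust prescription."""
    cfg = cfg or LPConfig()
    if d.grid != rp.grid:
        raise AssemblyError("influence matrix and prescription are on different grids")
    mat = d.matrix.tocsc()
    empty = np.flatnonzero(np.diff(mat.indptr) == 0)
    if empty.size:
        raise AssemblyError(f"influence matrix has all-zero columns at {empty.tolist()}")
    mat = mat.tocsr()
    m_ap = mat.shape[1]

    target_idx, target_rx, bounds_lo, bounds_hi, rows = [], [], [], [], []
    for mi, pmap in enumerate(rp.maps):
        idx = pmap.target_indices
        target_idx.append(idx)
        target_rx.append(pmap.dose.values.reshape(-1)[idx])
        flat_min = pmap.d_min.reshape(-1)[idx] * pmap.delta[0]
        flat_max = pmap.d_max.reshape(-1)[idx] * pmap.delta[1]
        bounds_lo.append(flat_min)
        bounds_hi.append(flat_max)
        rows.extend((int(i), mi, "ceiling") for i in idx)
    k_t = sum(len(i) for i in target_idx)

    oar_idx_list, oar_caps = [], []
    for oar in rp.oars:
        idx = oar.mask.mask_indices
        oar_idx_list.append(idx)
        oar_caps.append(np.full(len(idx), float(oar.cap_gy)))
    oar_idx = np.concatenate(oar_idx_list) if oar_idx_list else np.empty(0, dtype=int)
    oar_caps = np.concatenate(oar_caps) if oar_caps else np.empty(0)
    k_o = len(oar_idx)
    rows.extend((int(i), mi, "floor") for mi, idx in enumerate(target_idx) for i in idx)
    rows.extend((int(i), -1, "oar") for i in oar_idx)

    all_t = np.concatenate(target_idx)
    d_t = mat[all_t, :]
    blocks = []
    # ceilings: D w - x <= Dmax * dmax
    blocks.append(sparse.hstack([
        d_t, -sparse.eye(k_t), sparse.csr_matrix((k_t, k_t)),
        sparse.csr_matrix((k_t, k_o)),
    ]))
    # floors: -D w - y <= -Dmin * dmin
    blocks.append(sparse.hstack([
        -d_t, sparse.csr_matrix((k_t, k_t)), -sparse.eye(k_t),
        sparse.csr_matrix((k_t, k_o)),
    ]))
    if k_o:
        d_o = mat[oar_idx, :]
        blocks.append(sparse.hstack([
            d_o, sparse.csr_matrix((k_o, 2 * k_t)), -sparse.eye(k_o),
        ]))
    a_ub = sparse.vstack(blocks, format="csr")
    b_ub = np.concatenate([np.concatenate(bounds_hi), -np.concatenate(bounds_lo),
                           oar_caps])
    c = np.concatenate([
        np.zeros(m_ap),
        np.full(k_t, cfg.p_t_max),
        np.full(k_t, cfg.p_t_min),
        np.full(k_o, cfg.p_oar_max),
    ])
    return LPProblem(c=c, a_ub=a_ub, b_ub=b_ub, n_weights=m_ap, n_target_pairs=k_t,
                     n_oar=k_o, rows=rows, target_idx=target_idx,
                     target_rx=np.concatenate(target_rx), oar_idx=oar_idx,
                     oar_caps=oar_caps, config=cfg)


def solve(problem: LPProblem, d: DoseInfluenceMatrix) -> LPSolution:
    """Solve the assembled LP with HiGHS and recover all variable blocks."""
    cfg = problem.config
    ub = cfg.weight_upper
    bounds = [(0, ub)] * problem.n_weights + [(0, None)] * (
        2 * problem.n_target_pairs + problem.n_oar
    )
    res = linprog(
        problem.c, A_ub=problem.a_ub, b_ub=problem.b_ub, bounds=bounds,
        method="highs",
        options={"primal_feasibility_tolerance": cfg.tolerance,
                 "dual_feasibility_tolerance": cfg.tolerance},
    )
    if res.status != 0 or res.x is None:
        report = {"status": int(res.status), "message": res.message}
        if res.x is not None:
            viol = problem.a_ub @ res.x - problem.b_ub
            report["max_violation"] = float(np.max(viol))
        raise SolverError(f"LP solve failed: {res.message}", report)
    z = np.clip(res.x, 0.0, None)  # clamp solver round-off at the bounds
    m, k = problem.n_weights, problem.n_target_pairs
    if cfg.center_tiebreak and k > 0:
        z2 = _centering_pass(problem, float(res.fun), bounds)
        if z2 is not None:
            z = z2
    weights = z[:m]
    slacks = _analytic_slacks(problem, weights)
    dose = compute_dose(d, weights)
    return LPSolution(weights=weights, objective=slacks["of"], status="optimal",
                      dose=dose, **{kk: slacks[kk] for kk in
                                    ("x_target", "y_target", "x_oar")})


def _analytic_slacks(problem: LPProblem, weights: np.ndarray) -> dict:
    """Optimal slack blocks for fixed weights, from the assembled rows."""
    m, k, ko = problem.n_weights, problem.n_target_pairs, problem.n_oar
    d_t = problem.a_ub[:k, :m]
    dose_t = np.asarray(d_t @ weights).ravel()
    ceil = problem.b_ub[:k]
    floor = -problem.b_ub[k:2 * k]
    x_t = np.maximum(0.0, dose_t - ceil)
    y_t = np.maximum(0.0, floor - dose_t)
    if ko:
        d_o = problem.a_ub[2 * k:, :m]
        x_o = np.maximum(0.0, np.asarray(d_o @ weights).ravel() - problem.b_ub[2 * k:])
    else:
        x_o = np.empty(0)
    cfg = problem.config
    of = float(cfg.p_t_max * x_t.sum() + cfg.p_t_min * y_t.sum()
               + cfg.p_oar_max * x_o.sum())
    return {"x_target": x_t, "y_target": y_t, "x_oar": x_o, "of": of}


def _centering_pass(problem: LPProblem, of_star: float, bounds) -> np.ndarray | None:
    """Second LP: subject to the original constraints and objective <= its
    optimum, minimize the worst per-map mean relative deviation
    ``|dose - prescription| / prescription`` (plus a small total-deviation
    term for uniqueness).  With several stacked maps this picks the evenly
    balanced compromise among the degenerate optima; with one map it
    reduces to plain centering on the prescription."""
    m, k, ko = problem.n_weights, problem.n_target_pairs, problem.n_oar
    nz = m + 2 * k + ko
    rx = problem.target_rx
    scale = sparse.diags(1.0 / rx)
    d_rel = (scale @ problem.a_ub[:k, :m]).tocsr()
    # variables: [z (nz), a (k), t (1)]; a >= |D w / rx - 1|, t >= map means
    pad = sparse.csr_matrix((k, nz - m))
    z1 = sparse.csr_matrix((k, 1))
    upper = sparse.hstack([d_rel, pad, -sparse.eye(k), z1])
    lower = sparse.hstack([-d_rel, pad, -sparse.eye(k), z1])
    of_row = sparse.hstack([sparse.csr_matrix(problem.c), sparse.csr_matrix((1, k + 1))])
    mean_rows, offset = [], 0
    c = np.zeros(nz + k + 1)
    c[-1] = 1.0
    for idx in problem.target_idx:
        km = len(idx)
        row = np.zeros(nz + k + 1)
        row[nz + offset:nz + offset + km] = 1.0 / km
        row[-1] = -1.0
        mean_rows.append(sparse.csr_matrix(row))
        c[nz + offset:nz + offset + km] += 1e-3 / km
        offset += km
    a_ub = sparse.vstack([
        sparse.hstack([problem.a_ub, sparse.csr_matrix((problem.a_ub.shape[0], k + 1))]),
        of_row, upper, lower, *mean_rows,
    ], format="csr")
    slack = problem.config.tolerance * 10 * (1.0 + abs(of_star))
    b_ub = np.concatenate([problem.b_ub, [of_star + slack], np.ones(k), -np.ones(k),
                           np.zeros(len(mean_rows))])
    res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=bounds + [(0, None)] * (k + 1),
                  method="highs",
                  options={"primal_feasibility_tolerance": problem.config.tolerance,
                           "dual_feasibility_tolerance": problem.config.tolerance})
    if res.status != 0 or res.x is None:
        return None
    return np.clip(res.x[:nz], 0.0, None)


@dataclass
class SlackReport:
    """Analytically recovered slacks for fixed weights (the LP oracle)."""

    x_target: list[np.ndarray]   # per map
    y_target: list[np.ndarray]
    x_oar: np.ndarray

    def objective(self, cfg: LPConfig) -> float:
        xs = sum(float(x.sum()) for x in self.x_target)
        ys = sum(float(y.sum()) for y in self.y_target)
        return cfg.p_t_max * xs + cfg.p_t_min * ys + cfg.p_oar_max * float(self.x_oar.sum())


def recover_slacks(weights: np.ndarray, d: DoseInfluenceMatrix,
                   rp: RobustPrescription) -> SlackReport:
    """Optimal slacks for fixed weights: x = max(0, dose - ceiling),
    y = max(0, floor - dose) per (voxel, map), analogously for OARs."""
    dose_flat = np.asarray(d.matrix @ np.asarray(weights, dtype=float)).ravel()
    xs, ys = [], []
    for pmap in rp.maps:
        idx = pmap.target_indices
        ceil = pmap.d_max.reshape(-1)[idx] * pmap.delta[1]
        floor = pmap.d_min.reshape(-1)[idx] * pmap.delta[0]
        dv = dose_flat[idx]
        xs.append(np.maximum(0.0, dv - ceil))
        ys.append(np.maximum(0.0, floor - dv))
    oar_x = []
    for oar in rp.oars:
        idx = oar.mask.mask_indices
        oar_x.append(np.maximum(0.0, dose_flat[idx] - oar.cap_gy))
    x_oar = np.concatenate(oar_x) if oar_x else np.empty(0)
    return SlackReport(x_target=xs, y_target=ys, x_oar=x_oar)


def compute_dose(d: DoseInfluenceMatrix, weights: np.ndarray) -> ImageVolume:
    """Planned dose ``dose_i = sum_j w_j d_ij`` on the dose grid."""
    w = np.asarray(weights, dtype=float)
    if w.shape != (d.matrix.shape[1],):
        raise AssemblyError(
            f"weights shape {w.shape} does not match {d.matrix.shape[1]} apertures"
        )
    flat = np.asarray(d.matrix @ w).ravel()
    return ImageVolume(d.grid, flat.reshape(d.grid.shape), "dose-Gy")


def plan(d: DoseInfluenceMatrix, rp: RobustPrescription,
         cfg: LPConfig | None = None) -> LPSolution:
    """Assemble and solve in one step."""
    problem = assemble(d, rp, cfg)
    return solve(problem, d)
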