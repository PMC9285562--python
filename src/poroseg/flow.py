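"""Steady incompressible Stokes-Brinkman flow on a voxel grid.

Solves

    0 = -grad(p) + mu lap(v_s) - P_v v_s,      div(v_s) = 0

for the superficial velocity ``v_s`` and pressure on the fluid voxels of a
(possibly porous) domain, with inlet-velocity / outlet-pressure / no-slip
wall boundary conditions.  Convection is dropped: the method operates in the
creeping regime (inlet Re < 1) precisely so the flow fills the domain by
porosity alone, which makes the system linear and the solution deterministic.

Discretisation is a marker-and-cell (MAC) staggered grid: face-normal
velocities, cell-centred pressures, 7-point Laplacian, resistance averaged
onto faces.  The symmetric saddle-point system is solved either by a sparse
direct factorisation (small systems) or by conjugate gradients on the
pressure Schur complement, with per-axis LU factors of the velocity block
and a variable-coefficient pressure-Poisson preconditioner.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy import ndimage

from .porous import FluidProps, PorosityField, ResistanceField

log = logging.getLogger(__name__)

# face type codes
NONE, INTERIOR, WALL, INLET, OUTLET, SYMMETRY = -1, 0, 1, 2, 3, 4
_LABEL_CODE = {"wall": WALL, "inlet": INLET, "outlet": OUTLET, "symmetry": SYMMETRY}
_AXIS = {"x": 0, "y": 1, "z": 2}

_EYE = np.eye(3, dtype=int)


class ConvergenceError(RuntimeError):
    """Raised when the linear solve fails to meet the residual tolerance."""


@dataclass(frozen=True)
class FaceSelector:
    """Selects exterior faces on one bounding-box side, optionally masked.

    ``side`` is one of ``x-``, ``x+``, ``y-``, ``y+``, ``z-``, ``z+``; the
    optional boolean ``mask`` has the shape of that side plane.
    """

    side: str
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.side) != 2 or self.side[0] not in "xyz" or self.side[1] not in "+-":
            raise ValueError(f"invalid side {self.side!r}; expected e.g. 'x-'")

    @property
    def axis(self) -> int:
        return _AXIS[self.side[0]]

    @property
    def is_upper(self) -> bool:
        return self.side[1] == "+"


def _as_selectors(spec) -> list[FaceSelector]:
    if spec is None:
        return []
    if isinstance(spec, (FaceSelector, str)):
        spec = [spec]
    return [s if isinstance(s, FaceSelector) else FaceSelector(s) for s in spec]


@dataclass
class FlowDomain:
    """Fluid voxels, per-voxel resistance, spacing (m) and face labels."""

    fluid_mask: np.ndarray
    resistance: np.ndarray  # P_v per voxel, kg m^-3 s^-1
    spacing: float  # m, isotropic
    face_type: list[np.ndarray]
    n_removed_cells: int = 0
    n_removed_components: int = 0

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.fluid_mask.shape

    @property
    def n_fluid(self) -> int:
        return int(self.fluid_mask.sum())

    @property
    def empty(self) -> bool:
        return self.n_fluid == 0

    def count_faces(self, code: int) -> int:
        return int(sum((ft == code).sum() for ft in self.face_type))


@dataclass
class SolverConfig:
    """Inlet speed, residual tolerance and solver selection.

    ``inlet_profile`` optionally prescribes a per-face speed pattern on the
    inlet side plane(s) instead of a uniform plug; positive values always
    mean inflow.
    """

    inlet_speed: float = 1e-4  # m/s
    tol: float = 1e-8  # relative residual on momentum + continuity
    max_iter: int = 5000
    method: str = "auto"  # auto | direct | schur
    direct_threshold: int = 45_000  # unknown count below which spsolve is used
    inlet_profile: np.ndarray | None = None


@dataclass
class FlowSolution:
    """Staggered face velocities, cell pressures and derived speed field."""

    face_velocity: list[np.ndarray]  # per-axis face grids, m/s (signed, +axis)
    pressure: np.ndarray  # per cell, Pa (0 outside fluid)
    speed: np.ndarray  # cell-centred |v_s|
    domain: FlowDomain
    residuals: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# domain construction
# ---------------------------------------------------------------------------

def _classify_faces(mask: np.ndarray, labelled: list[tuple[int, FaceSelector]]
                    ) -> list[np.ndarray]:
    nd = mask.shape
    ftype = []
    for d in range(3):
        shape = list(nd)
        shape[d] += 1
        lo = np.zeros(shape, bool)
        hi = np.zeros(shape, bool)
        sl = [slice(None)] * 3
        sl[d] = slice(1, None)
        lo[tuple(sl)] = mask  # lower-adjacent cell is fluid
        sl[d] = slice(0, nd[d])
        hi[tuple(sl)] = mask  # upper-adjacent cell is fluid
        F = np.full(shape, NONE, np.int8)
        F[lo & hi] = INTERIOR
        F[lo ^ hi] = WALL
        ftype.append(F)
    for code, sel in labelled:
        d = sel.axis
        k = nd[d] if sel.is_upper else 0
        sl = [slice(None)] * 3
        sl[d] = k
        plane = ftype[d][tuple(sl)]
        eligible = plane == WALL
        if sel.mask is not None:
            eligible = eligible & np.asarray(sel.mask, bool)
        plane[eligible] = code
    return ftype


def _boundary_cells(mask: np.ndarray, sel: FaceSelector) -> np.ndarray:
    """Fluid cells adjacent to the selected side plane (respecting the mask)."""
    d = sel.axis
    sl = [slice(None)] * 3
    sl[d] = -1 if sel.is_upper else 0
    plane = mask[tuple(sl)]
    if sel.mask is not None:
        plane = plane & np.asarray(sel.mask, bool)
    out = np.zeros_like(mask)
    out[tuple(sl)] = plane
    return out


def build_domain(pf: PorosityField, rf: ResistanceField,
                 inlet_spec, outlet_spec, symmetry=()) -> FlowDomain:
    """Label exterior faces and prune fluid not connecting inlet to outlet.

    ``inlet_spec``/``outlet_spec`` are :class:`FaceSelector` (or side strings,
    or lists of either); unlabeled exterior faces become no-slip walls.
    Fluid components that do not connect an inlet face to an outlet face
    cannot carry a consistent prescribed influx and are removed from the
    domain (logged); if nothing connects, an empty domain with a warning is
    returned and the solver reports zero net flux.
    """
    if pf.solid_mask is None:
        raise ValueError("porosity field must be solidified before building a domain")
    if not pf.is_isotropic:
        raise ValueError("flow domain requires isotropic spacing")
    mask = np.asarray(pf.fluid_mask, bool)
    inlets = _as_selectors(inlet_spec)
    outlets = _as_selectors(outlet_spec)
    syms = _as_selectors(symmetry)
    if not inlets or not outlets:
        raise ValueError("at least one inlet and one outlet selector are required")
    labelled = ([(INLET, s) for s in inlets] + [(OUTLET, s) for s in outlets]
                + [(SYMMETRY, s) for s in syms])

    ftype = _classify_faces(mask, labelled)
    if not any((ft == INLET).any() for ft in ftype):
        raise ValueError("inlet selection intersects no fluid voxels")
    if not any((ft == OUTLET).any() for ft in ftype):
        raise ValueError("outlet selection intersects no fluid voxels")

    # keep only components touching both an inlet and an outlet face
    lab, nlab = ndimage.label(mask, structure=ndimage.generate_binary_structure(3, 1))
    in_cells = np.zeros_like(mask)
    for s in inlets:
        in_cells |= _boundary_cells(mask, s)
    out_cells = np.zeros_like(mask)
    for s in outlets:
        out_cells |= _boundary_cells(mask, s)
    in_labels = set(np.unique(lab[in_cells])) - {0}
    out_labels = set(np.unique(lab[out_cells])) - {0}
    keep = in_labels & out_labels
    mask2 = mask & np.isin(lab, sorted(keep))
    removed_cells = int(mask.sum() - mask2.sum())
    removed_comp = int(nlab - len(keep))
    if removed_cells:
        log.info("removed %d fluid voxels in %d components not connecting "
                 "inlet to outlet", removed_cells, removed_comp)
    if not keep:
        warnings.warn("no fluid component connects an inlet to an outlet; "
                      "the flow solution will carry zero net flux")
    ftype = _classify_faces(mask2, labelled)
    pv = np.where(mask2, rf.P_v, 0.0)
    return FlowDomain(mask2, pv, rf.d, ftype, removed_cells, removed_comp)


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------

def _face_values(dom: FlowDomain, cfg: SolverConfig) -> list[np.ndarray]:
    """Prescribed normal-velocity values (signed along +axis) on known faces."""
    vals = [np.zeros(ft.shape) for ft in dom.face_type]
    nd = dom.shape
    for d in range(3):
        ft = dom.face_type[d]
        inlet = ft == INLET
        if not inlet.any():
            continue
        sl_lo = [slice(None)] * 3
        sl_lo[d] = 0
        sl_hi = [slice(None)] * 3
        sl_hi[d] = nd[d]
        for sl, sign in ((tuple(sl_lo), +1.0), (tuple(sl_hi), -1.0)):
            sel = inlet[sl]
            if not sel.any():
                continue
            speed = cfg.inlet_speed
            if cfg.inlet_profile is not None:
                speed = np.broadcast_to(cfg.inlet_profile, sel.shape)[sel]
            plane = vals[d][sl]
            plane[sel] = sign * speed
    return vals


def _assemble(dom: FlowDomain, mu: float, cfg: SolverConfig):
    """Build A (velocity block), C (gradient), b_u, g and index maps."""
    h = dom.spacing
    nd = dom.shape
    mask = dom.fluid_mask
    cell_id = np.full(nd, -1, np.int64)
    ncell = dom.n_fluid
    cell_id[mask] = np.arange(ncell)
    fvals = _face_values(dom, cfg)

    fids, offsets, counts = [], [], []
    off = 0
    for d in range(3):
        unk = (dom.face_type[d] == INTERIOR) | (dom.face_type[d] == OUTLET)
        ids = np.full(dom.face_type[d].shape, -1, np.int64)
        k = int(unk.sum())
        ids[unk] = off + np.arange(k)
        fids.append(ids)
        offsets.append(off)
        counts.append(k)
        off += k
    nu = off

    diag = np.zeros(nu)
    bu = np.zeros(nu)
    rows, cols, vals = [], [], []
    crows, ccols, cvals = [], [], []
    g = np.zeros(ncell)

    pv = dom.resistance
    for d in range(3):
        ft = dom.face_type[d]
        idx = np.argwhere((ft == INTERIOR) | (ft == OUTLET))
        if idx.size == 0:
            continue
        ids_here = fids[d][tuple(idx.T)]
        # adjacent cells (lower = idx - e_d, upper = idx in cell coords)
        low = idx - _EYE[d]
        upp = idx
        low_ok = (low[:, d] >= 0)
        low_ok &= mask[tuple(np.where(low_ok[:, None], low, 0).T)] & low_ok
        upp_ok = (upp[:, d] < nd[d])
        upp_ok &= mask[tuple(np.where(upp_ok[:, None], upp, 0).T)] & upp_ok
        # face resistance: mean of adjacent fluid-cell P_v
        p_lo = np.where(low_ok, pv[tuple(np.where(low_ok[:, None], low, 0).T)], 0.0)
        p_up = np.where(upp_ok, pv[tuple(np.where(upp_ok[:, None], upp, 0).T)], 0.0)
        nadj = low_ok.astype(float) + upp_ok.astype(float)
        pface = (p_lo + p_up) / np.maximum(nadj, 1.0)
        diag[ids_here] += pface * h ** 3

        # pressure gradient coupling: + h^2 p_upper - h^2 p_lower
        if low_ok.any():
            crows.append(ids_here[low_ok])
            ccols.append(cell_id[tuple(low[low_ok].T)])
            cvals.append(np.full(int(low_ok.sum()), -h * h))
        if upp_ok.any():
            crows.append(ids_here[upp_ok])
            ccols.append(cell_id[tuple(upp[upp_ok].T)])
            cvals.append(np.full(int(upp_ok.sum()), h * h))

        for a in range(3):
            for s in (-1, 1):
                nb = idx + s * _EYE[a]
                inb = (nb[:, a] >= 0) & (nb[:, a] < ft.shape[a])
                ntype = np.full(len(idx), NONE, np.int8)
                safe = np.where(inb[:, None], nb, 0)
                ntype[inb] = ft[tuple(safe[inb].T)]
                n_unk = (ntype == INTERIOR) | (ntype == OUTLET)
                if n_unk.any():
                    rows.append(ids_here[n_unk])
                    cols.append(fids[d][tuple(nb[n_unk].T)])
                    vals.append(np.full(int(n_unk.sum()), -mu * h))
                    diag[ids_here[n_unk]] += mu * h
                n_known = inb & ~n_unk & (ntype != NONE)
                if n_known.any():
                    diag[ids_here[n_known]] += mu * h
                    v = fvals[d][tuple(nb[n_known].T)]
                    bu[ids_here[n_known]] += mu * h * v
                ghost = ~inb | (ntype == NONE)
                if a == d or not ghost.any():
                    # along-axis ghost: zero-gradient (outlet); drop the term
                    continue
                # tangential ghost: reflect (no-slip/inlet) unless the side
                # face crossed is symmetry or outlet (zero-gradient)
                drop = np.zeros(len(idx), bool)
                for adj, ok in ((low, low_ok), (upp, upp_ok)):
                    side = adj.copy()
                    if s > 0:
                        side = side + _EYE[a]
                    lab_ok = ok & ghost
                    if not lab_ok.any():
                        continue
                    lab = dom.face_type[a][tuple(side[lab_ok].T)]
                    dd = np.zeros(len(idx), bool)
                    dd[lab_ok] = (lab == SYMMETRY) | (lab == OUTLET)
                    drop |= dd
                reflect = ghost & ~drop
                if reflect.any():
                    diag[ids_here[reflect]] += 2.0 * mu * h

    # divergence RHS from known faces (inlet; wall/symmetry carry zero)
    for d in range(3):
        ft = dom.face_type[d]
        known = (ft == INLET)
        if not known.any():
            continue
        kidx = np.argwhere(known)
        v = fvals[d][tuple(kidx.T)]
        low = kidx - _EYE[d]
        upp = kidx
        low_ok = (low[:, d] >= 0)
        low_ok &= mask[tuple(np.where(low_ok[:, None], low, 0).T)] & low_ok
        upp_ok = (upp[:, d] < nd[d])
        upp_ok &= mask[tuple(np.where(upp_ok[:, None], upp, 0).T)] & upp_ok
        if low_ok.any():  # face is the upper face of the lower cell (s=+1)
            np.add.at(g, cell_id[tuple(low[low_ok].T)], -h * h * v[low_ok])
        if upp_ok.any():  # face is the lower face of the upper cell (s=-1)
            np.add.at(g, cell_id[tuple(upp[upp_ok].T)], h * h * v[upp_ok])

    A = sp.coo_matrix((np.concatenate(vals) if vals else [],
                       (np.concatenate(rows) if rows else [],
                        np.concatenate(cols) if cols else [])),
                      shape=(nu, nu)).tocsr()
    A = A + sp.diags(diag)
    C = sp.coo_matrix((np.concatenate(cvals), (np.concatenate(crows),
                                               np.concatenate(ccols))),
                      shape=(nu, ncell)).tocsr()
    return A, C, bu, g, fids, cell_id, offsets, counts, fvals


# ---------------------------------------------------------------------------
# solve
# ---------------------------------------------------------------------------

def _solve_direct(A, C, bu, g):
    n_u, n_c = A.shape[0], C.shape[1]
    K = sp.bmat([[A, C], [C.T, None]], format="csc")
    rhs = np.concatenate([bu, -g])
    sol = spla.spsolve(K, rhs)
    return sol[:n_u], sol[n_u:]


def _solve_schur(A, C, bu, g, offsets, counts, cfg: SolverConfig):
    lus = []
    A_csc = A.tocsc()
    for off, k in zip(offsets, counts):
        if k == 0:
            lus.append(None)
            continue
        lus.append(spla.splu(A_csc[off:off + k, off:off + k]))

    def ainv(x):
        out = np.empty_like(x)
        for off, k, lu in zip(offsets, counts, lus):
            if k:
                out[off:off + k] = lu.solve(x[off:off + k])
        return out

    CT = C.T.tocsr()
    Sop = spla.LinearOperator((C.shape[1], C.shape[1]),
                              matvec=lambda p: CT @ ainv(C @ p))
    dinv = sp.diags(1.0 / A.diagonal())
    M = (CT @ dinv @ C).tocsc()
    Mlu = spla.splu(M)
    Mop = spla.LinearOperator(M.shape, matvec=Mlu.solve)
    rhs_p = CT @ ainv(bu) + g
    if np.linalg.norm(rhs_p) == 0:
        p = np.zeros(C.shape[1])
    else:
        p, info = spla.cg(Sop, rhs_p, M=Mop, rtol=min(cfg.tol * 1e-2, 1e-10),
                          atol=0.0, maxiter=cfg.max_iter)
        if info > 0:
            raise ConvergenceError(f"Schur CG did not converge in {info} iterations")
    u = ainv(bu - C @ p)
    return u, p


def solve_creeping_flow(domain: FlowDomain, fluid: FluidProps,
                        cfg: SolverConfig | None = None) -> FlowSolution:
    """Solve the Stokes-Brinkman system on the domain.

    Returns a :class:`FlowSolution` whose discrete divergence vanishes in
    every fluid cell to solver tolerance.  An empty domain yields the zero
    solution with a warning.
    """
    cfg = cfg or SolverConfig()
    nd = domain.shape
    if domain.empty:
        warnings.warn("empty flow domain: returning zero solution (zero net flux)")
        full = [np.zeros(ft.shape) for ft in domain.face_type]
        return FlowSolution(full, np.zeros(nd), np.zeros(nd), domain,
                            {"momentum": 0.0, "continuity": 0.0})

    A, C, bu, g, fids, cell_id, offsets, counts, fvals = _assemble(
        domain, fluid.mu, cfg)
    nu, nc = A.shape[0], C.shape[1]
    method = cfg.method
    if method == "auto":
        method = "direct" if nu + nc <= cfg.direct_threshold else "schur"
    log.info("solving Stokes-Brinkman: %d velocity + %d pressure unknowns (%s)",
             nu, nc, method)
    if method == "direct":
        u, p = _solve_direct(A, C, bu, g)
    elif method == "schur":
        u, p = _solve_schur(A, C, bu, g, offsets, counts, cfg)
    else:
        raise ValueError(f"unknown solver method {cfg.method!r}")

    scale_u = max(np.linalg.norm(bu), np.abs(cfg.inlet_speed) * fluid.mu *
                  domain.spacing * max(nu, 1) ** 0.5, 1e-300)
    res_mom = np.linalg.norm(A @ u + C @ p - bu) / scale_u
    flux_scale = max(abs(cfg.inlet_speed) * domain.spacing ** 2 *
                     max(domain.count_faces(INLET), 1), 1e-300)
    res_cont = np.abs(C.T @ u + g).max() / flux_scale
    if max(res_mom, res_cont) > cfg.tol:
        raise ConvergenceError(
            f"residuals above tolerance: momentum {res_mom:.2e}, "
            f"continuity {res_cont:.2e} (tol {cfg.tol:.1e})")

    full = []
    for d in range(3):
        F = fvals[d].copy()
        unk = fids[d] >= 0
        F[unk] = u[fids[d][unk]]
        full.append(F)
    pressure = np.zeros(nd)
    pressure[domain.fluid_mask] = p
    sol = FlowSolution(full, pressure, np.zeros(nd), domain,
                       {"momentum": float(res_mom), "continuity": float(res_cont),
                        "method": method})
    sol.speed = speed_field(sol)
    return sol


def speed_field(sol: FlowSolution) -> np.ndarray:
    """Cell-centred speed |v_s| from averaging opposing face velocities."""
    comps = []
    for d in range(3):
        F = sol.face_velocity[d]
        sl0 = [slice(None)] * 3
        sl0[d] = slice(0, -1)
        sl1 = [slice(None)] * 3
        sl1[d] = slice(1, None)
        comps.append(0.5 * (F[tuple(sl0)] + F[tuple(sl1)]))
    speed = np.sqrt(sum(c * c for c in comps))
    return np.where(sol.domain.fluid_mask, speed, 0.0)


def mass_balance_report(sol: FlowSolution, domain: FlowDomain | None = None) -> dict:
    """Inlet/outlet volume fluxes (m^3/s) and worst cell divergence."""
    dom = domain or sol.domain
    h = dom.spacing
    nd = dom.shape
    influx = outflux = 0.0
    div = np.zeros(nd)
    for d in range(3):
        F = sol.face_velocity[d]
        ft = dom.face_type[d]
        # outward sign: + if the lower-adjacent cell is fluid (face points out)
        sl = [slice(None)] * 3
        sl[d] = slice(1, None)
        low_fluid = np.zeros(ft.shape, bool)
        low_fluid[tuple(sl)] = dom.fluid_mask
        sign = np.where(low_fluid, 1.0, -1.0)
        influx += float((-sign * F * h * h)[ft == INLET].sum())
        outflux += float((sign * F * h * h)[ft == OUTLET].sum())
        sl0 = [slice(None)] * 3
        sl0[d] = slice(0, -1)
        sl1 = [slice(None)] * 3
        sl1[d] = slice(1, None)
        div += (F[tuple(sl1)] - F[tuple(sl0)]) * h * h
    div = np.where(dom.fluid_mask, div, 0.0)
    rel = abs(influx - outflux) / abs(influx) if influx != 0 else 0.0
    report = {"inlet_flux": influx, "outlet_flux": outflux,
              "relative_imbalance": rel,
              "max_cell_divergence": float(np.abs(div).max())}
    log.info("mass balance: in %.4e out %.4e (rel imbalance %.2e)",
             influx, outflux, rel)
    return report
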