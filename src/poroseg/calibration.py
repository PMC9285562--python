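"""Single-voxel channel calibration of the porous-model constants.

A boundary voxel of edge ``d`` with porosity ``eps`` is modelled as a 2-D
channel whose fluid strip has height ``eps * d`` (the solid slab occupies
the rest).  Creeping flow through the strip — no-slip bottom wall, shear-free
top, fully developed half-parabolic inflow — has the plane-Poiseuille
pressure gradient

    dp/L = 3 mu v / (eps d)^2,

which in the shrunken-voxel non-dimensionalisation

    f_b = (dp/L) eps d / (rho v^2),      Re_b = eps rho v d / mu

collapses onto the single curve ``f_b = A / Re_b + B`` with A = 3 and a
negligible inertial constant B.  The packed-bed-voxel non-dimensionalisation
of the same pressure drops does *not* collapse across porosities, which is
why the shrunken-voxel law is the one used for segmentation.

The numeric pressure drops reuse the 3-D staggered-grid Stokes solver
restricted to a single cell layer; the solid slab is excluded from the mesh.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .flow import FaceSelector, FlowDomain, SolverConfig, _classify_faces, \
    solve_creeping_flow, INLET, OUTLET, SYMMETRY, WALL
from .porous import FluidProps, FLUID_PRESETS

#: Reduced default campaign: a subset of the full 4-height x 10-porosity x
#: 15-velocity sweep; the friction relation is exact, not statistical, so a
#: small grid identifies the constants equally well.
DEFAULT_HEIGHTS_MM = (0.25, 1.0)
DEFAULT_POROSITIES = (0.3, 0.5, 0.7, 0.9)
DEFAULT_VELOCITIES = tuple(np.geomspace(5e-4, 4.0, 4))


@dataclass(frozen=True)
class ChannelCase:
    """One voxel-channel flow case.

    ``d`` is the voxel height (m), ``eps`` its porosity, ``v_in`` the mean
    inlet (physical) velocity (m/s); ``d_a`` is the voxel depth used only by
    the packed-bed non-dimensionalisation (defaults to ``d``).
    """

    d: float
    eps: float
    v_in: float
    fluid: FluidProps
    d_a: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.eps <= 1:
            raise ValueError("porosity must lie in (0, 1]")
        if self.d <= 0 or self.v_in <= 0:
            raise ValueError("voxel height and inlet velocity must be positive")

    @property
    def fluid_height(self) -> float:
        """Height of the fluid strip, eps * d."""
        return self.eps * self.d

    @property
    def solid_height(self) -> float:
        return (1.0 - self.eps) * self.d

    @property
    def depth(self) -> float:
        return self.d if self.d_a is None else self.d_a


@dataclass(frozen=True)
class FrictionPoint:
    """A (friction factor, bed Reynolds number) pair with provenance."""

    f_b: float
    re_b: float
    eps: float
    d: float
    v_in: float

    def __post_init__(self) -> None:
        if self.f_b <= 0 or self.re_b <= 0:
            raise ValueError("friction factor and Reynolds number must be positive")


@dataclass(frozen=True)
class FitResult:
    """Least-squares constants of ``f_b = A / Re_b + B``."""

    A: float
    B: float
    rms_residual: float
    n_points: int


def channel_pressure_drop_analytic(case: ChannelCase) -> float:
    """Plane-Poiseuille pressure gradient ``3 mu v / (eps d)^2`` (Pa/m).

    Closed form for a channel of height ``eps*d`` with a no-slip bottom and
    a shear-free top at mean velocity ``v``; the oracle for the numeric
    solver.
    """
    if case.eps == 0:
        raise ValueError("porosity zero leaves no fluid strip")
    h = case.fluid_height
    return 3.0 * case.fluid.mu * case.v_in / (h * h)


def _half_parabola(v_mean: float, heights: np.ndarray, H: float) -> np.ndarray:
    """Fully developed half-parabolic profile, zero at the wall, max at top."""
    eta = heights / H
    return 1.5 * v_mean * (2.0 * eta - eta * eta)


def channel_pressure_drop_numeric(case: ChannelCase, resolution: int = 64,
                                  length_factor: float = 1.0,
                                  tol: float = 1e-8) -> float:
    """Streamwise pressure gradient from a 2-D creeping-flow solve (Pa/m).

    The fluid strip (height ``eps*d``) is meshed with ``resolution`` square
    cells across; boundary conditions are a no-slip bottom wall, a symmetry
    (shear-free) top, the half-parabolic profile at the inlet and zero
    pressure at the outlet.  The gradient is the least-squares slope of the
    column-averaged pressure.
    """
    if resolution < 8:
        raise ValueError("need at least 8 cells across the fluid strip")
    H = case.fluid_height
    ny = int(resolution)
    h = H / ny
    nx = max(int(round(length_factor * ny)), 8)
    mask = np.ones((nx, ny, 1), bool)

    ycell = (np.arange(ny) + 0.5) * h
    profile = _half_parabola(case.v_in, ycell, H)[:, None]  # (ny, 1) plane

    labelled = [(INLET, FaceSelector("x-")), (OUTLET, FaceSelector("x+")),
                (SYMMETRY, FaceSelector("y+")), (SYMMETRY, FaceSelector("z-")),
                (SYMMETRY, FaceSelector("z+"))]
    ftype = _classify_faces(mask, labelled)
    dom = FlowDomain(mask, np.zeros(mask.shape), h, ftype)
    cfg = SolverConfig(inlet_speed=case.v_in, inlet_profile=profile, tol=tol)
    sol = solve_creeping_flow(dom, case.fluid, cfg)

    pcol = sol.pressure[:, :, 0].mean(axis=1)
    x = (np.arange(nx) + 0.5) * h
    slope = np.polyfit(x, pcol, 1)[0]
    dpdl = -float(slope)
    if dpdl <= 0:
        raise RuntimeError("non-positive pressure gradient; solve did not converge")
    return dpdl


def friction_point_shrunken(case: ChannelCase, dpdl: float) -> FrictionPoint:
    """Shrunken-voxel non-dimensionalisation of a channel pressure drop.

    ``f_b = (dp/L) eps d / (rho v^2)`` and ``Re_b = eps rho v d / mu``; with
    these definitions the viscous law implies ``f_b * Re_b = A`` exactly.
    """
    if dpdl <= 0:
        raise ValueError("pressure gradient must be positive")
    f = case.fluid
    fb = dpdl * case.eps * case.d / (f.rho * case.v_in ** 2)
    reb = case.eps * f.rho * case.v_in * case.d / f.mu
    return FrictionPoint(fb, reb, case.eps, case.d, case.v_in)


def friction_point_packed(case: ChannelCase, dpdl: float) -> FrictionPoint:
    """Packed-bed-voxel non-dimensionalisation of the same pressure drop.

    Uses ``f_b = (dp/L) eps^2 (d^2 d_a)^{1/3} / (rho v^2 (1-eps)^{2/3})``
    and ``Re_b = rho v (d^2 d_a)^{1/3} / mu``.  Degenerate at eps = 1.
    Points from different porosities do not collapse onto one curve under
    this scaling — the diagnostic that rules the packed-bed model out.
    """
    if dpdl <= 0:
        raise ValueError("pressure gradient must be positive")
    if case.eps >= 1:
        raise ValueError("packed-bed form is degenerate at eps = 1")
    f = case.fluid
    dchar = (case.d ** 2 * case.depth) ** (1.0 / 3.0)
    fb = dpdl * case.eps ** 2 * dchar / (f.rho * case.v_in ** 2 *
                                         (1.0 - case.eps) ** (2.0 / 3.0))
    reb = f.rho * case.v_in * dchar / f.mu
    return FrictionPoint(fb, reb, case.eps, case.d, case.v_in)


def fit_ergun_constants(points: list[FrictionPoint]) -> FitResult:
    """Unweighted least squares of ``f_b = A / Re_b + B``."""
    if len(points) < 2:
        raise ValueError("need at least two friction points")
    reb = np.array([p.re_b for p in points])
    fb = np.array([p.f_b for p in points])
    if np.unique(reb).size < 2:
        raise ValueError("all Re_b identical: rank-deficient fit")
    X = np.column_stack([1.0 / reb, np.ones_like(reb)])
    coef, *_ = np.linalg.lstsq(X, fb, rcond=None)
    resid = fb - X @ coef
    return FitResult(float(coef[0]), float(coef[1]),
                     float(np.sqrt(np.mean(resid ** 2))), len(points))


def collapse_diagnostic(points: list[FrictionPoint]) -> dict:
    """Spread of the per-porosity fitted viscous constant A.

    Groups the points by porosity, fits ``f_b = A/Re_b + B`` per group and
    returns the coefficient of variation of A across groups: ~0 when the
    non-dimensionalisation collapses all porosities onto one curve, large
    when it does not.
    """
    groups: dict[float, list[FrictionPoint]] = {}
    for p in points:
        groups.setdefault(round(p.eps, 12), []).append(p)
    if len(groups) < 3:
        raise ValueError("need at least three porosity groups")
    a_values = {e: fit_ergun_constants(g).A for e, g in sorted(groups.items())}
    arr = np.array(list(a_values.values()))
    return {"cv": float(arr.std() / arr.mean()), "per_group_A": a_values}


def run_campaign(heights_m=None, porosities=None, velocities=None,
                 fluid: FluidProps | None = None, resolution: int = 64,
                 analytic: bool = False, depth_m: float | None = None
                 ) -> tuple[pd.DataFrame, FitResult]:
    """Run the channel campaign and fit the shrunken-voxel constants.

    Returns one row per case (d, eps, v, dp/L and both non-dimensionalised
    points) plus the shrunken-model :class:`FitResult`.  ``analytic=True``
    uses the closed-form pressure drops (exact recovery of A = 3);
    otherwise each case is solved numerically.
    """
    heights = [h * 1e-3 for h in DEFAULT_HEIGHTS_MM] if heights_m is None else list(heights_m)
    porosities = DEFAULT_POROSITIES if porosities is None else porosities
    velocities = DEFAULT_VELOCITIES if velocities is None else velocities
    fluid = fluid or FLUID_PRESETS["unit"]
    rows = []
    for d in heights:
        for eps in porosities:
            for v in velocities:
                case = ChannelCase(d=d, eps=eps, v_in=v, fluid=fluid, d_a=depth_m)
                dpdl = (channel_pressure_drop_analytic(case) if analytic
                        else channel_pressure_drop_numeric(case, resolution))
                ps = friction_point_shrunken(case, dpdl)
                pp = friction_point_packed(case, dpdl) if eps < 1 else None
                rows.append({"d_m": d, "eps": eps, "v_in": v, "dpdl": dpdl,
                             "fb_shrunken": ps.f_b, "reb_shrunken": ps.re_b,
                             "fb_packed": pp.f_b if pp else np.nan,
                             "reb_packed": pp.re_b if pp else np.nan})
    df = pd.DataFrame(rows)
    pts = [FrictionPoint(r.fb_shrunken, r.reb_shrunken, r.eps, r.d_m, r.v_in)
           for r in df.itertuples()]
    return df, fit_ergun_constants(pts)


def friction_points_from_frame(df: pd.DataFrame, model: str = "shrunken"
                               ) -> list[FrictionPoint]:
    """Rebuild :class:`FrictionPoint` lists from a campaign table."""
    fb, reb = f"fb_{model}", f"reb_{model}"
    out = []
    for r in df.itertuples():
        f, re = getattr(r, fb), getattr(r, reb)
        if np.isfinite(f) and np.isfinite(re):
            out.append(FrictionPoint(f, re, r.eps, r.d_m, r.v_in))
    return out
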