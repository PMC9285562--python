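"""Velocity iso-surface sweep, spherical-model indicator and selection.

The computed speed field varies smoothly across the porous boundary, so the
object surface is recovered as a velocity-magnitude iso-surface.  To choose
the iso-value automatically the segmented volume V and area A at each level
are matched to a model sphere,

    (4/3) pi (R0 + dR)^3 = V,        2 pi (r0 + dr)^2 = A,

with R0, r0 fixed by a reference iso-value (one order of magnitude below the
inlet speed for compact objects; the inlet speed itself for complex ones).
The area relation keeps the ``2 pi`` prefactor of the original formulation;
the constant rescales r0 and dr jointly and moves no plateau or inflexion.
Plotting dR and dr against the (log) iso-value shows a plateau where the
surface is insensitive to the threshold; the plateau's end (or its start,
when coarse thresholding removed the background and no terminal upturn
exists) is the selected segmentation value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree

#: Default iso-value sweep bounds (m/s).
DEFAULT_SWEEP_BOUNDS = (1e-14, 1e-6)
DEFAULT_SWEEP_POINTS = 33

#: Floor applied before taking log10 of the speed for interpolation.
_LOG_FLOOR = 1e-250


class EmptySurfaceError(ValueError):
    """Raised when an iso-value exceeds the field maximum."""


@dataclass
class SurfaceMesh:
    """A triangulated surface in world millimetres."""

    vertices: np.ndarray  # (n, 3) mm
    triangles: np.ndarray  # (m, 3) int
    n_components: int = 1

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        self._tm = trimesh.Trimesh(self.vertices, self.triangles, process=False)

    @property
    def area(self) -> float:
        """Total surface area, mm^2."""
        return float(self._tm.area)

    @property
    def volume(self) -> float:
        """Enclosed volume by the divergence theorem, mm^3 (unsigned)."""
        return abs(float(self._tm.volume))

    @property
    def watertight(self) -> bool:
        return bool(self._tm.is_watertight)

    def as_trimesh(self) -> trimesh.Trimesh:
        return self._tm


@dataclass
class IsoSweep:
    """Volume, area and component count per iso-value (ascending)."""

    iso_values: np.ndarray
    volumes: np.ndarray  # mm^3
    areas: np.ndarray  # mm^2
    component_counts: np.ndarray


@dataclass
class IndicatorCurve:
    """Model-sphere radius changes dR (volume) and dr (area) per iso-value."""

    iso_values: np.ndarray
    dR: np.ndarray  # mm
    dr: np.ndarray  # mm
    R0: float
    r0: float
    iso0: float


@dataclass
class SelectionResult:
    """Chosen iso-value with the detection method and diagnostics."""

    chosen_iso: float
    method: str  # plateau-inflexion | plateau-start | user-override
    diagnostics: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# iso-surface extraction
# ---------------------------------------------------------------------------

def extract_isosurface(speed: np.ndarray, iso: float, spacing, origin=(0, 0, 0),
                       log_interp: bool = False,
                       largest_component: bool = True) -> SurfaceMesh:
    """Marching-cubes surface of ``speed >= iso`` in world millimetres.

    The field is zero-padded by one voxel so surfaces touching the grid
    boundary close; vertex positions account for the pad.  With
    ``log_interp`` the marching cubes runs on log10(speed): the level sets
    are identical but edge interpolation becomes accurate when the speed
    decays exponentially across the porous boundary.
    """
    from skimage import measure

    spacing = np.asarray(spacing, dtype=float).reshape(3)
    origin = np.asarray(origin, dtype=float).reshape(3)
    speed = np.asarray(speed, dtype=float)
    if iso <= 0:
        raise ValueError("iso value must be positive")
    if iso >= speed.max():
        raise EmptySurfaceError(f"iso {iso:g} is above the field maximum "
                                f"{speed.max():g}")
    field_ = np.pad(speed, 1)
    level = float(iso)
    if log_interp:
        field_ = np.log10(np.maximum(field_, _LOG_FLOOR))
        level = float(np.log10(iso))
    verts, faces_, *_ = measure.marching_cubes(field_, level=level,
                                               spacing=tuple(spacing))
    verts = verts + (origin - spacing)  # undo the one-voxel pad
    mesh = SurfaceMesh(verts, faces_)
    n_comp = int(mesh.as_trimesh().body_count)
    if largest_component and n_comp > 1:
        pieces = mesh.as_trimesh().split(only_watertight=False)
        best = max(pieces, key=lambda m: (abs(m.volume), m.area))
        mesh = SurfaceMesh(np.asarray(best.vertices), np.asarray(best.faces))
    mesh.n_components = n_comp if not largest_component else 1
    return mesh


def iso_sweep(speed: np.ndarray, iso_values, spacing, origin=(0, 0, 0),
              log_interp: bool = False) -> IsoSweep:
    """Volume/area/component count for each iso-value (sorted ascending)."""
    iso_values = np.sort(np.asarray(iso_values, dtype=float))
    if np.any(iso_values <= 0):
        raise ValueError("iso values must be positive")
    vols, areas, counts = [], [], []
    for iso in iso_values:
        try:
            m = extract_isosurface(speed, iso, spacing, origin,
                                   log_interp=log_interp, largest_component=False)
        except EmptySurfaceError:
            vols.append(0.0)
            areas.append(0.0)
            counts.append(0)
            continue
        vols.append(m.volume)
        areas.append(m.area)
        counts.append(int(m.as_trimesh().body_count))
    return IsoSweep(iso_values, np.asarray(vols), np.asarray(areas),
                    np.asarray(counts))


def indicator_curve(sweep: IsoSweep, iso0: float) -> IndicatorCurve:
    """Spherical-model radius changes relative to the reference iso-value.

    ``R0 = (3 V(iso0) / 4 pi)^(1/3)`` and ``r0 = sqrt(A(iso0) / 2 pi)``;
    dR and dr are the radius changes needed to match each sweep volume/area.
    """
    i0 = np.flatnonzero(np.isclose(sweep.iso_values, iso0, rtol=1e-9))
    if i0.size == 0:
        raise ValueError(f"reference iso {iso0:g} is not in the sweep")
    i0 = int(i0[0])
    V0, A0 = sweep.volumes[i0], sweep.areas[i0]
    if V0 <= 0 or A0 <= 0:
        raise ValueError("zero volume/area at the reference iso-value")
    R0 = (3.0 * V0 / (4.0 * np.pi)) ** (1.0 / 3.0)
    r0 = np.sqrt(A0 / (2.0 * np.pi))
    dR = (3.0 * sweep.volumes / (4.0 * np.pi)) ** (1.0 / 3.0) - R0
    dr = np.sqrt(sweep.areas / (2.0 * np.pi)) - r0
    return IndicatorCurve(sweep.iso_values.copy(), dR, dr, float(R0), float(r0),
                          float(iso0))


def select_iso(curve: IndicatorCurve, indicator: str = "dR",
               slope_fraction: float = 0.05, min_run: int = 2,
               override: float | None = None) -> SelectionResult:
    """Detect the plateau of the indicator curve and pick the iso-value.

    Slopes are measured against log10(iso); segments with slope magnitude
    below ``slope_fraction`` of the maximum slope form the plateau.  When
    segments below the plateau (lower iso) still change rapidly — noise
    flooding in — the plateau's low-iso end (the inflexion) is returned;
    when the curve stays flat to the bottom of the sweep the plateau start
    (its high-iso edge) is returned instead.
    """
    if override is not None:
        return SelectionResult(float(override), "user-override",
                               {"note": "user supplied iso-value"})
    if curve.iso_values.size < 8:
        raise ValueError("need at least 8 sweep points to detect a plateau")
    y = {"dR": curve.dR, "dr": curve.dr}[indicator]
    x = np.log10(curve.iso_values)
    slopes = np.abs(np.diff(y) / np.diff(x))
    smax = slopes.max()
    if smax == 0:
        raise ValueError("indicator curve is entirely flat: no plateau "
                         "boundary; choose the iso-value manually")
    thr = slope_fraction * smax
    low = slopes < thr
    # maximal runs of consecutive low-slope segments
    runs = []
    start = None
    for i, flag in enumerate(np.append(low, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_run:
                runs.append((start, i - 1))
            start = None
    if not runs:
        raise ValueError("no plateau found in the indicator curve; "
                         "choose the iso-value manually")
    # tie-break: the plateau whose low-iso end is lowest
    run = min(runs, key=lambda r: r[0])
    lo_seg, hi_seg = run
    upturn = bool(np.any(slopes[:lo_seg] >= thr))
    iso_low_edge = float(curve.iso_values[lo_seg])
    iso_high_edge = float(curve.iso_values[hi_seg + 1])
    if upturn:
        chosen, method = iso_low_edge, "plateau-inflexion"
    else:
        chosen, method = iso_high_edge, "plateau-start"
    diag = {"indicator": indicator, "slope_threshold": float(thr),
            "max_slope": float(smax), "plateau_low_edge": iso_low_edge,
            "plateau_high_edge": iso_high_edge, "terminal_upturn": upturn,
            "n_plateaus": len(runs)}
    return SelectionResult(chosen, method, diag)


# ---------------------------------------------------------------------------
# cloud-to-mesh distance
# ---------------------------------------------------------------------------

def _closest_dist_point_triangle(p: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Paired point-triangle distances; ``p`` (n,3), ``tri`` (n,3,3)."""
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = p - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = p - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)
    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    closest = np.empty_like(p)
    done = np.zeros(len(p), bool)

    def assign(mask, pts):
        m = mask & ~done
        closest[m] = pts[m] if pts.ndim == 2 else pts
        done[m] = True

    assign((d1 <= 0) & (d2 <= 0), a)
    assign((d3 >= 0) & (d4 <= d3), b)
    assign((d6 >= 0) & (d5 <= d6), c)
    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = np.where(d1 - d3 != 0, d1 / (d1 - d3), 0.0)
        assign((vc <= 0) & (d1 >= 0) & (d3 <= 0), a + ab * v_ab[:, None])
        v_ac = np.where(d2 - d6 != 0, d2 / (d2 - d6), 0.0)
        assign((vb <= 0) & (d2 >= 0) & (d6 <= 0), a + ac * v_ac[:, None])
        den_bc = (d4 - d3) + (d5 - d6)
        v_bc = np.where(den_bc != 0, (d4 - d3) / den_bc, 0.0)
        assign((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0),
               b + (c - b) * v_bc[:, None])
        denom = va + vb + vc
        denom = np.where(denom != 0, denom, 1.0)
        v = vb / denom
        w = vc / denom
        assign(np.ones(len(p), bool), a + ab * v[:, None] + ac * w[:, None])
    return np.linalg.norm(p - closest, axis=1)


def point_mesh_distances(points: np.ndarray, mesh: SurfaceMesh,
                         chunk: int = 4096) -> np.ndarray:
    """Unsigned distance from each point to the nearest mesh triangle.

    Candidate triangles come from a k-d tree on triangle centroids; an exact
    refinement pass widens the candidate set by the largest triangle radius,
    so the result is the true minimum distance.
    """
    points = np.asarray(points, dtype=float)
    tri = mesh.vertices[mesh.triangles]  # (m, 3, 3)
    centroids = tri.mean(axis=1)
    rmax = float(np.linalg.norm(tri - centroids[:, None, :], axis=2).max())
    tree = cKDTree(centroids)
    out = np.empty(len(points))
    for s in range(0, len(points), chunk):
        pts = points[s:s + chunk]
        _, nearest = tree.query(pts, k=1)
        upper = _closest_dist_point_triangle(pts, tri[nearest])
        groups = tree.query_ball_point(pts, upper + rmax + 1e-12)
        lens = np.array([len(gr) for gr in groups])
        flat = np.concatenate([np.asarray(gr) for gr in groups])
        rep = np.repeat(np.arange(len(pts)), lens)
        d = _closest_dist_point_triangle(pts[rep], tri[flat])
        best = np.full(len(pts), np.inf)
        np.minimum.at(best, rep, d)
        out[s:s + chunk] = np.minimum(best, upper)
    return out


def cloud_to_mesh_distance(test: SurfaceMesh, reference: SurfaceMesh,
                           pixel_size_mm: float) -> dict:
    """Cloud-to-mesh distance statistics normalised by pixel size.

    For every vertex of ``test`` the unsigned distance to the nearest point
    on any ``reference`` triangle is computed; mean, max and standard
    deviation are reported in units of the original in-plane pixel size.
    """
    if len(test.vertices) == 0 or len(reference.triangles) == 0:
        raise ValueError("empty mesh")
    if pixel_size_mm <= 0:
        raise ValueError("pixel size must be positive")
    d = point_mesh_distances(test.vertices, reference) / pixel_size_mm
    return {"mean": float(d.mean()), "max": float(d.max()),
            "sd": float(d.std()), "n_vertices": int(len(d))}


def export_surface(mesh: SurfaceMesh, path, file_format: str | None = None) -> Path:
    """Write STL (binary), PLY or OBJ; round-trips preserve geometry."""
    path = Path(path)
    fmt = (file_format or path.suffix.lstrip(".")).lower()
    if fmt not in {"stl", "ply", "obj"}:
        raise ValueError(f"unsupported surface format {fmt!r}")
    mesh.as_trimesh().export(str(path), file_type=fmt)
    return path


def load_surface(path) -> SurfaceMesh:
    """Read a surface mesh back (STL/PLY/OBJ)."""
    tm = trimesh.load(str(path), process=False, force="mesh")
    return SurfaceMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
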