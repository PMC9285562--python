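"""Ground-truthed volumetric phantoms with partial-volume rendering.

Phantoms are unions of analytic solids (spheres, capsules, torus segments)
describing the fluid region of a vessel or airway.  Each voxel's fluid
fraction is estimated by stratified sub-sampling of the signed distance
function — the same partial-volume averaging that real scanners produce at
tissue boundaries — and intensity follows the linear blend
``I = I_s + eps (I_f - I_s)``.  Optional slice-thickness blur (applied
first, acquisition order), additive Gaussian noise and speckle blobs
emulate the noise floor of clinical CT; a fixed seed makes every phantom
bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, asdict

import numpy as np
import yaml
from scipy import ndimage

from .imagepre import VolumetricImage
from .porous import ConversionSpec, render_intensity_from_porosity
from .segmentation import SurfaceMesh


# ---------------------------------------------------------------------------
# analytic primitives (signed distance to the fluid boundary; inside < 0)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return np.linalg.norm(pts - np.asarray(self.center), axis=-1) - self.radius


@dataclass(frozen=True)
class Capsule:
    """Cylinder with hemispherical end caps between two points (a tube)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip(((pts - a) @ ab) / denom, 0.0, 1.0) if denom > 0 else 0.0
        closest = a + np.multiply.outer(t, ab)
        return np.linalg.norm(pts - closest, axis=-1) - self.radius


@dataclass(frozen=True)
class TorusSegment:
    """Circular-arc tube: centre-circle of radius R in the z-normal plane,
    tube radius r, arc between angles (rad); capped with spherical ends."""

    center: tuple[float, float, float]
    ring_radius: float
    tube_radius: float
    angle_start: float = 0.0
    angle_end: float = 2.0 * np.pi

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        rel = pts - np.asarray(self.center)
        phi = np.arctan2(rel[..., 1], rel[..., 0])
        # wrap into the arc range, then clamp
        span = self.angle_end - self.angle_start
        phi = np.mod(phi - self.angle_start, 2.0 * np.pi)
        phi = np.clip(phi, 0.0, span) + self.angle_start
        ring = np.stack([self.ring_radius * np.cos(phi),
                         self.ring_radius * np.sin(phi),
                         np.zeros_like(phi)], axis=-1)
        return np.linalg.norm(rel - ring, axis=-1) - self.tube_radius


_PRIMITIVES = {"sphere": Sphere, "capsule": Capsule, "torus": TorusSegment}
_PRIMITIVE_NAMES = {v: k for k, v in _PRIMITIVES.items()}


@dataclass
class PhantomSpec:
    """Geometry, intensities, grid and noise parameters of a phantom."""

    primitives: list
    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]  # mm, may be anisotropic
    i_fluid: float = 200.0
    i_solid: float = 0.0
    noise_sd: float = 0.0
    slice_blur_sigma_z: float = 0.0  # mm
    speckle_count: int = 0
    speckle_radius_mm: float = 1.0
    speckle_amplitude: float = 0.0
    seed: int = 0

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        """Signed distance to the union fluid boundary (inside < 0)."""
        if not self.primitives:
            raise ValueError("phantom has no primitives")
        d = self.primitives[0].sdf(pts)
        for prim in self.primitives[1:]:
            d = np.minimum(d, prim.sdf(pts))
        return d

    def conversion(self) -> ConversionSpec:
        return ConversionSpec(self.i_fluid, self.i_solid)

    def to_yaml(self) -> str:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.floating):
                return float(obj)
            if isinstance(obj, np.integer):
                return int(obj)
            return obj

        doc = plain(asdict(self))
        doc["primitives"] = [
            {"kind": _PRIMITIVE_NAMES[type(p)], **plain(asdict(p))}
            for p in self.primitives]
        return yaml.safe_dump(doc, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PhantomSpec":
        doc = yaml.safe_load(text)
        prims = []
        for p in doc.pop("primitives"):
            kind = p.pop("kind")
            p = {k: tuple(v) if isinstance(v, list) else v for k, v in p.items()}
            prims.append(_PRIMITIVES[kind](**p))
        doc["shape"] = tuple(doc["shape"])
        doc["spacing"] = tuple(doc["spacing"])
        return cls(primitives=prims, **doc)


@dataclass
class GroundTruth:
    """Exact reference for a phantom: SDF plus a finely tessellated mesh."""

    spec: PhantomSpec
    mesh: SurfaceMesh
    analytic_volume: float | None = None

    def sdf(self, pts: np.ndarray) -> np.ndarray:
        return self.spec.sdf(pts)


def _voxel_centres(spec: PhantomSpec) -> tuple[np.ndarray, ...]:
    axes = [np.arange(n) * s for n, s in zip(spec.shape, spec.spacing)]
    return tuple(axes)


def voxelize_partial_volume(spec: PhantomSpec, supersampling: int = 3) -> np.ndarray:
    """Per-voxel fluid fraction by stratified sub-sampling of the SDF.

    Voxels whose centre SDF magnitude exceeds half the voxel diagonal are
    exactly 0 or 1; boundary voxels average ``n^3`` sub-cell midpoints.
    """
    n = int(supersampling)
    if n < 2:
        raise ValueError("supersampling must be at least 2 per axis")
    sp = np.asarray(spec.spacing, dtype=float)
    ax = _voxel_centres(spec)
    centres = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
    phi = spec.sdf(centres)
    half_diag = 0.5 * float(np.linalg.norm(sp))
    eps = np.where(phi <= -half_diag, 1.0, 0.0)
    boundary = np.abs(phi) < half_diag
    if boundary.any():
        idx = np.argwhere(boundary)
        # sub-cell midpoints (stratified, deterministic)
        off = (np.arange(n) + 0.5) / n - 0.5
        offs = np.stack(np.meshgrid(off, off, off, indexing="ij"), -1).reshape(-1, 3)
        pts = (idx[:, None, :] + offs[None, :, :]) * sp
        frac = (spec.sdf(pts) < 0).mean(axis=1)
        eps[tuple(idx.T)] = frac
    return eps


def render_intensity(eps: np.ndarray, spec: PhantomSpec) -> VolumetricImage:
    """Intensity from porosity, then slice blur, speckle and noise.

    The blur acts along z only (slice-thickness smearing); speckle blobs are
    small random spheres of offset intensity; Gaussian noise is added last.
    All randomness comes from ``spec.seed``.
    """
    data = render_intensity_from_porosity(eps, spec.conversion()).astype(float)
    rng = np.random.default_rng(spec.seed)
    if spec.slice_blur_sigma_z > 0:
        data = ndimage.gaussian_filter1d(
            data, sigma=spec.slice_blur_sigma_z / spec.spacing[2], axis=2,
            mode="nearest")
    if spec.speckle_count > 0 and spec.speckle_amplitude != 0:
        sp = np.asarray(spec.spacing)
        extent = (np.asarray(spec.shape) - 1) * sp
        centres = rng.uniform(0, 1, (spec.speckle_count, 3)) * extent
        signs = rng.choice([-1.0, 1.0], spec.speckle_count)
        ax = _voxel_centres(spec)
        grid = np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)
        for c, s in zip(centres, signs):
            blob = np.linalg.norm(grid - c, axis=-1) <= spec.speckle_radius_mm
            data[blob] += s * spec.speckle_amplitude
    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, data.shape)
    return VolumetricImage(data, np.asarray(spec.spacing))


def ground_truth_mesh(spec: PhantomSpec, refine: int = 2) -> SurfaceMesh:
    """Marching-cubes mesh of the SDF zero level on a refined grid."""
    from skimage import measure

    sp = np.asarray(spec.spacing) / refine
    shape = tuple((np.asarray(spec.shape) - 1) * refine + 1)
    ax = [np.arange(n) * s for n, s in zip(shape, sp)]
    phi = spec.sdf(np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1))
    phi = np.pad(phi, 1, constant_values=phi.max() + 1.0)
    verts, faces, *_ = measure.marching_cubes(phi, level=0.0, spacing=tuple(sp))
    return SurfaceMesh(verts - sp, faces)


def _render(spec: PhantomSpec, supersampling: int) -> VolumetricImage:
    return render_intensity(voxelize_partial_volume(spec, supersampling), spec)


def aneurysm_phantom(tube_radius_mm: float, sac_radius_mm: float,
                     neck_offset_mm: float, shape=(64, 64, 64),
                     spacing_mm: float = 0.5, i_fluid: float = 200.0,
                     i_solid: float = 0.0, noise_sd: float = 10.0,
                     slice_blur_sigma_z: float = 0.0, seed: int = 0,
                     supersampling: int = 3, refine: int = 2,
                     **noise_kwargs) -> tuple[VolumetricImage, GroundTruth]:
    """Sphere-on-tube phantom: a parent vessel with a saccular aneurysm.

    The tube runs along x through the whole grid (open at both x faces, so
    the lumen forms the inlet/outlet); the sac sphere sits ``neck_offset``
    from the tube axis at mid-length.  With the default noise sd the
    contrast-to-noise ratio is ``(i_fluid - i_solid) / noise_sd``.
    """
    shape = tuple(int(n) for n in shape)
    extent = (np.asarray(shape) - 1) * spacing_mm
    if tube_radius_mm < 2 * spacing_mm:
        raise ValueError("tube radius must span at least two voxels")
    cy, cz = extent[1] / 2, extent[2] / 2
    margin = 10.0 * spacing_mm
    prims: list = [Capsule((-margin, cy, cz), (extent[0] + margin, cy, cz),
                           tube_radius_mm)]
    if sac_radius_mm > 0:
        if sac_radius_mm < 2 * spacing_mm:
            raise ValueError("sac radius must span at least two voxels")
        if neck_offset_mm >= tube_radius_mm + sac_radius_mm:
            raise ValueError("sac is disconnected from the tube")
        prims.append(Sphere((extent[0] / 2, cy + neck_offset_mm, cz),
                            sac_radius_mm))
    spec = PhantomSpec(primitives=prims, shape=shape,
                       spacing=(spacing_mm,) * 3, i_fluid=i_fluid,
                       i_solid=i_solid, noise_sd=noise_sd,
                       slice_blur_sigma_z=slice_blur_sigma_z, seed=seed,
                       **noise_kwargs)
    img = _render(spec, supersampling)
    gt = GroundTruth(spec, ground_truth_mesh(spec, refine))
    return img, gt


def channel_phantom(channel_radius_mm: float = 1.5, wall_gap_mm: float = 1.0,
                    shape=(48, 32, 32), spacing_mm: float = 0.5,
                    i_fluid: float = 200.0, i_solid: float = 0.0,
                    noise_sd: float = 0.0, seed: int = 0,
                    supersampling: int = 3) -> tuple[VolumetricImage, GroundTruth]:
    """Two parallel narrow channels separated by a thin solid wall."""
    shape = tuple(int(n) for n in shape)
    extent = (np.asarray(shape) - 1) * spacing_mm
    cz = extent[2] / 2
    cy = extent[1] / 2
    off = channel_radius_mm + wall_gap_mm / 2
    margin = 10.0 * spacing_mm
    prims = [Capsule((-margin, cy - off, cz), (extent[0] + margin, cy - off, cz),
                     channel_radius_mm),
             Capsule((-margin, cy + off, cz), (extent[0] + margin, cy + off, cz),
                     channel_radius_mm)]
    spec = PhantomSpec(primitives=prims, shape=shape, spacing=(spacing_mm,) * 3,
                       i_fluid=i_fluid, i_solid=i_solid, noise_sd=noise_sd,
                       seed=seed)
    return _render(spec, supersampling), GroundTruth(spec, ground_truth_mesh(spec))


def bifurcation_phantom(parent_radius_mm: float = 2.0,
                        branch_radius_mm: float = 1.5, shape=(48, 48, 32),
                        spacing_mm: float = 0.5, i_fluid: float = 200.0,
                        i_solid: float = 0.0, noise_sd: float = 0.0,
                        seed: int = 0, supersampling: int = 3
                        ) -> tuple[VolumetricImage, GroundTruth]:
    """Symmetric Y bifurcation: parent enters at x-, branches exit at x+."""
    shape = tuple(int(n) for n in shape)
    extent = (np.asarray(shape) - 1) * spacing_mm
    cy, cz = extent[1] / 2, extent[2] / 2
    xm = extent[0] / 2
    margin = 10.0 * spacing_mm
    span = extent[1] / 2 - 2.0 * branch_radius_mm
    prims = [Capsule((-margin, cy, cz), (xm, cy, cz), parent_radius_mm),
             Capsule((xm, cy, cz), (extent[0] + margin, cy + span, cz),
                     branch_radius_mm),
             Capsule((xm, cy, cz), (extent[0] + margin, cy - span, cz),
                     branch_radius_mm)]
    spec = PhantomSpec(primitives=prims, shape=shape, spacing=(spacing_mm,) * 3,
                       i_fluid=i_fluid, i_solid=i_solid, noise_sd=noise_sd,
                       seed=seed)
    return _render(spec, supersampling), GroundTruth(spec, ground_truth_mesh(spec))


def capsule_sphere_union_volume(capsule: Capsule, sphere: Sphere) -> float:
    """Closed-form union volume when the sphere sits coaxially past one end.

    Valid when the sphere centre lies on the capsule axis beyond an end
    point: the overlap is exactly the two-sphere lens between the sac and
    the end-cap sphere (spherical-cap correction).
    """
    a = np.asarray(capsule.p0, dtype=float)
    b = np.asarray(capsule.p1, dtype=float)
    L = float(np.linalg.norm(b - a))
    r, R = capsule.radius, sphere.radius
    v_capsule = np.pi * r * r * L + 4.0 / 3.0 * np.pi * r ** 3
    v_sphere = 4.0 / 3.0 * np.pi * R ** 3
    dists = [float(np.linalg.norm(np.asarray(sphere.center) - e)) for e in (a, b)]
    d = min(dists)
    if d >= R + r:
        return v_capsule + v_sphere
    if d + 1e-12 < abs(R - r):
        raise ValueError("one body is contained in the other; no closed form")
    # lens volume of two intersecting spheres at centre distance d
    lens = (np.pi * (R + r - d) ** 2
            * (d * d + 2 * d * r - 3 * r * r + 2 * d * R + 6 * r * R - 3 * R * R)
            / (12.0 * d))
    return v_capsule + v_sphere - lens
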