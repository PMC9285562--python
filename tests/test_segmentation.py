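"""Iso-surface extraction, spherical-model indicator, selection and C2M."""

import numpy as np
import pytest

from poroseg.segmentation import (EmptySurfaceError, IndicatorCurve,
                                  SurfaceMesh, cloud_to_mesh_distance,
                                  export_surface, extract_isosurface,
                                  indicator_curve, iso_sweep, load_surface,
                                  select_iso)


@pytest.fixture(scope="module")
def radial_field():
    """Radially decreasing speed field exp(-r) on a 64^3 grid, 0.5 mm."""
    n, sp = 64, 0.5
    ax = np.arange(n) * sp
    g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
    r = np.linalg.norm(g - 16.0, axis=-1)
    return np.exp(-r), sp


class TestExtractIsosurface:
    def test_sphere_volume_closed_form(self, radial_field):
        f, sp = radial_field
        R = 10.0
        m = extract_isosurface(f, float(np.exp(-R)), (sp,) * 3)
        v_true = 4.0 / 3.0 * np.pi * R ** 3
        assert abs(m.volume - v_true) / v_true < 0.02
        assert m.watertight

    def test_iso_above_maximum_rejected(self, radial_field):
        f, sp = radial_field
        with pytest.raises(EmptySurfaceError):
            extract_isosurface(f, 2.0, (sp,) * 3)

    def test_small_component_near_maximum(self, radial_field):
        f, sp = radial_field
        m = extract_isosurface(f, float(f.max()) * 0.999, (sp,) * 3)
        assert m.watertight
        assert m.volume < 1.0  # tight blob around the peak

    def test_volume_agrees_with_voxel_count(self, radial_field):
        """Divergence-theorem volume vs voxel counting within a shell."""
        f, sp = radial_field
        iso = float(np.exp(-10.0))
        m = extract_isosurface(f, iso, (sp,) * 3)
        nvox = int((f >= iso).sum())
        # the two estimates differ at most by a one-voxel boundary shell,
        # whose size is bounded by surface area in voxel units
        area_vox = m.area / sp ** 2
        assert abs(m.volume / sp ** 3 - nvox) <= area_vox

    def test_world_coordinates(self):
        """Vertices land at origin + spacing * index positions."""
        f = np.zeros((8, 8, 8))
        f[3:5, 3:5, 3:5] = 1.0
        m = extract_isosurface(f, 0.5, (2.0, 2.0, 2.0), origin=(10, 0, -5))
        lo, hi = m.vertices.min(axis=0), m.vertices.max(axis=0)
        np.testing.assert_allclose(lo, np.array([10, 0, -5]) + 2.0 * 2.5)
        np.testing.assert_allclose(hi, np.array([10, 0, -5]) + 2.0 * 4.5)


class TestIsoSweep:
    def test_monotone_volumes_for_radial_field(self, radial_field):
        f, sp = radial_field
        isos = np.exp(-np.linspace(14, 4, 12))
        sw = iso_sweep(f, isos, (sp,) * 3)
        assert np.all(np.diff(sw.volumes) < 0)

    def test_two_bumps_component_count(self):
        n, sp = 48, 1.0
        ax = np.arange(n) * sp
        g = np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)
        f = (np.exp(-np.linalg.norm(g - np.array([14, 24, 24]), axis=-1) / 3)
             + 0.5 * np.exp(-np.linalg.norm(g - np.array([34, 24, 24]), axis=-1) / 3))
        # between the saddle and the lower peak the level set has 2 components
        sw = iso_sweep(f, [0.2], (sp,) * 3)
        assert sw.component_counts[0] == 2

    def test_iso_above_max_zero_volume(self, radial_field):
        f, sp = radial_field
        sw = iso_sweep(f, [0.5, 2.0], (sp,) * 3)
        assert sw.volumes[1] == 0.0
        assert sw.component_counts[1] == 0


class TestIndicatorCurve:
    def _sweep(self, radial_field, isos):
        f, sp = radial_field
        return iso_sweep(f, isos, (sp,) * 3)

    def test_zero_at_reference(self, radial_field):
        isos = np.exp(-np.linspace(13, 5, 9))
        sw = self._sweep(radial_field, isos)
        curve = indicator_curve(sw, float(isos[4]))
        assert curve.dR[4] == 0.0
        assert curve.dr[4] == 0.0

    def test_concentric_spheres_radius_change(self, radial_field):
        """For f = exp(-r), R(iso) = -ln iso, so dR = ln(iso0/iso)."""
        isos = np.exp(-np.array([12.0, 10.0, 8.0]))
        sw = self._sweep(radial_field, isos)
        curve = indicator_curve(sw, float(isos[1]))
        np.testing.assert_allclose(curve.dR, [2.0, 0.0, -2.0], atol=0.05)

    def test_monotone_dR_for_monotone_volume(self, radial_field):
        isos = np.exp(-np.linspace(13, 5, 9))
        sw = self._sweep(radial_field, isos)
        curve = indicator_curve(sw, float(isos[0]))
        assert np.all(np.diff(curve.dR) < 0)

    def test_reference_not_in_sweep_rejected(self, radial_field):
        sw = self._sweep(radial_field, np.exp(-np.linspace(12, 6, 8)))
        with pytest.raises(ValueError, match="not in the sweep"):
            indicator_curve(sw, 1e-3)


class TestSelectIso:
    def _curve(self, isos, dR):
        dR = np.asarray(dR, float)
        return IndicatorCurve(np.asarray(isos, float), dR, dR.copy(),
                              1.0, 1.0, float(isos[-1]))

    def test_flat_then_steep_returns_breakpoint(self):
        """Plateau at high iso, noise upturn below: inflexion at the break."""
        isos = np.geomspace(1e-14, 1e-6, 17)
        dR = np.where(isos < 1e-10, np.log10(1e-10 / isos), 0.0)
        sel = select_iso(self._curve(isos, dR))
        assert sel.chosen_iso == pytest.approx(1e-10, rel=1e-6)
        assert sel.method == "plateau-inflexion"

    def test_flat_to_bottom_returns_plateau_start(self):
        """No terminal upturn: the plateau's high-iso edge is selected."""
        isos = np.geomspace(1e-14, 1e-6, 17)
        dR = np.where(isos > 1e-9, -np.log10(1e-9 / isos), 0.0)
        sel = select_iso(self._curve(isos, dR))
        assert sel.method == "plateau-start"
        assert sel.chosen_iso == pytest.approx(1e-9, rel=1e-6)

    def test_strictly_linear_curve_rejected(self):
        isos = np.geomspace(1e-14, 1e-6, 17)
        dR = np.log10(isos)
        with pytest.raises(ValueError, match="plateau"):
            select_iso(self._curve(isos, dR))

    def test_user_override_honoured(self):
        isos = np.geomspace(1e-14, 1e-6, 17)
        sel = select_iso(self._curve(isos, np.log10(isos)), override=3e-9)
        assert sel.chosen_iso == 3e-9
        assert sel.method == "user-override"

    def test_too_few_points_rejected(self):
        isos = np.geomspace(1e-10, 1e-8, 4)
        with pytest.raises(ValueError, match="8 sweep points"):
            select_iso(self._curve(isos, np.zeros(4)))


def _sphere_mesh(radius, centre=(0.0, 0.0, 0.0), subdivisions=3):
    import trimesh

    tm = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(tm.vertices) + np.asarray(centre),
                       np.asarray(tm.faces))


class TestCloudToMesh:
    def test_self_distance_zero(self):
        m = _sphere_mesh(5.0)
        d = cloud_to_mesh_distance(m, m, 0.5)
        assert d["mean"] == 0.0 and d["max"] == 0.0 and d["sd"] == 0.0

    def test_concentric_spheres(self):
        """Distance between concentric spheres is the radius gap."""
        inner, outer = _sphere_mesh(5.0), _sphere_mesh(5.5)
        d = cloud_to_mesh_distance(inner, outer, 0.5)
        assert d["mean"] == pytest.approx(0.5 / 0.5, rel=0.02)
        assert d["sd"] < 0.05

    def test_rigid_rotation_invariance(self):
        rng = np.random.default_rng(0)
        a, b = _sphere_mesh(4.0), _sphere_mesh(4.7, centre=(0.5, 0, 0))
        d1 = cloud_to_mesh_distance(a, b, 1.0)
        theta = 0.7
        R = np.array([[np.cos(theta), -np.sin(theta), 0],
                      [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
        a2 = SurfaceMesh(a.vertices @ R.T, a.triangles)
        b2 = SurfaceMesh(b.vertices @ R.T, b.triangles)
        d2 = cloud_to_mesh_distance(a2, b2, 1.0)
        assert d2["mean"] == pytest.approx(d1["mean"], rel=1e-9)
        assert d2["max"] == pytest.approx(d1["max"], rel=1e-9)

    def test_empty_mesh_rejected(self):
        m = _sphere_mesh(1.0)
        empty = SurfaceMesh(np.zeros((0, 3)), np.zeros((0, 3), int))
        with pytest.raises(ValueError):
            cloud_to_mesh_distance(empty, m, 1.0)


class TestExport:
    def _tetra(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]])
        return SurfaceMesh(v, f)

    def test_stl_round_trip(self, tmp_path):
        m = self._tetra()
        path = export_surface(m, tmp_path / "t.stl")
        back = load_surface(path)
        assert len(back.triangles) == 4
        assert back.volume == pytest.approx(m.volume, rel=1e-6)

    def test_ply_round_trip_counts(self, tmp_path):
        m = _sphere_mesh(3.0)
        back = load_surface(export_surface(m, tmp_path / "s.ply"))
        assert len(back.triangles) == len(m.triangles)

    def test_obj_non_watertight(self, tmp_path):
        m = self._tetra()
        open_mesh = SurfaceMesh(m.vertices, m.triangles[:2])
        assert not open_mesh.watertight
        path = export_surface(open_mesh, tmp_path / "o.obj")
        assert path.exists()

    def test_deterministic_bytes(self, tmp_path):
        m = _sphere_mesh(2.0)
        p1 = export_surface(m, tmp_path / "a.stl")
        p2 = export_surface(m, tmp_path / "b.stl")
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_surface(self._tetra(), tmp_path / "t.xyz")
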