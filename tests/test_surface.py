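import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import chisquare

from epsim.electrostatics import (GridSpec, SolventParams, bjerrum_length,
                                  debye_kappa, dh_potential_grid)
from epsim.structure_io import ChargedAtom, ChargedStructure
from epsim.surface import (EmptySurfaceError, IsoSurface, buried_interface_area,
                           extract_isosurface, sample_surface_points, sasa,
                           signed_isosurfaces, surface_area)


def iso_radius_oracle(level=1.0):
    """1D root of l_B exp(-κr)/r = level for a +1 e charge at default salt."""
    lb, kap = bjerrum_length(), debye_kappa(SolventParams())
    return brentq(lambda r: lb * np.exp(-kap * r) / r - level, 0.5, 20.0)


class TestExtract:
    def test_point_charge_sphere_radius(self, ion_dh_grid, sphere_surface):
        r_star = iso_radius_oracle()
        r = np.linalg.norm(sphere_surface.vertices, axis=1)
        assert np.abs(r - r_star).max() <= ion_dh_grid.spec.spacing

    def test_sphere_area(self, sphere_surface):
        r_star = iso_radius_oracle()
        assert surface_area(sphere_surface) == pytest.approx(
            4 * np.pi * r_star ** 2, rel=0.05)

    def test_negative_level_empty_for_positive_field(self, ion_dh_grid):
        with pytest.raises(EmptySurfaceError):
            extract_isosurface(ion_dh_grid, -1.0)

    def test_vertices_lie_on_level_set(self, ion_dh_grid, sphere_surface):
        phi = ion_dh_grid.interpolate(sphere_surface.vertices)
        assert np.abs(phi - 1.0).max() <= 1e-6

    def test_origin_translation_translates_vertices(self, ion):
        g1 = dh_potential_grid(ion)
        shift = np.array([3.0, -2.0, 5.0])
        shifted_spec = GridSpec(origin=g1.spec.origin + shift,
                                spacing=g1.spec.spacing, shape=g1.spec.shape)
        moved = ChargedStructure("ion", [
            ChargedAtom(a.name, a.position + shift, a.charge, a.radius)
            for a in ion.atoms])
        g2 = dh_potential_grid(moved, shifted_spec)
        s1 = extract_isosurface(g1, 1.0)
        s2 = extract_isosurface(g2, 1.0)
        assert np.allclose(s2.vertices, s1.vertices + shift, atol=1e-9)

    def test_signed_pair_with_half_level_fallback(self, dipole):
        grid = dh_potential_grid(dipole)
        surf = signed_isosurfaces(grid, 1.0)
        assert surf["+"].level == 1.0 and surf["-"].level == -1.0
        # a weak dipole needs the half-level retry on both signs
        weak = ChargedStructure("weak", [
            ChargedAtom(a.name, a.position, 0.04 * a.charge, a.radius)
            for a in dipole.atoms])
        gw = dh_potential_grid(weak)
        assert abs(gw.values.max()) < 1.0
        sw = signed_isosurfaces(gw, 1.0)
        assert sw["+"].level == 0.5 and sw["-"].level == -0.5


class TestArea:
    def test_unit_right_triangle(self):
        s = IsoSurface(level=1.0, sign="+",
                       vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                       faces=np.array([[0, 1, 2]]))
        assert surface_area(s) == pytest.approx(0.5)

    def test_two_triangles(self):
        s = IsoSurface(level=1.0, sign="+",
                       vertices=np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0],
                                          [1, 1, 0]]),
                       faces=np.array([[0, 1, 2], [1, 3, 2]]))
        assert surface_area(s) == pytest.approx(1.0)

    def test_degenerate_mesh_warns_and_returns_zero(self):
        s = IsoSurface(level=1.0, sign="+", vertices=np.zeros((0, 3)),
                       faces=np.zeros((0, 3), dtype=int))
        with pytest.warns(UserWarning):
            assert surface_area(s) == 0.0


class TestSampling:
    def test_points_lie_on_mesh_triangles(self, sphere_surface, rng):
        pc = sample_surface_points(sphere_surface, 200, rng)
        v = sphere_surface.vertices
        f = sphere_surface.faces
        a, b, c = v[f[:, 0]], v[f[:, 1]], v[f[:, 2]]
        normals = np.cross(b - a, c - a)
        norms = np.linalg.norm(normals, axis=1)
        ok = norms > 1e-12
        normals, a_ok = normals[ok] / norms[ok, None], a[ok]
        # distance of each sample to its nearest triangle plane
        d = np.abs(np.einsum("ij,kj->ki", normals, pc.points)
                   - np.einsum("ij,ij->i", normals, a_ok)[None, :])
        assert d.min(axis=1).max() < 1e-9

    def test_octant_occupancy_uniform(self, sphere_surface):
        rng = np.random.default_rng(7)
        pc = sample_surface_points(sphere_surface, 10_000, rng)
        signs = (pc.points > 0).astype(int)
        octant = signs[:, 0] * 4 + signs[:, 1] * 2 + signs[:, 2]
        counts = np.bincount(octant, minlength=8)
        assert chisquare(counts).pvalue > 0.01

    def test_seed_determinism(self, sphere_surface):
        p1 = sample_surface_points(sphere_surface, 50, np.random.default_rng(5))
        p2 = sample_surface_points(sphere_surface, 50, np.random.default_rng(5))
        p3 = sample_surface_points(sphere_surface, 50, np.random.default_rng(6))
        assert np.array_equal(p1.points, p2.points)
        assert not np.array_equal(p1.points, p3.points)

    def test_sample_mean_approaches_centroid(self, sphere_surface):
        areas = sphere_surface.triangle_areas
        v = sphere_surface.vertices
        f = sphere_surface.faces
        tri_centroids = v[f].mean(axis=1)
        centroid = (tri_centroids * areas[:, None]).sum(0) / areas.sum()
        pc = sample_surface_points(sphere_surface, 50_000,
                                   np.random.default_rng(11))
        r_star = np.linalg.norm(v, axis=1).mean()
        assert np.linalg.norm(pc.points.mean(0) - centroid) < 0.05 * r_star

    def test_empty_surface_rejected(self, rng):
        s = IsoSurface(level=1.0, sign="+", vertices=np.zeros((0, 3)),
                       faces=np.zeros((0, 3), dtype=int))
        with pytest.raises(EmptySurfaceError):
            sample_surface_points(s, 10, rng)


def _ball(label, center, radius=1.6, charge=0.0):
    return ChargedStructure(label, [
        ChargedAtom("C", np.asarray(center, dtype=float), charge, radius)])


class TestSASA:
    def test_single_atom_closed_form(self):
        s = _ball("one", [0, 0, 0], radius=1.6)
        assert sasa(s, probe_radius=1.4).sum() == pytest.approx(
            4 * np.pi * 3.0 ** 2, rel=1e-6)

    def test_coincident_atoms_share_one_sphere(self):
        s = ChargedStructure("two", [
            ChargedAtom("A", np.zeros(3), 0.0, 1.6),
            ChargedAtom("B", np.zeros(3), 0.0, 1.6)])
        total = sasa(s, probe_radius=1.4, n_sphere_points=4000).sum()
        assert total == pytest.approx(4 * np.pi * 3.0 ** 2, rel=0.02)

    def test_buried_atom_has_zero_area(self):
        shell_dirs = np.random.default_rng(0).normal(size=(80, 3))
        shell_dirs /= np.linalg.norm(shell_dirs, axis=1)[:, None]
        atoms = [ChargedAtom("X", np.zeros(3), 0.0, 1.0)]
        atoms += [ChargedAtom(f"S{i}", 2.0 * d, 0.0, 1.8)
                  for i, d in enumerate(shell_dirs)]
        areas = sasa(ChargedStructure("shell", atoms), probe_radius=1.4)
        assert areas[0] == pytest.approx(0.0, abs=1e-9)

    def test_rotation_invariance(self, rng):
        from scipy.spatial.transform import Rotation
        from tests.conftest import random_structure
        s = random_structure(rng, n_atoms=8, box=3.0)
        R = Rotation.from_rotvec([0.3, 1.1, -0.7]).as_matrix()
        rotated = ChargedStructure("rot", [
            ChargedAtom(a.name, R @ a.position, a.charge, a.radius)
            for a in s.atoms])
        a1 = sasa(s).sum()
        a2 = sasa(rotated).sum()
        assert a2 == pytest.approx(a1, rel=0.01)


class TestBuriedInterface:
    def test_distant_structures_bury_nothing(self):
        a = _ball("A", [0, 0, 0])
        b = _ball("B", [20, 0, 0])
        assert buried_interface_area(a, b) == 0.0

    def test_symmetry(self):
        a = _ball("A", [0, 0, 0])
        b = _ball("B", [2.5, 0, 0])
        assert buried_interface_area(a, b) == buried_interface_area(b, a)

    def test_touching_spheres_match_cap_oracle(self):
        # two atoms radius r, probe p, centers d apart with d < 2(r+p):
        # each expanded sphere loses a cap of area 2πR(R - d/2), R = r + p
        r, p, d = 1.6, 1.4, 2.5
        R = r + p
        expected = 2 * np.pi * R * (R - d / 2)
        a = _ball("A", [0, 0, 0], radius=r)
        b = _ball("B", [d, 0, 0], radius=r)
        got = buried_interface_area(a, b, probe_radius=p, n_sphere_points=4000)
        assert got == pytest.approx(expected, rel=0.02)
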