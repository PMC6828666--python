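"""Grid maps: LJ potential, truncation, convolution, density, sampling."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from openpocket import grids
from openpocket.grids import (
    ConvolutionSpec,
    GridMap,
    GridSpec,
    atom_density_map,
    fumigation_map,
    gaussian_convolve,
    gaussian_convolve_direct,
    lj_potential_map,
    make_grid,
    read_map_text,
    sample_map,
    truncate_attractive,
    write_map_text,
)
from tests.conftest import atoms_structure, single_atom_structure


class TestMakeGrid:
    def test_single_atom_padding(self, single_atom):
        spec = make_grid(single_atom, 1.0, 5.0)
        assert spec.origin == (-5.0, -5.0, -5.0)
        assert spec.dims == (11, 11, 11)

    def test_minimum_dims_enforced(self, single_atom):
        spec = make_grid(single_atom, 1.0, 0.0)
        assert all(d >= 2 for d in spec.dims)

    def test_padding_respected(self):
        st_ = atoms_structure([(0, 0, 0), (3.3, 1.1, -2.2)])
        spec = make_grid(st_, 0.7, 4.0)
        lo = np.asarray(spec.origin)
        hi = spec.upper_corner
        for xyz in st_.coords():
            assert np.all(xyz - lo >= 4.0 - 1e-9)
            assert np.all(hi - xyz >= 4.0 - 1e-9)

    def test_empty_structure_rejected(self):
        from openpocket.structure import Structure

        with pytest.raises(ValueError):
            make_grid(Structure(), 1.0, 1.0)


class TestLJPotential:
    def test_single_atom_minimum(self, single_atom):
        spec = make_grid(single_atom, 0.25, 6.0)
        m = lj_potential_map(single_atom, spec)
        atom = single_atom.residues[0].atoms[0]
        A, B = atom.lj.A, atom.lj.B
        assert m.values.min() == pytest.approx(-B * B / (4 * A), rel=0.01)
        idx = np.unravel_index(np.argmin(m.values), m.values.shape)
        node = np.asarray(spec.origin) + spec.spacing * np.array(idx)
        assert np.linalg.norm(node) == pytest.approx(
            (2 * A / B) ** (1 / 6), abs=2 * spec.spacing)

    def test_zero_crossing_distance(self, single_atom):
        atom = single_atom.residues[0].atoms[0]
        A, B = atom.lj.A, atom.lj.B
        d0 = (A / B) ** (1 / 6)
        spec = GridSpec(origin=(d0, 0.0, 0.0), spacing=1.0, dims=(2, 2, 2))
        m = lj_potential_map(single_atom, spec)
        assert m.values[0, 0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_two_atom_additivity(self):
        pair = atoms_structure([(0, 0, 0), (4, 0, 0)])
        one = atoms_structure([(0, 0, 0)])
        other = atoms_structure([(4, 0, 0)])
        spec = make_grid(pair, 1.0, 5.0)
        vp = lj_potential_map(pair, spec).values
        v1 = lj_potential_map(one, spec).values
        v2 = lj_potential_map(other, spec).values
        # clash-clamped nodes (removed by truncation anyway) are exempt
        ok = vp < grids.CLASH_VALUE / 2
        np.testing.assert_allclose(vp[ok], (v1 + v2)[ok], rtol=1e-9)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(3)
        st_ = atoms_structure(rng.uniform(-3, 3, size=(20, 3)))
        spec = make_grid(st_, 1.5, 3.0)
        m = lj_potential_map(st_, spec)
        nodes = spec.node_coords().reshape(-1, 3)
        ref = np.zeros(len(nodes))
        clash = np.zeros(len(nodes), dtype=bool)
        for _, a in st_.atoms():
            d2 = np.sum((nodes - a.coords) ** 2, axis=1)
            near = d2 < grids.CLASH_DISTANCE**2
            clash |= near
            d2 = np.where(near, grids.CLASH_DISTANCE**2, d2)
            ref += a.lj.A / d2**6 - a.lj.B / d2**3
        ref[clash] = grids.CLASH_VALUE
        np.testing.assert_allclose(m.values.reshape(-1), ref, rtol=1e-9)


class TestTruncation:
    def test_boundary_convention(self):
        spec = GridSpec((0, 0, 0), 1.0, (2, 2, 2))
        vals = np.zeros((2, 2, 2))
        vals[0, 0, :] = [-2.0, -0.8]
        vals[0, 1, :] = [-0.5, 3.0]
        m = truncate_attractive(GridMap(spec, vals, kind="P0"))
        assert m.values[0, 0, 0] == -2.0
        assert m.values[0, 0, 1] == -0.8   # boundary kept (<= convention)
        assert m.values[0, 1, 0] == 0.0
        assert m.values[0, 1, 1] == 0.0

    def test_all_positive_becomes_zero(self):
        spec = GridSpec((0, 0, 0), 1.0, (3, 3, 3))
        m = truncate_attractive(GridMap(spec, np.ones((3, 3, 3)), kind="P0"))
        assert np.all(m.values == 0.0)

    def test_all_attractive_unchanged(self):
        spec = GridSpec((0, 0, 0), 1.0, (3, 3, 3))
        vals = np.full((3, 3, 3), -1.5)
        m = truncate_attractive(GridMap(spec, vals, kind="P0"))
        np.testing.assert_array_equal(m.values, vals)


class TestConvolution:
    def test_zero_map(self):
        spec = GridSpec((0, 0, 0), 0.5, (9, 9, 9))
        m = gaussian_convolve(GridMap(spec, np.zeros((9, 9, 9))),
                              ConvolutionSpec(2.0))
        assert np.all(m.values == 0.0)

    def test_constant_field_interior_response(self):
        lam = 2.0
        spec = GridSpec((0, 0, 0), 0.5, (41, 41, 41))
        m = gaussian_convolve(GridMap(spec, np.full((41, 41, 41), 3.0)),
                              ConvolutionSpec(lam))
        # interior nodes >= 3 lambda from every face
        assert m.values[20, 20, 20] == pytest.approx(
            3.0 * math.pi**1.5, rel=0.01)

    def test_impulse_matches_direct_summation(self):
        spec = GridSpec((0, 0, 0), 0.7, (13, 13, 13))
        vals = np.zeros((13, 13, 13))
        vals[6, 6, 6] = 2.5
        vals[2, 9, 4] = -1.0
        fast = gaussian_convolve(GridMap(spec, vals), ConvolutionSpec(1.3))
        ref = gaussian_convolve_direct(GridMap(spec, vals),
                                       ConvolutionSpec(1.3))
        np.testing.assert_allclose(fast.values, ref.values, rtol=1e-6,
                                   atol=1e-12)

    def test_impulse_closed_form(self):
        h, lam = 0.5, 1.5
        spec = GridSpec((0, 0, 0), h, (15, 15, 15))
        vals = np.zeros((15, 15, 15))
        vals[7, 7, 7] = 4.0
        m = gaussian_convolve(GridMap(spec, vals), ConvolutionSpec(lam))
        for idx in ((7, 7, 7), (8, 7, 7), (9, 10, 7)):
            d2 = h * h * sum((i - 7) ** 2 for i in idx)
            expected = 4.0 * (h**3 / lam**3) * math.exp(-d2 / lam**2)
            assert m.values[idx] == pytest.approx(expected, rel=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(5)
        spec = GridSpec((0, 0, 0), 0.8, (10, 10, 10))
        x = rng.normal(size=(10, 10, 10))
        y = rng.normal(size=(10, 10, 10))
        conv = ConvolutionSpec(1.1)
        lhs = gaussian_convolve(GridMap(spec, 2.0 * x + 3.0 * y), conv).values
        rhs = (2.0 * gaussian_convolve(GridMap(spec, x), conv).values
               + 3.0 * gaussian_convolve(GridMap(spec, y), conv).values)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_small_lambda_approaches_scaled_identity(self):
        # on an impulse, the off-centre response decays monotonically to 0
        # while the centre stays at h^3/lam^3 x exp(0) x value
        h = 1.0
        spec = GridSpec((0, 0, 0), h, (7, 7, 7))
        vals = np.zeros((7, 7, 7))
        vals[3, 3, 3] = 1.0
        prev_ratio = None
        for lam in (2.0, 1.0, 0.5):
            m = gaussian_convolve(GridMap(spec, vals), ConvolutionSpec(lam))
            ratio = m.values[4, 3, 3] / m.values[3, 3, 3]
            assert ratio == pytest.approx(math.exp(-h * h / lam**2), rel=1e-9)
            if prev_ratio is not None:
                assert ratio < prev_ratio
            prev_ratio = ratio


class TestAtomDensity:
    def test_centre_value_and_w_a_falloff(self):
        st_ = single_atom_structure()
        w = st_.residues[0].atoms[0].w_a
        spec = GridSpec((0, 0, 0), w, (2, 2, 2))  # nodes at 0 and w
        m = atom_density_map(st_, spec)
        assert m.values[0, 0, 0] == pytest.approx(1.0, abs=1e-6)
        assert m.values[1, 0, 0] == pytest.approx(math.exp(-1), abs=1e-6)

    def test_coincident_atoms_add(self):
        st_ = atoms_structure([(0, 0, 0), (0, 0, 0)])
        spec = GridSpec((0, 0, 0), 1.0, (2, 2, 2))
        m = atom_density_map(st_, spec)
        assert m.values[0, 0, 0] == pytest.approx(2.0, abs=1e-6)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        st_ = atoms_structure(rng.uniform(-4, 4, size=(30, 3)))
        spec = make_grid(st_, 1.7, 2.0)
        m = atom_density_map(st_, spec)
        nodes = spec.node_coords().reshape(-1, 3)
        ref = np.zeros(len(nodes))
        for _, a in st_.atoms():
            d2 = np.sum((nodes - a.coords) ** 2, axis=1)
            ref += np.exp(-d2 / a.w_a**2)
        np.testing.assert_allclose(m.values.reshape(-1), ref, rtol=1e-9)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(13)
        pts = rng.uniform(-3, 3, size=(10, 3))
        shift = np.array([7.3, -2.1, 4.4])
        st1 = atoms_structure(pts)
        st2 = atoms_structure(pts + shift)
        spec1 = GridSpec((-5, -5, -5), 1.0, (11, 11, 11))
        spec2 = GridSpec(tuple(np.array(spec1.origin) + shift), 1.0,
                         (11, 11, 11))
        np.testing.assert_allclose(atom_density_map(st1, spec1).values,
                                   atom_density_map(st2, spec2).values,
                                   rtol=1e-9)


class TestFumigationMap:
    def test_definitional_identity(self, hollow_sphere):
        spec = make_grid(hollow_sphere, 1.0, 4.0)
        conv = ConvolutionSpec(12.0)
        f = fumigation_map(hollow_sphere, spec, conv)
        d = atom_density_map(hollow_sphere, spec)
        dc = gaussian_convolve(d, conv)
        np.testing.assert_allclose(f.values, dc.values - d.values,
                                   rtol=1e-12)
        assert f.kind == "F"

    def test_far_from_atoms_vanishes(self, hollow_sphere):
        spec = make_grid(hollow_sphere, 1.0, 60.0)
        f = fumigation_map(hollow_sphere, spec, ConvolutionSpec(5.0))
        corner = f.values[0, 0, 0]
        assert abs(corner) < 1e-6

    def test_cavity_mean_exceeds_exterior_shell_mean(self, hollow_sphere):
        spec = make_grid(hollow_sphere, 0.5, 8.0)
        f = fumigation_map(hollow_sphere, spec, ConvolutionSpec(12.0))
        nodes = spec.node_coords()
        r = np.linalg.norm(nodes, axis=-1)
        cavity = f.values[r < 4.0]
        # exterior shell of equal thickness just outside the wall band
        shell = f.values[(r > 7.4) & (r < 11.4)]
        assert cavity.mean() > shell.mean()


class TestSampleMap:
    def _ramp(self):
        spec = GridSpec((0, 0, 0), 1.0, (6, 6, 6))
        nodes = spec.node_coords()
        vals = 2.0 * nodes[..., 0] - 0.5 * nodes[..., 1] + nodes[..., 2] + 3
        return GridMap(spec, vals)

    def test_node_and_edge_midpoint(self):
        m = self._ramp()
        assert sample_map(m, (2.0, 3.0, 1.0)) == pytest.approx(
            m.values[2, 3, 1])
        mid = sample_map(m, (2.5, 3.0, 1.0))
        assert mid == pytest.approx(
            0.5 * (m.values[2, 3, 1] + m.values[3, 3, 1]))

    @settings(max_examples=30, deadline=None)
    @given(st.tuples(*[st.floats(0.0, 5.0) for _ in range(3)]))
    def test_linear_ramp_reproduced_exactly(self, point):
        m = self._ramp()
        x, y, z = point
        expected = 2.0 * x - 0.5 * y + z + 3
        assert sample_map(m, point) == pytest.approx(expected, abs=1e-9)

    def test_outside_box_is_zero(self):
        m = self._ramp()
        assert sample_map(m, (100.0, 0.0, 0.0)) == 0.0


class TestMapSerialization:
    def test_text_round_trip(self):
        rng = np.random.default_rng(2)
        spec = GridSpec((1.5, -2.0, 0.25), 0.5, (4, 3, 5))
        m = GridMap(spec, rng.normal(size=(4, 3, 5)), kind="F")
        m2 = read_map_text(write_map_text(m))
        assert m2.kind == "F"
        assert m2.spec == spec
        np.testing.assert_allclose(m2.values, m.values, rtol=1e-6)
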