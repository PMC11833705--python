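"""LENS and τSOAP descriptor series: formulas, invariances, contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leapkit.descriptors import lens, normalize, smooth, soap_spectrum, tau_soap
from leapkit.soap import SoapCalculator
from leapkit.synthetic import (
    LatticeSpec,
    inject_rearrangement,
    inject_swap,
    make_vibrating_lattice,
)
from leapkit.trajectory_io import NeighborLists, ParticleTrajectory, build_neighbor_lists


def _lists_to_neighborlists(frames):
    """Build a NeighborLists from explicit per-frame lists of one center."""
    return NeighborLists(
        rcut=1.0,
        centers=np.array([0]),
        candidates=np.arange(100),
        lists=[[np.asarray(f, dtype=np.int64)] for f in frames],
    )


def _bag_difference_lens(a, b):
    """Independent oracle: symmetric multiset difference over concatenation."""
    a, b = list(a), list(b)
    if not a and not b:
        return 0.0
    sym = set(a) ^ set(b)
    return len(sym) / (len(a) + len(b))


class TestLens:
    @pytest.mark.parametrize("a,b,expected", [
        ([1, 2, 3], [1, 2, 4], 2 / 6),        # hand enumeration
        ([1, 2, 3], [1, 2, 3], 0.0),          # identical lists
        ([1, 2], [3, 4, 5], 1.0),             # disjoint lists
        ([], [], 0.0),                        # both empty, by convention
        ([], [1, 2], 1.0),                    # one-sided empty
    ])
    def test_formula(self, a, b, expected):
        series = lens(_lists_to_neighborlists([a, b]))
        assert series.values[0, 0] == pytest.approx(expected)

    def test_matches_bag_difference_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            pool = np.arange(30)
            a = rng.choice(pool, size=rng.integers(0, 12), replace=False)
            b = rng.choice(pool, size=rng.integers(0, 12), replace=False)
            got = lens(_lists_to_neighborlists([np.sort(a), np.sort(b)]))
            assert got.values[0, 0] == pytest.approx(_bag_difference_lens(a, b))

    def test_range_and_length(self, vibrating_lattice):
        nl = build_neighbor_lists(vibrating_lattice, 1.25)
        series = lens(nl)
        assert series.values.shape == (vibrating_lattice.n_units,
                                       vibrating_lattice.n_frames - 1)
        assert (series.values >= 0).all() and (series.values <= 1).all()


class TestSoap:
    def test_translation_invariance(self, random_gas):
        traj = random_gas(n=50, periodic=False, seed=4)
        shifted = traj.copy()
        shifted.positions += np.array([5.0, -3.0, 2.0])
        a = soap_spectrum(traj, rcut=2.0, n_max=4, l_max=3)
        b = soap_spectrum(shifted, rcut=2.0, n_max=4, l_max=3)
        np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-10)

    def test_rotation_invariance(self, random_gas):
        from scipy.spatial.transform import Rotation

        traj = random_gas(n=50, periodic=False, seed=4)
        R = Rotation.random(random_state=7).as_matrix()
        rotated = traj.copy()
        rotated.positions = traj.positions @ R.T
        a = soap_spectrum(traj, rcut=2.0, n_max=4, l_max=3)
        b = soap_spectrum(rotated, rcut=2.0, n_max=4, l_max=3)
        np.testing.assert_allclose(a.vectors, b.vectors, atol=1e-8)

    def test_single_neighbor_axis_degeneracy(self):
        calc = SoapCalculator(rcut=1.5, n_max=4, l_max=3)
        vx = calc.power_spectrum(np.array([[0.8, 0.0, 0.0]]))
        vy = calc.power_spectrum(np.array([[0.0, 0.8, 0.0]]))
        np.testing.assert_allclose(vx, vy, atol=1e-12)

    def test_zero_neighbors_flagged(self):
        pos = np.zeros((2, 2, 3))
        pos[:, 1, 0] = 50.0
        traj = ParticleTrajectory(pos + 0.0, ids=[0, 1])
        s = soap_spectrum(traj, rcut=1.0, n_max=3, l_max=2)
        assert s.empty.all()
        assert (s.vectors == 0).all()

    def test_vectors_unit_norm(self, vibrating_lattice):
        s = soap_spectrum(vibrating_lattice, rcut=1.25, n_max=4, l_max=3)
        norms = np.linalg.norm(s.vectors, axis=-1)
        ok = ~s.empty
        np.testing.assert_allclose(norms[ok], 1.0, atol=1e-12)


class TestTauSoap:
    def _series_from_vectors(self, v0, v1):
        from leapkit.descriptors import SoapSeries

        vecs = np.stack([np.atleast_2d(v0), np.atleast_2d(v1)], axis=1)
        return SoapSeries(vectors=vecs, empty=np.zeros((1, 2), bool),
                          centers=np.array([0]))

    def test_identical_vectors_zero(self):
        v = np.array([1.0, 0.0, 0.0])
        s = tau_soap(self._series_from_vectors(v, v))
        assert s.values[0, 0] == pytest.approx(0.0)

    def test_orthogonal_vectors_sqrt2(self):
        s = tau_soap(self._series_from_vectors([1.0, 0.0], [0.0, 1.0]))
        assert s.values[0, 0] == pytest.approx(np.sqrt(2.0))

    def test_half_dot_gives_one(self):
        v0 = np.array([1.0, 0.0])
        v1 = np.array([0.5, np.sqrt(3) / 2])  # unit vector, dot = 0.5
        s = tau_soap(self._series_from_vectors(v0, v1))
        assert s.values[0, 0] == pytest.approx(1.0)

    def test_empty_environment_propagates_nan(self):
        from leapkit.descriptors import SoapSeries

        vecs = np.zeros((1, 3, 2))
        vecs[0, :, 0] = 1.0
        empty = np.array([[False, True, False]])
        s = tau_soap(SoapSeries(vectors=vecs, empty=empty, centers=np.array([0])))
        assert np.isnan(s.values[0, 0]) and np.isnan(s.values[0, 1])


class TestDescriptorContracts:
    """The pure-event oracles on a frozen lattice."""

    RCUT = 1.25

    def test_pure_swap(self, frozen_lattice):
        a, b = 0, frozen_lattice.n_units // 2
        traj, _ = inject_swap(frozen_lattice, 2, int(frozen_lattice.ids[a]),
                              int(frozen_lattice.ids[b]), rcut=self.RCUT)
        d = lens(build_neighbor_lists(traj, self.RCUT))
        l = tau_soap(soap_spectrum(traj, rcut=self.RCUT, n_max=4, l_max=3))
        for unit in (a, b):
            assert d.values[unit, 1] == pytest.approx(1.0)
            assert l.values[unit, 1] == pytest.approx(0.0, abs=1e-6)
            # quiet elsewhere
            assert d.values[unit, 0] == 0.0 and d.values[unit, 2] == 0.0

    def test_swap_neighbor_lens_matches_enumeration(self, frozen_lattice):
        a, b = 0, frozen_lattice.n_units // 2
        traj, _ = inject_swap(frozen_lattice, 2, int(frozen_lattice.ids[a]),
                              int(frozen_lattice.ids[b]), rcut=self.RCUT)
        nl = build_neighbor_lists(traj, self.RCUT)
        d = lens(nl)
        for c in range(traj.n_units):
            la, lb = nl.lists[1][c], nl.lists[2][c]
            expected = _bag_difference_lens(la, lb)
            assert d.values[c, 1] == pytest.approx(expected)

    def test_adjacent_swap_rejected(self, frozen_lattice):
        with pytest.raises(ValueError, match="2\\*rcut"):
            inject_swap(frozen_lattice, 2, 0, 1, rcut=self.RCUT)

    def test_pure_rearrangement(self, frozen_lattice):
        cid = int(frozen_lattice.ids[40])
        traj, _ = inject_rearrangement(frozen_lattice, 2, cid, 0.4,
                                       rcut=self.RCUT, seed=5)
        d = lens(build_neighbor_lists(traj, self.RCUT))
        l = tau_soap(soap_spectrum(traj, rcut=self.RCUT, n_max=4, l_max=3))
        k = 40
        assert d.values[k, 1] == pytest.approx(0.0)
        assert l.values[k, 1] > 0.1

    def test_zero_scale_rearrangement_is_identity(self, frozen_lattice):
        cid = int(frozen_lattice.ids[40])
        traj, _ = inject_rearrangement(frozen_lattice, 2, cid, 0.0,
                                       rcut=self.RCUT, seed=5)
        np.testing.assert_array_equal(traj.positions, frozen_lattice.positions)

    def test_rearrangement_monotone_in_scale(self, frozen_lattice):
        cid = int(frozen_lattice.ids[40])
        responses = []
        for scale in (0.1, 0.3, 0.5):
            traj, _ = inject_rearrangement(frozen_lattice, 2, cid, scale,
                                           rcut=self.RCUT, seed=9)
            l = tau_soap(soap_spectrum(traj, centers=[cid], rcut=self.RCUT,
                                       n_max=4, l_max=3))
            responses.append(l.values[0, 1])
        assert responses[0] < responses[1] < responses[2]

    def test_global_rigid_motion_silent(self, frozen_lattice):
        traj = frozen_lattice.copy()
        traj.box = None
        traj.periodic = np.zeros(3, bool)
        for f in range(traj.n_frames):
            traj.positions[f] += f * np.array([0.3, 0.1, -0.2])
        d = lens(build_neighbor_lists(traj, self.RCUT))
        l = tau_soap(soap_spectrum(traj, rcut=self.RCUT, n_max=4, l_max=3))
        assert np.abs(d.values).max() == 0.0
        assert np.nanmax(np.abs(l.values)) < 1e-6


class TestSmooth:
    def _series(self, vals):
        from leapkit.descriptors import DescriptorSeries

        return DescriptorSeries(kind="lens", values=np.asarray(vals, float),
                                centers=np.arange(len(vals)))

    def test_constant_unchanged(self):
        s = smooth(self._series([[2.0, 2.0, 2.0, 2.0]]), 3)
        np.testing.assert_allclose(s.values, 2.0)

    def test_width_one_identity(self):
        s = self._series([[0.1, 0.9, 0.4]])
        out = smooth(s, 1)
        np.testing.assert_array_equal(out.values, s.values)
        assert out.state == "smoothed"

    def test_truncated_edges(self):
        out = smooth(self._series([[0.0, 1.0, 2.0]]), 3)
        np.testing.assert_allclose(out.values, [[0.5, 1.0, 1.5]])

    def test_nan_excluded_from_window(self):
        out = smooth(self._series([[0.0, np.nan, 2.0]]), 3)
        np.testing.assert_allclose(out.values[0, 1], 1.0)

    def test_width_exceeding_length_rejected(self):
        with pytest.raises(ValueError, match="width"):
            smooth(self._series([[0.0, 1.0]]), 5)


class TestNormalize:
    def _series(self, vals):
        from leapkit.descriptors import DescriptorSeries

        return DescriptorSeries(kind="lens", values=np.asarray(vals, float),
                                centers=np.arange(np.shape(vals)[0]))

    def test_linear_map(self):
        out = normalize(self._series([[2.0, 3.0, 4.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.5, 1.0]])
        assert out.bounds == (2.0, 4.0)

    def test_identity_bounds(self):
        out = normalize(self._series([[0.0, 0.25, 1.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 0.25, 1.0]])

    def test_constant_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="constant"):
            out = normalize(self._series([[3.0, 3.0]]))
        np.testing.assert_allclose(out.values, 0.0)

    def test_global_scope_across_centers(self):
        out = normalize(self._series([[0.0, 1.0], [3.0, 2.0]]))
        np.testing.assert_allclose(out.values, [[0.0, 1 / 3], [1.0, 2 / 3]])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            normalize(self._series([[np.nan, np.nan]]))

    def test_denormalize_roundtrip(self):
        s = self._series([[2.0, 3.0, 4.0]])
        back = normalize(s).denormalize()
        np.testing.assert_allclose(back.values, s.values)


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=2, max_size=30),
       st.integers(min_value=1, max_value=5))
def test_smoothing_preserves_mean_of_constant_padding(values, width):
    """A centered truncated-window average never exceeds the value range."""
    from leapkit.descriptors import DescriptorSeries

    s = DescriptorSeries(kind="lens", values=np.array([values]),
                         centers=np.array([0]))
    if width > s.n_steps:
        return
    out = smooth(s, width)
    assert out.values.min() >= min(values) - 1e-12
    assert out.values.max() <= max(values) + 1e-12
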