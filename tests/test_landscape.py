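import numpy as np
import pytest

from pairscape.constants import R_KCAL
from pairscape.errors import ContractError, MaskedValueError
from pairscape.free_energy import GridSpec
from pairscape.free_energy.surface import FESurface
from pairscape.landscape import (FEProfile, basin_map, discrimination_gap,
                                 extract_state, find_minima,
                                 fit_elastic_constant, opening_propensity,
                                 overlay_structures, profile_reference,
                                 propensity_at, reduce_profile,
                                 relative_opening, state_threshold)
from pairscape.synthetic_data import (build_duplex, make_surface,
                                      perturb_central_pair)

RT = R_KCAL * 300.0


def surface_from_function(fn, spec, stderr=0.0):
    c = spec.center_grid()
    v = fn(c)
    v = v - v.min()
    return FESurface(spec, v, np.full(v.shape, stderr), np.zeros(len(v), bool))


def profile_from_values(centers, values, stderr=None, T=300.0):
    values = np.asarray(values, dtype=float)
    if stderr is None:
        stderr = np.zeros_like(values)
    return FEProfile("cv0", "deg", np.asarray(centers, float),
                     values - values.min(), np.asarray(stderr, float),
                     np.zeros(len(values), bool), T)


class TestStateThreshold:
    def test_half_rt_at_300(self):
        assert state_threshold(300.0) == pytest.approx(0.2981, abs=1e-4)
        assert round(state_threshold(300.0), 1) == 0.3


class TestFindMinima:
    def test_double_well_1d(self):
        spec = GridSpec((-2.0,), (2.0,), (101,), (False,))
        s = surface_from_function(lambda c: (c[:, 0] ** 2 - 1) ** 2, spec)
        minima = find_minima(s, min_depth=0.2)
        assert len(minima) == 2
        locs = sorted(m.location[0] for m in minima)
        assert locs[0] == pytest.approx(-1.0, abs=0.05)
        assert locs[1] == pytest.approx(1.0, abs=0.05)

    def test_monotone_plane_has_no_interior_minima(self):
        spec = GridSpec((0, 0), (1, 1), (20, 20), (False, False))
        s = surface_from_function(lambda c: 3 * c[:, 0] + c[:, 1], spec)
        assert find_minima(s) == []
        assert len(find_minima(s, include_boundary=True)) == 1

    def test_canonical_single_basin(self):
        spec = GridSpec((-76, -4), (52, 4), (64, 32), (False, False))
        s = surface_from_function(make_surface("canonical_like").value, spec)
        assert len(find_minima(s, min_depth=0.5)) == 1

    @pytest.mark.parametrize("noise_seed", [0, 1, 2])
    def test_mismatch_five_basins_in_depth_order(self, noise_seed):
        spec = GridSpec((-76, -4), (52, 4), (64, 32), (False, False))
        rng = np.random.default_rng(noise_seed)
        surf = make_surface("mismatch_like")

        def noisy(c):
            return surf.value(c) + rng.normal(0, 0.02, len(c))
        s = surface_from_function(noisy, spec)
        minima = find_minima(s, min_depth=0.5)
        assert len(minima) == 5
        assert [m.label for m in minima] == [1, 2, 3, 4, 5]
        depths = [m.value for m in minima]
        assert depths == sorted(depths)
        assert minima[0].location[0] == pytest.approx(0.0, abs=3.0)

    def test_pruning_removes_shallow_satellites(self):
        spec = GridSpec((-2.0,), (2.0,), (201,), (False,))

        def fn(c):
            x = c[:, 0]
            return (x ** 2 - 1) ** 2 + 0.05 * np.sin(20 * x)
        s = surface_from_function(fn, spec)
        assert len(find_minima(s, min_depth=0.3)) == 2
        assert len(find_minima(s, min_depth=0.0)) > 2


class TestExtractState:
    spec = GridSpec((-2.0,), (2.0,), (81,), (False,))

    def _surface(self):
        return surface_from_function(
            lambda c: 3.0 * (c[:, 0] ** 2 - 1) ** 2, self.spec)

    def test_members_match_analytic_isocontour(self):
        s = self._surface()
        minima = find_minima(s, min_depth=0.5)
        left = [m for m in minima if m.location[0] < 0][0]
        xs = np.linspace(-2, 2, 400)
        st = extract_state(s, xs[:, None], left, threshold=state_threshold())
        # analytic contour: 3(x^2-1)^2 <= 0.298 around x = -1
        inside = [i for i, x in enumerate(xs)
                  if x < 0 and 3 * (x ** 2 - 1) ** 2 <= 0.2981]
        got = set(st.member_frames)
        assert got
        sym_diff = got.symmetric_difference(inside)
        # bin discretization may flip frames near the contour edge only
        edge = 3 * (xs[sorted(sym_diff)] ** 2 - 1) ** 2 if sym_diff else []
        assert all(abs(v - 0.2981) < 0.15 for v in np.atleast_1d(edge))

    def test_zero_threshold_only_min_bin(self):
        s = self._surface()
        minima = find_minima(s, min_depth=0.5)
        xs = np.linspace(-2, 2, 400)
        st = extract_state(s, xs[:, None], minima[0], threshold=0.0)
        bins = {int(self.spec.flat_index(np.array([[xs[f]]]))[0])
                for f in st.member_frames}
        assert bins == {minima[0].bin_index}

    def test_states_partition_frames(self):
        s = self._surface()
        minima = find_minima(s, min_depth=0.5)
        xs = np.linspace(-2, 2, 400)
        sets = [set(extract_state(s, xs[:, None], m).member_frames)
                for m in minima]
        assert sets[0].isdisjoint(sets[1])

    def test_representative_structure_from_trajectory(self, class_i_duplex):
        spec2 = GridSpec((-80.0, -4.0), (40.0, 4.0), (30, 8), (False, False))
        c = spec2.center_grid()
        v = 0.002 * c[:, 0] ** 2 + 0.5 * c[:, 1] ** 2
        s = FESurface(spec2, v - v.min(), np.zeros_like(v),
                      np.zeros(len(v), bool))
        minima = find_minima(s, min_depth=0.1)
        openings = [-3.0, 0.0, 3.0]
        traj = [perturb_central_pair(class_i_duplex, o, 0.0) for o in openings]
        cvs = np.array([[o, 0.0] for o in openings])
        st = extract_state(s, cvs, minima[0], threshold=1.0, trajectory=traj)
        assert st.member_frames == [0, 1, 2]
        assert st.representative is not None
        assert all(a.element != "H" for a in st.representative)


class TestBasinMap:
    def test_every_unmasked_bin_reaches_a_sink(self):
        spec = GridSpec((-2.0,), (2.0,), (51,), (False,))
        s = surface_from_function(lambda c: (c[:, 0] ** 2 - 1) ** 2, spec)
        sinks = basin_map(s)
        assert set(sinks) <= set(np.flatnonzero(sinks == sinks[np.arange(51)]))
        assert len(set(sinks[sinks >= 0])) == 2


class TestReduceProfile:
    def test_separable_surface_exact(self):
        spec = GridSpec((0, 0), (1, 1), (15, 12), (False, False))
        c = spec.center_grid()
        f = np.sin(3 * c[:, 0])
        g = np.cos(5 * c[:, 1]) * 2
        v = f + g
        s = FESurface(spec, v - v.min(), np.zeros_like(v),
                      np.zeros(len(v), bool))
        prof = reduce_profile(s)
        fx = np.sin(3 * spec.centers(0))
        assert np.allclose(prof.value, fx - fx.min(), atol=1e-10)

    def test_constant_surface_zero_profile(self):
        spec = GridSpec((0, 0), (1, 1), (10, 10), (False, False))
        v = np.zeros(100)
        s = FESurface(spec, v, v.copy(), np.zeros(100, bool))
        prof = reduce_profile(s)
        assert np.allclose(prof.value, 0.0)

    def test_gaussian_well_entropic_offset_rt_ln2(self):
        # two columns with harmonic wells of stiffness k and 4k: the softer
        # well is lower by RT ln 2 after reduction
        spec = GridSpec((0, -3), (1, 3), (2, 4001), (False, False))
        c = spec.center_grid()
        k2 = 8.0
        k1 = 4 * k2
        k = np.where(c[:, 0] < 0.5, k1, k2)
        v = 0.5 * k * c[:, 1] ** 2
        s = FESurface(spec, v - v.min(), np.zeros_like(v),
                      np.zeros(len(v), bool))
        prof = reduce_profile(s)
        offset = prof.value[0] - prof.value[1]
        assert offset == pytest.approx(RT * np.log(2.0), abs=2e-3)

    def test_masked_column_masked_in_profile(self):
        spec = GridSpec((0, 0), (1, 1), (4, 4), (False, False))
        v = np.zeros(16)
        mask = np.zeros(16, bool)
        mask[0:4] = True            # first x-column fully masked
        s = FESurface(spec, v, v.copy(), mask)
        prof = reduce_profile(s)
        assert prof.mask[0]
        assert not prof.mask[1:].any()

    def test_error_propagation_boltzmann_weights(self):
        spec = GridSpec((0, 0), (1, 1), (2, 2), (False, False))
        v = np.zeros(4)
        e = np.array([0.3, 0.4, 0.0, 0.0])
        s = FESurface(spec, v, e, np.zeros(4, bool))
        prof = reduce_profile(s)
        # flat surface: equal Boltzmann weights 1/2 in each column
        assert prof.stderr[0] == pytest.approx(0.5 * np.hypot(0.3, 0.4))
        assert prof.stderr[1] == 0.0


class TestRelativeOpeningAndPropensity:
    def test_shift_to_reference(self):
        p = profile_from_values(np.arange(-80.0, 41.0, 10.0),
                                0.01 * (np.arange(-80.0, 41.0, 10.0) - 10) ** 2)
        rel = relative_opening(p, 10.0)
        assert rel.centers.min() == -90.0
        assert rel.value[np.argmin(np.abs(rel.centers))] == \
            pytest.approx(0.0, abs=1e-12)

    def test_zero_shift_identity_and_round_trip(self):
        p = profile_from_values(np.linspace(-50, 50, 11),
                                np.linspace(-50, 50, 11) ** 2 * 1e-3)
        r0 = relative_opening(p, 0.0)
        assert np.array_equal(r0.centers, p.centers)
        back = relative_opening(relative_opening(p, 7.0), -7.0)
        assert np.allclose(back.centers, p.centers)

    def test_linear_profile_value(self):
        centers = np.arange(-100.0, 101.0, 1.0)
        p = profile_from_values(centers, np.abs(centers) / 10.0)
        v, _ = propensity_at(p, -60.0)
        assert v == pytest.approx(6.0)

    def test_bin_center_exact_and_interpolation_bounds(self):
        centers = np.array([-70.0, -60.0, -50.0])
        p = profile_from_values(centers, np.array([3.0, 1.0, 0.0]))
        v, _ = propensity_at(p, -60.0)
        assert v == pytest.approx(1.0)
        v2, _ = propensity_at(p, -55.0)
        assert min(1.0, 0.0) <= v2 <= max(1.0, 0.0) + 3.0
        assert 0.0 <= v2 <= 1.0

    def test_masked_region_raises(self):
        centers = np.array([-70.0, -60.0, -50.0])
        p = profile_from_values(centers, np.array([3.0, 1.0, 0.0]))
        p.mask[1] = True
        with pytest.raises(MaskedValueError):
            propensity_at(p, -61.0)
        with pytest.raises(MaskedValueError):
            propensity_at(p, -200.0)

    def test_profile_reference_subbin(self):
        centers = np.arange(-20.0, 21.0, 4.0)
        p = profile_from_values(centers, 0.01 * (centers - 1.0) ** 2)
        assert profile_reference(p) == pytest.approx(1.0, abs=1e-9)

    def test_opening_propensity_matches_analytic(self):
        centers = np.arange(-80.0, 21.0, 2.0)
        p = profile_from_values(centers, 0.002 * (centers - 1.0) ** 2,
                                stderr=np.full(centers.shape, 1e-6))
        v, e = opening_propensity(p, -60.0)
        assert v == pytest.approx(0.002 * 3600.0, rel=0.01)


class TestDiscriminationGap:
    def test_class_i_aat_example(self):
        g = discrimination_gap((8.36, 0.08), (5.25, 0.11))
        assert g.gap == pytest.approx(3.11)
        assert g.gap_stderr == pytest.approx(0.14, abs=0.005)

    def test_class_i_agc_example(self):
        g = discrimination_gap((10.21, 0.10), (5.25, 0.11))
        assert g.gap == pytest.approx(4.96)

    def test_identical_profiles(self):
        g = discrimination_gap((5.0, 0.2), (5.0, 0.2))
        assert g.gap == 0.0
        assert g.gap_stderr == pytest.approx(np.sqrt(2) * 0.2)

    def test_gap_identity_invariant(self):
        g = discrimination_gap((9.9, 0.1), (6.6, 0.2))
        assert g.gap == g.canonical - g.mismatch


class TestElasticConstant:
    def test_exact_quadratic_self_fit(self):
        centers = np.arange(125.0, 176.0, 2.5)
        vals = 0.5 * 0.01 * (centers - 160.0) ** 2
        p = profile_from_values(centers, vals)
        k, a0 = fit_elastic_constant(p)
        assert k == pytest.approx(0.01, abs=1e-6)
        assert a0 == pytest.approx(160.0, abs=1e-4)

    def test_noisy_recovery_median(self):
        centers = np.arange(128.0, 172.1, 2.0)
        ks = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vals = 0.5 * 0.01 * (centers - 155.0) ** 2 + \
                rng.normal(0, 0.05, centers.size)
            p = profile_from_values(centers, vals,
                                    stderr=np.full(centers.size, 0.05))
            k, _ = fit_elastic_constant(p)
            ks.append(k)
        assert np.median(ks) == pytest.approx(0.01, rel=0.10)

    def test_reference_constant_invariance(self):
        centers = np.arange(125.0, 176.0, 2.5)
        base = 0.5 * 0.02 * (centers - 150.0) ** 2
        k1, a1 = fit_elastic_constant(profile_from_values(centers, base))
        k2, a2 = fit_elastic_constant(profile_from_values(centers, base + 5.0))
        assert k1 == pytest.approx(k2, abs=1e-9)
        assert a1 == pytest.approx(a2, abs=1e-6)

    def test_nonconvex_warns(self):
        centers = np.arange(125.0, 176.0, 2.5)
        vals = -0.5 * 0.01 * (centers - 150.0) ** 2
        p = profile_from_values(centers, vals)
        with pytest.warns(UserWarning, match="non-convex"):
            k, _ = fit_elastic_constant(p)
        assert k <= 0

    def test_too_few_bins_rejected(self):
        p = profile_from_values(np.array([140.0, 150, 160]), np.zeros(3))
        with pytest.raises(ContractError):
            fit_elastic_constant(p)


class TestOverlay:
    def _surface(self):
        spec = GridSpec((-80, -4), (40, 4), (30, 16), (False, False))
        c = spec.center_grid()
        v = 0.002 * c[:, 0] ** 2 + 0.5 * c[:, 1] ** 2
        mask = np.zeros(len(v), bool)
        mask[v > 10.0] = True
        return FESurface(spec, v - v.min(), np.zeros_like(v), mask)

    def test_global_minimum_structure_zero(self, class_i_duplex):
        s = self._surface()
        recs = overlay_structures(s, [class_i_duplex])
        assert recs[0]["in_domain"]
        assert recs[0]["value"] == pytest.approx(0.0, abs=0.05)

    def test_masked_region_flagged(self, class_i_duplex):
        s = self._surface()
        far = perturb_central_pair(class_i_duplex, -70.0, 3.5)
        recs = overlay_structures(s, [far])
        assert recs[0]["in_domain"]
        assert recs[0]["masked"]

    def test_round_trip_with_perturb(self, class_i_duplex):
        s = self._surface()
        moved = perturb_central_pair(class_i_duplex, -30.0, 1.0)
        recs = overlay_structures(s, [moved])
        assert recs[0]["opening"] == pytest.approx(-30.0, abs=1e-6)
        assert recs[0]["shear"] == pytest.approx(1.0, abs=1e-6)
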