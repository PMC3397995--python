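"""Probe battery: field statistics, shift/gain/separability indices,
sensitivity vectors, compensation index, protocol simulation."""

import numpy as np
import pandas as pd
import pytest

from reachdepth import analysis as an, geometry3d as g3d, network as nw
from reachdepth.encoding import N_INPUTS, input_layout
from reachdepth.fixtures import (
    difference_field,
    gain_only_field,
    toy_single_path_network,
    identity_readout_network,
)


@pytest.fixture(scope="module")
def net():
    return identity_readout_network(seed=3, n_hlu=6)


class TestFieldStats:
    def _field(self, values, axes):
        return an.ResponseField(axes=axes, values=values, field="target_rf",
                                context=an.ProbeContext())

    def test_symmetric_peak_com_at_peak(self):
        g = np.arange(-7.0, 13.1, 1.0)  # grid symmetric about the peak
        f = self._field(np.exp(-0.5 * ((g - 3.0) / 2.0) ** 2)[:, None],
                        (g, np.array([0.0])))
        com, amax, _ = an.field_stats(f)
        assert com[0] == pytest.approx(3.0, abs=1e-9)
        assert amax[0] == 3.0

    def test_uniform_field_com_at_centroid(self):
        g0 = np.array([0.0, 1.0, 2.0])
        g1 = np.array([10.0, 20.0])
        f = self._field(np.ones((3, 2)), (g0, g1))
        com, amax, amin = an.field_stats(f)
        assert np.allclose(com, [1.0, 15.0])
        # ties break at the lowest grid index
        assert np.allclose(amax, [0.0, 10.0]) and np.allclose(amin, [0.0, 10.0])

    def test_two_gaussian_mixture_matches_closed_form(self):
        g = np.linspace(-20, 20, 401)
        w1, w2, c1, c2, s = 1.0, 0.5, -5.0, 8.0, 2.0
        f1 = w1 * np.exp(-0.5 * ((g - c1) / s) ** 2)
        f2 = w2 * np.exp(-0.5 * ((g - c2) / s) ** 2)
        field = self._field((f1 + f2)[:, None], (g, np.array([0.0])))
        com, _, _ = an.field_stats(field)
        expected = ((f1 + f2) * g).sum() / (f1 + f2).sum()
        assert com[0] == pytest.approx(expected, abs=1e-6)
        # closed form: weighted mean of the two centres (equal widths)
        assert com[0] == pytest.approx((w1 * c1 + w2 * c2) / (w1 + w2), abs=1e-3)

    def test_all_zero_field_raises(self):
        f = self._field(np.zeros((3, 3)), (np.arange(3.0), np.arange(3.0)))
        with pytest.raises(an.FieldStatsError):
            an.field_stats(f)


class TestProbing:
    def test_probe_is_deterministic(self, net):
        f1 = an.probe_response_field(net, "hlu", 2, "target_rf")
        f2 = an.probe_response_field(net, "hlu", 2, "target_rf")
        assert np.array_equal(f1.values, f2.values)

    def test_context_isolation_hand_inputs_constant(self, net):
        """Probing the target RF must leave hand-related inputs fixed."""
        ctx = an.ProbeContext()
        base = ctx.resolve(g3d.GeometryParams())
        axes, h, p = an.probe_layer(net, "target_rf", ctx)
        # reconstruct the input batch and verify hand slices are constant
        from reachdepth.analysis import _context_batch
        g0, g1 = np.meshgrid(axes[0], axes[1], indexing="ij")
        x = _context_batch(ctx, {("target_obs", 0): g0.ravel(),
                                 ("target_obs", 1): g1.ravel()},
                           g3d.GeometryParams())
        lay = input_layout()
        assert np.ptp(x[:, lay["hand_position"]], axis=0).max() == 0.0
        assert np.ptp(x[:, lay["vergence"]], axis=0).max() == 0.0
        assert np.ptp(x[:, lay["target_position"]], axis=0).max() > 0.0

    def test_single_input_unit_reproduces_its_tuning(self):
        """An HLU wired to exactly one position unit inherits (through
        the sigmoid) a field peaked at that unit's preferred direction."""
        from reachdepth.encoding import build_position_lattice
        lat = build_position_lattice()
        target_slice = input_layout()["target_position"]
        unit = int(np.flatnonzero((lat.x == 10) & (lat.z == -10))[0])
        net = toy_single_path_network(w_in_value=0.0)
        net.w_in[0, target_slice.start + unit] = 4.0
        field = an.probe_response_field(
            net, "hlu", 0, "target_rf",
            axes=(np.arange(-40.0, 41.0, 5.0), np.arange(-40.0, 41.0, 5.0)),
        )
        _, amax, _ = an.field_stats(field)
        assert amax[0] == lat.x[unit] and amax[1] == lat.z[unit]
        # activation at the peak matches the sigmoid of the tuning value
        peak = field.values.max()
        assert peak == pytest.approx(1 / (1 + np.exp(-4.0)), abs=1e-9)


class TestShiftIndex:
    def _shift_from_fields(self, levels, fields, grid):
        """Regression oracle on externally constructed 1-D fields."""
        coms = [(f * grid).sum() / f.sum() for f in fields]
        from scipy.stats import linregress
        return linregress(levels, coms).slope

    def test_translating_field_slope_one(self):
        from reachdepth.fixtures import translating_field
        grid = np.arange(-30.0, 30.1, 1.0)
        levels = np.arange(-5.0, 5.1, 1.0)
        slope = self._shift_from_fields(
            levels, [translating_field(grid, lv) for lv in levels], grid)
        assert slope == pytest.approx(1.0, abs=1e-4)

    def test_gain_only_field_slope_zero(self):
        grid = np.arange(-30.0, 30.1, 1.0)
        levels = np.arange(-5.0, 5.1, 1.0)
        slope = self._shift_from_fields(
            levels, [gain_only_field(grid, lv) for lv in levels], grid)
        assert slope == pytest.approx(0.0, abs=1e-9)

    def test_slope_recovered_under_activation_noise(self, rng):
        from reachdepth.fixtures import translating_field
        grid = np.arange(-30.0, 30.1, 1.0)
        levels = np.arange(-5.0, 5.1, 1.0)
        recovered = []
        for _ in range(20):
            fields = [
                np.clip(translating_field(grid, lv)
                        + rng.normal(0, 0.01, size=grid.shape), 0, None)
                for lv in levels
            ]
            recovered.append(self._shift_from_fields(levels, fields, grid))
        assert np.mean(np.abs(np.array(recovered) - 1.0)) < 0.05

    def test_network_shift_table_runs_and_is_deterministic(self, net):
        levels = np.array([4.0, 6.0, 8.0, 10.0])
        t1 = an.shift_index_table(net, "pou", [0, 1], "target_rd",
                                  "vergence", levels)
        t2 = an.shift_index_table(net, "pou", [0, 1], "target_rd",
                                  "vergence", levels)
        pd.testing.assert_frame_equal(t1, t2)

    def test_too_few_levels_rejected(self, net):
        with pytest.raises(ValueError):
            an.shift_index_table(net, "hlu", [0], "target_rf", "vergence",
                                 np.array([1.0, 2.0]))


class TestGainIndex:
    def test_constant_activity_gives_zero(self):
        net = toy_single_path_network(w_in_value=0.0)
        gi = an.gain_index(net, "hlu", 0, "vergence")
        assert gi.value == pytest.approx(0.0, abs=1e-12)
        assert not gi.modulated

    def test_three_to_one_ratio_gives_half(self):
        a = np.array([3.0, 1.0, 2.0])
        assert (a.max() - a.min()) / (a.max() + a.min()) == pytest.approx(0.5)
        # through the index machinery: a unit driven only by the vergence
        # input with activations in a 3:1 ratio across the vergence grid
        net = toy_single_path_network(w_in_value=0.0)
        lay = input_layout()
        net.w_in[0, lay["vergence"]] = 1.0
        cube_h, _ = an._gain_cube(net, an.ProbeContext(), g3d.GeometryParams())
        acts = cube_h[..., 0]
        amax, amin = acts.max(axis=0), acts.min(axis=0)
        expected = ((amax - amin) / (amax + amin)).mean()
        gi = an.gain_index(net, "hlu", 0, "vergence")
        assert gi.value == pytest.approx(expected, abs=1e-12)
        assert gi.value > 0

    def test_average_equals_enumeration_oracle(self, net):
        """Averaging over unrelated-parameter combinations equals the
        brute-force 4 x 5 x 5 enumeration."""
        params = g3d.GeometryParams()
        table = an.gain_index_table(net, "hlu", [1], ("hand_depth",))
        vals = []
        for f in an.GAIN_VERGENCE_FIX_CM:
            for t in an.GAIN_DEPTHS_CM:
                acts = []
                for h in an.GAIN_DEPTHS_CM:
                    from dataclasses import replace
                    ctx = replace(an.ProbeContext(), fixation_cm=f,
                                  hand_distance_cm=h, target_distance_cm=t)
                    base = ctx.resolve(params)
                    from reachdepth.encoding import encode_sample
                    x = encode_sample(base["hand_obs"], base["target_obs"],
                                      base["eye"], base["head"],
                                      float(base["vergence"]), params)
                    hact, _, _ = nw.forward(x, net)
                    acts.append(hact[1])
                acts = np.array(acts)
                vals.append((acts.max() - acts.min()) / (acts.max() + acts.min()))
        assert table.iloc[0].value == pytest.approx(np.mean(vals), abs=1e-10)


class TestSensitivityVectors:
    def test_zeroed_vergence_weights_give_zero_sensitivity(self):
        net = identity_readout_network(seed=0)
        lay = input_layout()
        net.w_in[:, lay["vergence"]] = 0.0
        for unit in range(net.n_hlu):
            assert np.all(an.sensitivity_vector(net, "hlu", unit, "vergence") == 0)
        for unit in range(net.n_pou):
            assert np.allclose(
                an.sensitivity_vector(net, "pou", unit, "vergence"), 0.0)

    def test_single_path_product(self):
        net = toy_single_path_network(w_in_value=0.7, w_out_value=-0.4)
        s_hlu = an.sensitivity_vector(net, "hlu", 0, "vergence")
        s_pou = an.sensitivity_vector(net, "pou", 0, "vergence")
        assert s_hlu == pytest.approx([0.7])
        assert s_pou == pytest.approx([0.7 * -0.4])

    def test_pou_sensitivity_matches_linearised_derivative(self, net):
        """The weight product equals the derivative of the POU
        pre-activation path through the linearised hidden layer."""
        lay = input_layout()
        x0 = np.full(N_INPUTS, 0.3)
        idx = lay["vergence"].start
        unit = 2
        eps = 1e-6
        s = an.sensitivity_vector(net, "pou", unit, "vergence")[0]

        def pou_preact_linear(x):
            # hidden layer linearised around x0's operating point
            z_h = net.w_in @ x + net.b_hlu
            h0 = 1 / (1 + np.exp(-(net.w_in @ x0 + net.b_hlu)))
            h_lin = h0 + h0 * (1 - h0) * (z_h - (net.w_in @ x0 + net.b_hlu))
            return (net.w_out @ h_lin)[unit]

        xp, xm = x0.copy(), x0.copy()
        xp[idx] += eps; xm[idx] -= eps
        fd = (pou_preact_linear(xp) - pou_preact_linear(xm)) / (2 * eps)
        h0 = 1 / (1 + np.exp(-(net.w_in @ x0 + net.b_hlu)))
        gains = h0 * (1 - h0)
        expected = (net.w_out[unit] * gains) @ net.w_in[:, idx]
        assert fd == pytest.approx(expected, rel=1e-5)
        # the raw sensitivity is the same contraction without the local
        # sigmoid gains
        assert s == pytest.approx(net.w_out[unit] @ net.w_in[:, idx], rel=1e-12)

    def test_unknown_group_rejected(self, net):
        with pytest.raises(ValueError):
            an.sensitivity_vector(net, "hlu", 0, "retina")


class TestSeparability:
    def test_single_variable_axis0_gives_zero(self):
        h = np.linspace(0, 1, 9)
        f = np.tile(np.exp(-(h - 0.4) ** 2)[:, None], (1, 9))
        assert an.separability_angle(f) == pytest.approx(0.0, abs=1e-9)

    def test_single_variable_axis1_gives_180(self):
        t = np.linspace(0, 1, 9)
        f = np.tile(t**2 + 0.1, (9, 1))
        assert an.separability_angle(f) == pytest.approx(180.0, abs=1e-9)

    def test_difference_field_gives_minus_90(self):
        lv = np.linspace(-20, 20, 11)
        f = difference_field(lv, lv)
        assert an.separability_angle(f) == pytest.approx(-90.0, abs=1.0)

    def test_sum_field_gives_plus_90(self):
        lv = np.linspace(-20, 20, 11)
        a, b = np.meshgrid(lv, lv, indexing="ij")
        f = np.exp(-0.5 * ((a + b) / 15.0) ** 2)
        assert an.separability_angle(f) == pytest.approx(90.0, abs=1.0)

    def test_flat_field_flagged(self):
        with pytest.raises(an.FieldStatsError):
            an.separability_angle(np.ones((5, 5)))

    def test_network_table(self, net):
        t = an.separability_table(net, "hlu", [0, 1], ("hand", "target"),
                                  np.arange(30.0, 71.0, 10.0))
        assert len(t) == 2
        assert t.angle_deg.between(-180, 180).all()


class TestCompensationIndex:
    def test_perfect_network_slope_exactly_one(self, small_set, rng):
        nc = g3d.no_compensation_vectors(small_set)
        observed = small_set.motor_cm - nc
        predicted = small_set.motor_cm - nc
        assert an.compensation_slope(observed, predicted) == pytest.approx(1.0)

    def test_context_blind_network_slope_near_zero(self, small_set):
        """A read-out that reproduces the default-context reconstruction
        itself ignores all extra-retinal signals: slope ~ 0."""
        nc = g3d.no_compensation_vectors(small_set)
        observed = nc - nc  # decoded == no-compensation vector
        predicted = small_set.motor_cm - nc
        assert abs(an.compensation_slope(observed, predicted)) < 1e-12

    def test_slope_invariant_to_sample_relabelling(self, small_set, rng):
        nc = g3d.no_compensation_vectors(small_set)
        m_hat = small_set.motor_cm * 0.8  # arbitrary imperfect decode
        perm = rng.permutation(len(small_set))
        s1 = an.compensation_slope(m_hat - nc, small_set.motor_cm - nc)
        s2 = an.compensation_slope((m_hat - nc)[perm],
                                   (small_set.motor_cm - nc)[perm])
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_all_default_context_testset_rejected(self):
        with pytest.raises(ValueError):
            an.compensation_slope(np.zeros((5, 3)), np.zeros((5, 3)))


class TestFerrainaProtocol:
    def test_cell_count_and_determinism(self, net):
        t = an.ferraina_protocol(net)
        per_unit = t.groupby(["layer", "unit"]).size()
        assert (per_unit == 45).all()  # 5 targets x 3 hands x 3 fixations
        t2 = an.ferraina_protocol(net)
        pd.testing.assert_frame_equal(t, t2)

    def test_vergence_gain_only_unit_scales_but_does_not_shift(self):
        """A unit driven by target disparity and multiplicatively by
        vergence has tuning curves that rescale across fixation distance
        but peak at the same target distance."""
        net = toy_single_path_network(w_in_value=0.0)
        lay = input_layout()
        from reachdepth.encoding import build_disparity_lattice
        lat = build_disparity_lattice()
        unit = int(np.flatnonzero((lat.x == 0) & (lat.z == 0))[0])
        net.w_in[0, lay["target_disparity"].start + unit] = 3.0
        net.w_in[0, lay["vergence"]] = 1.5
        t = an.ferraina_protocol(net)
        hlu = t[(t.layer == "hlu") & (t.hand_cm == 50.0)]
        peaks = hlu.loc[hlu.groupby("fixation_cm").activation.idxmax()]
        # peak always at the target nearest the fixation distance
        for _, row in peaks.iterrows():
            assert row.target_cm == min(
                an.FERRAINA_TARGETS_CM, key=lambda d: abs(d - row.fixation_cm))
        # overall level scales with vergence (nearer fixation = higher)
        means = hlu.groupby("fixation_cm").activation.mean()
        assert means.loc[30.0] > means.loc[80.0]


class TestVarianceRatio:
    def test_wider_distribution_detected(self, rng):
        wide = rng.normal(0, 1.0, 200)
        narrow = rng.normal(0, 0.3, 200)
        f, p = an.variance_ratio_test(wide, narrow)
        assert f > 1 and p < 0.01
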