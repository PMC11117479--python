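import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gradchip import (
    ConcentrationState,
    Path,
    PulseEvent,
    ReplacementProfile,
    apply_pulse,
    default_profile,
    oriented_fractions,
    run_schedule,
    steady_state_limit,
)
from gradchip.errors import ShapeError, ValidationError


def make_pulse(species="EGF", inlet=500.0, path=Path.PATH1, profile=None):
    return PulseEvent(
        species=species,
        channel=1,
        path=path,
        inlet_concentration=inlet,
        profile=profile or default_profile(),
    )


class TestDefaultProfile:
    def test_calibrated_fractions(self):
        p = default_profile()
        assert p.fractions == (0.2248, 0.2003, 0.1716, 0.1387, 0.1128)
        assert p.fractions[0] == 0.2248
        assert p.fractions[4] == 0.1128
        assert p.flow_speed_mm_s == 5.0
        assert p.duration_s == 4.0

    def test_strictly_decreasing(self):
        assert all(np.diff(default_profile().fractions) < 0)

    def test_profile_invariants_enforced(self):
        with pytest.raises(ValidationError):
            ReplacementProfile(5.0, 4.0, (0.5, 0.6))  # increasing
        with pytest.raises(ValidationError):
            ReplacementProfile(5.0, 4.0, (1.0, 0.5))  # not in (0, 1)
        with pytest.raises(ValidationError):
            ReplacementProfile(5.0, 4.0, ())


class TestOrientedFractions:
    def test_path1_keeps_order(self, profile):
        assert oriented_fractions(profile, Path.PATH1)[0] == 0.2248

    def test_path2_reverses(self, profile):
        assert oriented_fractions(profile, Path.PATH2)[0] == 0.1128
        assert oriented_fractions(profile, Path.PATH2) == tuple(
            reversed(profile.fractions)
        )

    def test_constant_profile_is_path_invariant(self):
        # the only monotone palindromes are constant profiles
        p = ReplacementProfile(5.0, 4.0, (0.2, 0.2, 0.2))
        assert oriented_fractions(p, Path.PATH1) == oriented_fractions(p, Path.PATH2)

    def test_single_chamber_profile_is_path_invariant(self):
        p = ReplacementProfile(5.0, 4.0, (0.25,))
        assert oriented_fractions(p, Path.PATH1) == oriented_fractions(p, Path.PATH2)

    def test_path_parsing(self):
        assert Path.parse("PATH-1") is Path.PATH1
        assert Path.parse(2) is Path.PATH2
        with pytest.raises(ValidationError):
            Path.parse("sideways")


class TestApplyPulse:
    def test_single_pulse_from_drug_free(self):
        state = ConcentrationState.blank(5, ["EGF"])
        new = apply_pulse(state, make_pulse(inlet=500.0))
        assert new.value(1, "EGF") == pytest.approx(112.40)
        assert new.time_s == 4.0

    def test_zero_inlet_keeps_chambers_clean(self):
        state = ConcentrationState.blank(5, ["EGF"])
        new = apply_pulse(state, make_pulse(inlet=0.0))
        assert np.all(new.concentrations == 0.0)

    def test_two_identical_pulses_match_unrolled_recurrence(self):
        # oracle: c2 = 500 * (1 - (1 - 0.2248)^2) = 199.53248
        state = ConcentrationState.blank(5, ["EGF"])
        pulse = make_pulse(inlet=500.0)
        state = apply_pulse(apply_pulse(state, pulse), pulse)
        assert state.value(1, "EGF") == pytest.approx(500 * (1 - 0.7752**2))
        assert state.value(1, "EGF") == pytest.approx(199.53248)

    def test_chamber_count_mismatch(self):
        state = ConcentrationState.blank(4, ["EGF"])
        with pytest.raises(ShapeError):
            apply_pulse(state, make_pulse())

    def test_unregistered_species(self):
        state = ConcentrationState.blank(5, ["FGF"])
        with pytest.raises(KeyError):
            apply_pulse(state, make_pulse(species="EGF"))

    def test_other_species_untouched(self):
        state = ConcentrationState(
            ("EGF", "FGF"), np.full((5, 2), 10.0), time_s=0.0
        )
        new = apply_pulse(state, make_pulse(species="EGF", inlet=500.0))
        assert np.all(new.concentrations[:, 1] == 10.0)


class TestRunSchedule:
    def test_empty_schedule_is_identity(self):
        state = ConcentrationState.blank(5, ["EGF"])
        trajectory = run_schedule(state, [])
        assert trajectory == [state]

    def test_single_pulse_equals_apply_pulse(self):
        state = ConcentrationState.blank(5, ["EGF"])
        pulse = make_pulse()
        trajectory = run_schedule(state, [pulse])
        assert len(trajectory) == 2
        np.testing.assert_array_equal(
            trajectory[-1].concentrations, apply_pulse(state, pulse).concentrations
        )

    def test_alternating_paths_middle_chamber(self):
        # chamber 3 of 5 has the same fraction in both directions
        state = ConcentrationState.blank(5, ["EGF"])
        pulses = [make_pulse(path=Path.PATH1), make_pulse(path=Path.PATH2)]
        final = run_schedule(state, pulses)[-1]
        f3 = default_profile().fractions[2]
        assert final.value(3, "EGF") == pytest.approx(500 * (1 - (1 - f3) ** 2))

    def test_trajectory_length(self):
        state = ConcentrationState.blank(5, ["EGF"])
        trajectory = run_schedule(state, [make_pulse()] * 7)
        assert len(trajectory) == 8
        assert trajectory[-1].time_s == pytest.approx(28.0)


class TestSteadyStateLimit:
    def test_zero_pulses_is_drug_free(self):
        state = steady_state_limit(make_pulse(), 0)
        assert np.all(state.concentrations == 0.0)

    def test_one_pulse_is_base_case(self):
        state = steady_state_limit(make_pulse(inlet=500.0), 1)
        expected = apply_pulse(ConcentrationState.blank(5, ["EGF"]), make_pulse())
        np.testing.assert_allclose(state.concentrations, expected.concentrations)

    def test_fifty_pulses_saturate(self):
        state = steady_state_limit(make_pulse(inlet=500.0), 50)
        assert np.all(state.concentrations > 500.0 * (1 - 0.003))

    @pytest.mark.parametrize("n", [1, 2, 5, 17, 50])
    def test_closed_form_matches_iterated_pulses(self, n):
        pulse = make_pulse(inlet=500.0)
        state = ConcentrationState.blank(5, ["EGF"])
        for _ in range(n):
            state = apply_pulse(state, pulse)
        closed = steady_state_limit(pulse, n)
        np.testing.assert_allclose(
            state.concentrations, closed.concentrations, rtol=1e-12, atol=1e-12
        )

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            steady_state_limit(make_pulse(), -1)


concentration = st.floats(0.0, 1000.0)


class TestScheduleProperties:
    @settings(deadline=None, max_examples=60)
    @given(
        inlets=st.lists(concentration, min_size=1, max_size=8),
        paths=st.lists(st.sampled_from([Path.PATH1, Path.PATH2]), min_size=8, max_size=8),
    )
    def test_boundedness(self, inlets, paths):
        state = ConcentrationState.blank(5, ["EGF"])
        pulses = [
            make_pulse(inlet=c, path=p) for c, p in zip(inlets, paths)
        ]
        final = run_schedule(state, pulses)[-1]
        assert np.all(final.concentrations >= 0.0)
        assert np.all(final.concentrations <= max(inlets) + 1e-9)

    @settings(deadline=None, max_examples=40)
    @given(n=st.integers(1, 30), inlet=st.floats(1.0, 1000.0))
    def test_monotone_approach_to_inlet(self, n, inlet):
        state = ConcentrationState.blank(5, ["EGF"])
        pulse = make_pulse(inlet=inlet)
        previous = state.concentrations
        for _ in range(n):
            state = apply_pulse(state, pulse)
            assert np.all(state.concentrations >= previous - 1e-12)
            assert np.all(state.concentrations <= inlet + 1e-9)
            previous = state.concentrations

    @settings(deadline=None, max_examples=40)
    @given(
        inlet_a=st.floats(1.0, 1000.0),
        inlet_b=st.floats(1.0, 1000.0),
        n=st.integers(1, 5),
    )
    def test_species_independence(self, inlet_a, inlet_b, n):
        state = ConcentrationState.blank(5, ["A", "B"])
        pa = make_pulse(species="A", inlet=inlet_a)
        pb = make_pulse(species="B", inlet=inlet_b, path=Path.PATH2)
        only_a = run_schedule(state, [pa] * n)[-1]
        interleaved = run_schedule(state, [pa, pb] * n)[-1]
        np.testing.assert_allclose(
            only_a.concentrations[:, 0], interleaved.concentrations[:, 0]
        )
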