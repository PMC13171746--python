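"""Cumulative margin model: arithmetic, phase semantics, invariants."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from margingate import (
    DomainError,
    MembraneState,
    Modifier,
    ModifierKind,
    apply_scenario,
    compute_margin,
    gamma_from_rheobase,
    percent_reduction,
    round_half_up,
)


def _mods(gamma=None, chronic=(), acute=()):
    mods = []
    if gamma is not None:
        mods.append(Modifier("gamma", ModifierKind.COMPRESSION, gamma))
    mods += [Modifier(f"c{i}", ModifierKind.CHRONIC_SHIFT, m) for i, m in enumerate(chronic)]
    mods += [Modifier(f"a{i}", ModifierKind.ACUTE_SHIFT, m) for i, m in enumerate(acute)]
    return mods


class TestComputeMargin:
    @pytest.mark.parametrize(
        "v_thr, v_rest, expected",
        [(-50.0, -68.4, 18.4), (0.0, -10.0, 10.0), (-48.0, -66.4, 18.4)],
    )
    def test_difference(self, v_thr, v_rest, expected):
        assert compute_margin(v_thr, v_rest) == pytest.approx(expected)

    @pytest.mark.parametrize("v_thr, v_rest", [(-50, -50), (-60, -50), (float("nan"), -60)])
    def test_rejects_nonpositive_or_nonfinite(self, v_thr, v_rest):
        with pytest.raises(DomainError):
            compute_margin(v_thr, v_rest)

    def test_error_names_both_values(self):
        with pytest.raises(DomainError, match="-50.*-50"):
            compute_margin(-50, -50)


class TestMembraneState:
    def test_from_potentials_derives_margin(self):
        state = MembraneState.from_potentials(v_rest=-68.4, v_thr=-50.0)
        assert state.margin == pytest.approx(18.4)

    def test_margin_only_baseline(self):
        assert MembraneState.from_margin(18.4).margin == 18.4

    def test_inconsistent_triple_rejected(self):
        with pytest.raises(DomainError):
            MembraneState(margin=5.0, v_rest=-68.4, v_thr=-50.0)

    def test_nonpositive_margin_rejected(self):
        with pytest.raises(DomainError):
            MembraneState.from_margin(0.0)


class TestGammaFromRheobase:
    def test_crs_ratio(self):
        assert gamma_from_rheobase(56, 100) == pytest.approx(0.56)

    def test_no_stress_effect(self):
        assert gamma_from_rheobase(100, 100) == 1.0

    def test_widening_ratio_returned_but_unusable_as_compression(self):
        ratio = gamma_from_rheobase(120, 100)
        assert ratio == pytest.approx(1.2)
        with pytest.raises(DomainError):
            Modifier("g", ModifierKind.COMPRESSION, ratio)

    @pytest.mark.parametrize("stress, ctrl", [(0, 100), (-5, 100), (50, 0)])
    def test_degenerate_rheobase(self, stress, ctrl):
        with pytest.raises(DomainError):
            gamma_from_rheobase(stress, ctrl)


class TestApplyScenario:
    def test_main_scenario(self):
        result = apply_scenario(18.4, _mods(0.56, chronic=[2.0], acute=[3.2]))
        assert result.effective_margin == pytest.approx(5.984)
        assert result.effective_margin_printed == 6.0
        assert result.percent_reduction_printed == 67.5
        assert not result.clamped

    def test_identity_scenario(self):
        result = apply_scenario(18.4, [])
        assert result.effective_margin == 18.4
        assert result.percent_reduction == 0.0

    def test_strong_inflammation_variant(self):
        result = apply_scenario(18.4, _mods(0.56, chronic=[6.0], acute=[3.2]))
        assert result.effective_margin == pytest.approx(3.744)
        assert result.effective_margin_printed == 3.7

    def test_floor_at_zero_sets_clamped(self):
        result = apply_scenario(18.4, _mods(0.56, chronic=[2.0], acute=[100.0]))
        assert result.effective_margin == 0.0
        assert result.clamped
        assert result.percent_reduction == 100.0

    def test_membrane_state_baseline_accepted(self):
        state = MembraneState.from_margin(18.4)
        result = apply_scenario(state, _mods(0.56, chronic=[2.0], acute=[3.2]))
        assert result.effective_margin == pytest.approx(5.984)

    def test_disabled_modifiers_skipped(self):
        mods = _mods(0.56, chronic=[2.0], acute=[3.2])
        mods = [m.disabled() for m in mods]
        assert apply_scenario(18.4, mods).effective_margin == 18.4

    def test_chronic_consuming_baseline_is_domain_error(self):
        with pytest.raises(DomainError):
            apply_scenario(18.4, _mods(0.56, chronic=[18.4], acute=[]))

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(DomainError):
            apply_scenario(0.0, [])

    def test_decomposition_chains(self):
        result = apply_scenario(18.4, _mods(0.56, chronic=[2.0], acute=[3.2]))
        steps = result.decomposition
        assert steps[0].before == 18.4
        for prev, nxt in zip(steps, steps[1:]):
            assert prev.after == nxt.before
        assert steps[-1].after == result.effective_margin

    def test_multiple_compressions_multiply(self):
        result = apply_scenario(10.0, _mods(None) + [
            Modifier("g1", ModifierKind.COMPRESSION, 0.5),
            Modifier("g2", ModifierKind.COMPRESSION, 0.5),
        ])
        assert result.effective_margin == pytest.approx(2.5)


class TestPercentReduction:
    @pytest.mark.parametrize(
        "baseline, effective, expected",
        [(18.4, 5.984, 67.47826086956522), (18.4, 18.4, 0.0), (10.0, 0.0, 100.0)],
    )
    def test_values(self, baseline, effective, expected):
        assert percent_reduction(baseline, effective) == pytest.approx(expected)

    def test_main_scenario_prints_67_5(self):
        assert round_half_up(percent_reduction(18.4, 5.984), 1) == 67.5

    def test_widening_out_of_domain(self):
        with pytest.raises(DomainError):
            percent_reduction(10.0, 12.0)


class TestRounding:
    @pytest.mark.parametrize(
        "x, expected",
        [(5.984, 6.0), (3.744, 3.7), (4.304, 4.3), (1.684, 1.7), (5.25, 5.3), (5.15, 5.2)],
    )
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(x, 1) == expected


# --- property tests -------------------------------------------------------

valid_gamma = st.floats(0.05, 1.0, allow_nan=False)
small_shift = st.floats(0.0, 3.0, allow_nan=False)
baseline_st = st.floats(10.0, 30.0, allow_nan=False)


@given(
    baseline=baseline_st,
    gamma=valid_gamma,
    chronic=st.lists(small_shift, max_size=3),
    acute=st.lists(small_shift, max_size=3),
    data=st.data(),
)
def test_phase_order_invariance(baseline, gamma, chronic, acute, data):
    """Permuting the modifier input order never changes the result."""
    mods = _mods(gamma, chronic=chronic, acute=acute)
    shuffled = data.draw(st.permutations(mods))
    a = apply_scenario(baseline, mods)
    b = apply_scenario(baseline, shuffled)
    assert a.effective_margin == pytest.approx(b.effective_margin, abs=1e-12)


@given(baseline=baseline_st, gamma=valid_gamma, chronic=small_shift, acute=small_shift)
def test_oracle_equivalence(baseline, gamma, chronic, acute):
    """apply_scenario equals direct evaluation of gamma*(M0 - chronic) - acute floored at 0."""
    expected = max(0.0, gamma * (baseline - chronic) - acute)
    result = apply_scenario(baseline, _mods(gamma, chronic=[chronic], acute=[acute]))
    assert result.effective_margin == pytest.approx(expected, abs=1e-12)


@given(
    baseline=baseline_st,
    gamma=valid_gamma,
    chronic=small_shift,
    acute=small_shift,
    extra_kind=st.sampled_from(["compression", "chronic_shift", "acute_shift"]),
    extra_mag=st.floats(0.05, 0.95),
)
def test_adding_a_hit_never_increases_margin(baseline, gamma, chronic, acute, extra_kind, extra_mag):
    mods = _mods(gamma, chronic=[chronic], acute=[acute])
    before = apply_scenario(baseline, mods).effective_margin
    extra = Modifier("extra", ModifierKind(extra_kind), extra_mag)
    after = apply_scenario(baseline, mods + [extra]).effective_margin
    assert after <= before + 1e-12


@given(baseline=baseline_st, chronic=small_shift, acute=small_shift)
def test_margin_affine_in_compression(baseline, chronic, acute):
    """For fixed shifts the unclamped margin is affine in gamma with slope (M0 - chronic)."""

    def margin(g):
        return g * (baseline - chronic) - acute  # unclamped closed form

    g1, g2 = 0.3, 0.9
    slope = (margin(g2) - margin(g1)) / (g2 - g1)
    assert slope == pytest.approx(baseline - chronic, rel=1e-9)
    # the model agrees with the closed form wherever the floor is inactive
    for g in (g1, g2):
        result = apply_scenario(baseline, _mods(g, chronic=[chronic], acute=[acute]))
        assert result.effective_margin == pytest.approx(max(0.0, margin(g)), abs=1e-12)
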