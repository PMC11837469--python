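"""Truncation-selection engine: differentials, responses, control."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from irmsim import (
    DegenerateExtinctionError,
    ExposureConfig,
    Mixture,
    ModelParams,
    Monotherapy,
    PopulationState,
    apply_cross_resistance,
    breeders_response,
    degree_of_control,
    field_survival,
    mixture_selection_differentials,
    mono_selection_differential,
    prs_to_bioassay,
    selection_intensity,
    single_generation_step,
)

PARAMS = ModelParams()


def truncated_mean_by_integration(p: float) -> float:
    """Independent oracle: mean of the top-p normal tail via quadrature."""
    q = norm.isf(p)
    val, _ = quad(lambda z: z * norm.pdf(z), q, 12.0)
    return val / p


class TestSelectionIntensity:
    def test_no_selection_at_full_survival(self):
        assert selection_intensity(1.0) == 0.0

    @pytest.mark.parametrize(
        "p,expected",
        [(0.5, 0.7978845608), (0.05, 2.0627128075)],  # frozen from the quadrature oracle
    )
    def test_closed_form_matches_quadrature(self, p, expected):
        assert selection_intensity(p) == pytest.approx(expected, abs=1e-8)
        assert selection_intensity(p) == pytest.approx(
            truncated_mean_by_integration(p), abs=1e-8
        )

    def test_domain_error_below_zero(self):
        with pytest.raises(ValueError):
            selection_intensity(0.0)
        with pytest.raises(ValueError):
            selection_intensity(-0.1)

    def test_tiny_survival_clamped_to_floor(self):
        assert np.isfinite(selection_intensity(1e-15))
        assert selection_intensity(1e-15) == selection_intensity(1e-10)

    def test_monotone_decreasing_in_survival(self):
        p = np.linspace(0.001, 1.0, 500)
        assert np.all(np.diff(selection_intensity(p)) < 0)


class TestMonotherapyDifferential:
    def test_zero_without_exposure_or_with_useless_insecticide(self):
        state = PopulationState(mean_prs_i=100.0)
        s, _ = mono_selection_differential(state, "i", 1.0, 0.0, PARAMS)
        assert s == 0.0
        s, p = mono_selection_differential(state, "i", 0.0, 0.7, PARAMS)
        assert s == 0.0 and p == 1.0

    def test_full_exposure_fully_susceptible(self):
        # p = field survival of susceptibles at full dose = phi2 = 0.15
        state = PopulationState(mean_prs_i=0.0, sigma=20.0)
        s, p = mono_selection_differential(state, "i", 1.0, 1.0, PARAMS)
        assert p == pytest.approx(0.15)
        assert s == pytest.approx(20.0 * selection_intensity(0.15), rel=1e-12)

    def test_dilution_by_unexposed(self):
        state = PopulationState(mean_prs_i=0.0, sigma=20.0)
        s_full, p = mono_selection_differential(state, "i", 1.0, 1.0, PARAMS)
        s_part, _ = mono_selection_differential(state, "i", 1.0, 0.5, PARAMS)
        expected = 0.5 * p * 20.0 * selection_intensity(p) / (0.5 + 0.5 * p)
        assert s_part == pytest.approx(expected, rel=1e-12)
        assert s_part < s_full

    def test_extinction_when_all_exposed_and_killed(self):
        state = PopulationState(mean_prs_i=0.0)
        with pytest.raises(DegenerateExtinctionError):
            mono_selection_differential(state, "i", 1.2, 1.0, PARAMS)
        # with escapees the differential is simply zero
        s, _ = mono_selection_differential(state, "i", 1.2, 0.9, PARAMS)
        assert s == 0.0


class TestMixtureDifferentials:
    def test_ineffective_partner_reduces_to_monotherapy(self):
        state = PopulationState(200.0, 500.0)
        s_mix, _, p_i, p_j = mixture_selection_differentials(state, 0.8, 0.0, 0.6, PARAMS)
        s_mono, _ = mono_selection_differential(state, "i", 0.8, 0.6, PARAMS)
        assert p_j == 1.0
        assert s_mix == pytest.approx(s_mono, rel=1e-12)

    def test_symmetry(self):
        state = PopulationState(300.0, 300.0)
        s_i, s_j, p_i, p_j = mixture_selection_differentials(state, 0.7, 0.7, 0.5, PARAMS)
        assert s_i == pytest.approx(s_j)
        assert p_i == pytest.approx(p_j)

    def test_full_exposure_independent_of_partner(self):
        state = PopulationState(200.0, 0.0)
        s_ref, *_ = mixture_selection_differentials(state, 0.9, 0.1, 1.0, PARAMS)
        for eff_j in (0.3, 0.6, 1.0):
            s_i, *_ = mixture_selection_differentials(state, 0.9, eff_j, 1.0, PARAMS)
            assert s_i == pytest.approx(s_ref, rel=1e-12)

    def test_effective_partner_dilutes_selection(self):
        # more effective partner -> smaller differential on the focal trait
        state = PopulationState(200.0, 200.0)
        values = [
            mixture_selection_differentials(state, 0.9, eff_j, 0.6, PARAMS)[0]
            for eff_j in np.linspace(0.0, 1.2, 13)
        ]
        assert np.all(np.diff(values) < 0)

    def test_requires_two_traits(self):
        with pytest.raises(ValueError):
            mixture_selection_differentials(PopulationState(0.0), 1.0, 1.0, 0.5, PARAMS)


class TestResponses:
    def test_breeders_equation_arithmetic(self):
        assert breeders_response(10.0, 10.0, 0.2, 1.0) == pytest.approx(2.0)
        assert breeders_response(10.0, 10.0, 0.0, 1.0) == 0.0
        assert breeders_response(10.0, 10.0, 0.2, 2.0) == pytest.approx(4.0)
        assert breeders_response(6.0, 10.0, 0.5, 1.0) == pytest.approx(4.0)

    def test_no_cross_resistance_keeps_direct_responses(self):
        t_i, t_j = apply_cross_resistance(3.0, 1.0, 15.0, 5.0, ModelParams())
        assert (t_i, t_j) == (3.0, 1.0)

    def test_correlated_response_sign_and_magnitude(self):
        params = ModelParams(cross_resistance=0.3, h2_i=0.2, h2_j=0.2)
        t_i, _ = apply_cross_resistance(0.0, 0.0, 0.0, 10.0, params)
        assert t_i == pytest.approx(0.3 * 0.2 * 10.0)  # 0.6
        negative = ModelParams(cross_resistance=-0.3)
        t_i, _ = apply_cross_resistance(0.0, 0.0, 0.0, 10.0, negative)
        assert t_i < 0

    def test_unequal_heritabilities_use_geometric_mean(self):
        params = ModelParams(cross_resistance=0.5, h2_i=0.1, h2_j=0.4)
        t_i, _ = apply_cross_resistance(0.0, 0.0, 0.0, 10.0, params)
        assert t_i == pytest.approx(0.5 * np.sqrt(0.04) * 10.0)


class TestDegreeOfControl:
    @pytest.mark.parametrize(
        "x,p,expected", [(1.0, 0.0, 1.0), (0.7, 0.5, 0.35), (0.9, 1.0, 0.0)]
    )
    def test_closed_form(self, x, p, expected):
        assert degree_of_control(x, p) == pytest.approx(expected)

    def test_monotone_in_exposure(self):
        x = np.linspace(0, 1, 101)
        assert np.all(np.diff(degree_of_control(x, 0.3)) >= 0)


class TestSingleGenerationStep:
    def test_no_exposure_leaves_state_unchanged(self):
        state = PopulationState(150.0, 250.0)
        outcome, new = single_generation_step(
            state, Mixture(1.0, 1.0), ExposureConfig(female_exposure=0.0), PARAMS
        )
        assert new == state
        assert outcome.response_i == 0.0 and outcome.response_j == 0.0

    def test_equal_male_exposure_gives_equal_differentials(self):
        state = PopulationState(100.0, 0.0)
        outcome, _ = single_generation_step(
            state, Monotherapy("i", 1.0), ExposureConfig(0.7, male_ratio=1.0), PARAMS
        )
        assert outcome.differential_female_i == outcome.differential_male_i

    def test_reduced_male_exposure_reduces_male_differential(self):
        state = PopulationState(100.0, 0.0)
        outcome, _ = single_generation_step(
            state, Monotherapy("i", 1.0), ExposureConfig(0.7, male_ratio=0.5), PARAMS
        )
        assert outcome.differential_male_i < outcome.differential_female_i

    def test_step_composes_primitives(self):
        # one step from a susceptible population reproduces the explicit
        # differential -> Breeder's equation -> new-mean chain
        state = PopulationState(0.0, sigma=20.0)
        x = 0.7
        s, p = mono_selection_differential(state, "i", 1.0, x, PARAMS)
        expected_response = breeders_response(s, s, PARAMS.h2_i, PARAMS.exposure_scaling)
        outcome, new = single_generation_step(
            state, Monotherapy("i", 1.0), ExposureConfig(x), PARAMS
        )
        assert outcome.response_i == pytest.approx(expected_response, rel=1e-12)
        assert new.mean_prs_i == pytest.approx(expected_response, rel=1e-12)
        delta_bioassay = 100 * (prs_to_bioassay(new.mean_prs_i) - prs_to_bioassay(0.0))
        assert delta_bioassay > 0
        assert outcome.degree_of_control == pytest.approx(x * (1 - p))

    def test_cost_differentials_pull_means_down(self):
        params = ModelParams(
            cost_differential_i_female=5.0, cost_differential_i_male=5.0
        )
        state = PopulationState(500.0, 0.0)
        _, new = single_generation_step(state, None, ExposureConfig(0.0), params)
        assert new.mean_prs_i == pytest.approx(500.0 - 0.2 * 5.0)
        assert new.mean_prs_j == 0.0

    def test_monotherapy_drives_partner_only_through_cross_resistance(self):
        state = PopulationState(100.0, 100.0)
        outcome, _ = single_generation_step(
            state, Monotherapy("i", 1.0), ExposureConfig(0.7), ModelParams()
        )
        assert outcome.response_j == 0.0
        coupled, _ = single_generation_step(
            state, Monotherapy("i", 1.0), ExposureConfig(0.7),
            ModelParams(cross_resistance=0.3),
        )
        assert coupled.response_j > 0

    def test_zero_cost_nonnegative_responses_with_nonnegative_alpha(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            state = PopulationState(rng.uniform(0, 2000), rng.uniform(0, 2000))
            params = ModelParams(cross_resistance=rng.choice([0.0, 0.3]))
            outcome, _ = single_generation_step(
                state,
                Mixture(rng.uniform(0, 1.2), rng.uniform(0, 1.2)),
                ExposureConfig(rng.uniform(0.05, 0.95)),
                params,
            )
            assert outcome.response_i >= 0 and outcome.response_j >= 0


class TestShapeProperties:
    def test_hump_over_efficacy_when_escape_dilutes(self):
        """With escapees, the response peaks at an intermediate efficacy."""
        state = PopulationState(100.0, sigma=20.0)  # 10% initial bioassay survival
        efficacies = np.linspace(0, 1.2, 13)
        for x in (0.3, 0.5, 0.7):
            s = [mono_selection_differential(state, "i", w, x, PARAMS)[0] for w in efficacies]
            peak = int(np.argmax(s))
            assert 0 < peak < len(s) - 1

    def test_strictly_increasing_at_full_exposure(self):
        state = PopulationState(225.0, sigma=20.0)
        efficacies = np.linspace(0, 1.2, 13)
        s = [mono_selection_differential(state, "i", w, 1.0, PARAMS)[0] for w in efficacies]
        assert np.all(np.diff(s) > 0)
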