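"""Regulatory functions, reaction terms, and model-variant algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rootniche import (
    ConfigError,
    DomainError,
    FullModelParams,
    Grid1D,
    ModelParams,
    ModelSpec,
    activation_mask,
    full_complex_rhs,
    lambda_eff,
    model_rhs,
    prod_bravo,
    prod_wox5,
    prod_z,
    qc_indicator,
    vi_indicator,
)
from rootniche.models import species_for


class TestIndicators:
    @pytest.mark.parametrize(
        "x,expected", [(0.0, 1.0), (7.5, 1.0), (-7.5, 1.0), (15.0, 0.0), (-8.0, 0.0)]
    )
    def test_qc_indicator_boundaries_inclusive(self, x, expected):
        assert qc_indicator(x, 15.0) == expected

    @pytest.mark.parametrize(
        "x,expected", [(-7.5, 1.0), (-7.5 - 1e-9, 0.0), (100.0, 1.0), (0.0, 1.0)]
    )
    def test_activation_mask_shootward(self, x, expected):
        assert activation_mask(x, 15.0) == expected

    @pytest.mark.parametrize("x,expected", [(7.5, 0.0), (7.6, 1.0), (22.5, 1.0), (22.6, 0.0)])
    def test_vi_region_half_open(self, x, expected):
        assert vi_indicator(x, 15.0) == expected

    @given(st.floats(-100, 100), st.floats(1.0, 40.0))
    @settings(max_examples=200, deadline=None)
    def test_qc_indicator_is_interval(self, x, L):
        assert qc_indicator(x, L) == float(-L / 2 <= x <= L / 2)

    def test_smoothed_masks_limit(self):
        x = np.linspace(-30, 30, 201)
        sharp = qc_indicator(x, 15.0)
        smooth = qc_indicator(x, 15.0, w=0.01)
        interior = np.abs(np.abs(x) - 7.5) > 0.5
        assert np.allclose(sharp[interior], smooth[interior], atol=1e-8)

    def test_nonpositive_qc_length_rejected(self):
        with pytest.raises(ConfigError):
            qc_indicator(0.0, 0.0)


class TestProductions:
    def test_linear_bravo_production(self):
        p = ModelParams(alpha_L=0.5)
        spec = ModelSpec("sequestration", "linear")
        assert prod_bravo(2.0, 0.0, p, spec) == pytest.approx(1.0)

    def test_hill_half_saturation(self):
        p = ModelParams(alpha=1.0, k_B=0.4, n=2)
        spec = ModelSpec("sequestration", "hill")
        assert prod_bravo(0.4, 0.0, p, spec) == pytest.approx(0.5)

    def test_columella_side_masked(self):
        p = ModelParams()
        for mode in ("linear", "hill"):
            spec = ModelSpec("sequestration", mode)
            assert prod_bravo(3.0, -p.L_QC, p, spec) == 0.0

    def test_basal_vi_only(self):
        p = ModelParams(alpha_0=0.7)
        spec = ModelSpec("sequestration_z", "hill", basal_vi_production=True)
        x = np.array([0.0, 10.0, 22.5, 23.0, -10.0])
        vals = prod_bravo(np.zeros_like(x), x, p, spec)
        assert np.allclose(vals, [0.0, 0.7, 0.7, 0.0, 0.0])

    def test_negative_activator_rejected(self):
        with pytest.raises(DomainError):
            prod_bravo(-0.1, 0.0, ModelParams(), ModelSpec())

    def test_wox5_constant_inside_qc(self):
        p = ModelParams(gamma=2.0)
        spec = ModelSpec("sequestration", "linear")
        assert prod_wox5(5.0, 0.0, p, spec) == pytest.approx(2.0)
        assert prod_wox5(5.0, 2 * p.L_QC, p, spec) == 0.0

    @pytest.mark.parametrize("h", [1.0, 2.0, 4.0])
    def test_self_repression_half_point_any_exponent(self, h):
        p = ModelParams(gamma=2.0, k_W=3.0, h=h)
        spec = ModelSpec("sequestration", "linear", wox5_self_repression=True)
        assert prod_wox5(3.0, 0.0, p, spec) == pytest.approx(1.0)

    def test_self_repression_needs_positive_k_w(self):
        p = ModelParams(k_W=0.0)
        spec = ModelSpec("sequestration", "linear", wox5_self_repression=True)
        with pytest.raises(ConfigError):
            prod_wox5(1.0, 0.0, p, spec)

    def test_z_half_saturation_without_repression(self):
        p = ModelParams(beta=2.0, k_Z=0.5, n=2)
        spec = ModelSpec("sequestration_z", "hill")
        assert prod_z(0.5, 0.0, p, spec) == pytest.approx(1.0)

    def test_c_zero_disables_repression_exactly(self):
        p = ModelParams(c=0.0)
        spec = ModelSpec("mixed", "hill")
        assert prod_z(1.0, 50.0, p, spec) == prod_z(1.0, 0.0, p, spec)

    def test_strong_repression_suppresses(self):
        spec = ModelSpec("repression", "hill")
        vals = [prod_z(1.0, 1.0, ModelParams(c=c), spec) for c in (0.1, 10.0, 1e6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-5


class TestReactionTerms:
    def test_zero_state_is_fixed_point_outside_qc(self, variant_configs):
        for name, (spec, p) in variant_configs.items():
            x = np.array([3 * p.L_QC])
            state = {s: np.zeros(1) for s in species_for(spec)}
            out = model_rhs(state, x, p, spec)
            for s, du in out.items():
                assert np.all(du == 0.0), (name, s)

    def test_sequestration_term_by_term(self):
        p = ModelParams(alpha_L=0.4, d_B=0.2, d_W=0.3, lam=0.5, gamma=1.1)
        spec = ModelSpec("sequestration", "linear")
        out = model_rhs({"B": 1.0, "W": 1.0}, 0.0, p, spec)
        assert out["B"] == pytest.approx(0.4 - 0.2 - 0.5)
        assert out["W"] == pytest.approx(1.1 - 0.3 - 0.5)

    def test_mutant_drops_bravo_equation_and_lambda_term(self):
        p = ModelParams(gamma=1.1, d_W=0.3, lam=5.0)
        spec = ModelSpec("sequestration", "linear", genotype="bravo")
        out = model_rhs({"W": 1.0}, 0.0, p, spec)
        assert set(out) == {"W"}
        assert out["W"] == pytest.approx(1.1 - 0.3)

    def test_mixed_with_c_zero_equals_sequestration_z(self):
        rng = np.random.default_rng(0)
        x = np.linspace(-30, 30, 13)
        state = {s: rng.random(13) for s in ("B", "W", "Z")}
        p = ModelParams(c=0.0)
        mixed = model_rhs(state, x, p, ModelSpec("mixed", "hill"))
        seqz = model_rhs(state, x, p, ModelSpec("sequestration_z", "hill"))
        for s in mixed:
            np.testing.assert_allclose(mixed[s], seqz[s])

    def test_mixed_with_lambda_zero_equals_repression(self):
        rng = np.random.default_rng(1)
        x = np.linspace(-30, 30, 13)
        state = {s: rng.random(13) for s in ("B", "W", "Z")}
        p = ModelParams(lam=0.0)
        mixed = model_rhs(state, x, p, ModelSpec("mixed", "hill"))
        repr_ = model_rhs(state, x, p, ModelSpec("repression", "hill"))
        for s in mixed:
            np.testing.assert_allclose(mixed[s], repr_[s])

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_reactions_never_drive_zero_species_negative(self, seed):
        """Componentwise nonnegativity: every negative term carries a factor
        of its own species, so a zeroed species cannot go negative."""
        rng = np.random.default_rng(seed)
        x = np.linspace(-40, 40, 9)
        for variant in ("sequestration", "sequestration_z", "repression", "mixed", "sequestration_S"):
            spec = ModelSpec(variant, "hill")
            p = ModelParams(alpha_S=0.2)
            species = species_for(spec)
            for zeroed in species:
                state = {s: rng.random(9) * 3 for s in species}
                state[zeroed] = np.zeros(9)
                out = model_rhs(state, x, p, spec)
                assert np.all(out[zeroed] >= 0.0), (variant, zeroed)

    def test_unknown_variant_rejected(self):
        with pytest.raises(ConfigError):
            ModelSpec("osmosis", "linear")


class TestFullComplex:
    def test_lambda_eff_limits(self):
        assert lambda_eff(FullModelParams(k_on=0.3, k_off=0.0, d_C=0.2)) == pytest.approx(0.3)
        assert lambda_eff(FullModelParams(k_on=0.3, k_off=0.5, d_C=0.0)) == pytest.approx(0.0)
        assert lambda_eff(FullModelParams(k_on=0.3, k_off=0.0, d_C=0.0)) == pytest.approx(0.3)
        assert lambda_eff(FullModelParams(k_on=0.4, k_off=0.1, d_C=0.3)) == pytest.approx(0.4 * 0.3 / 0.4)

    def test_mass_action_terms(self):
        p = ModelParams(alpha_L=0.0, gamma=0.0, d_B=0.0, d_W=0.0)
        fp = FullModelParams(k_on=0.2, k_off=0.1, d_C=0.3)
        out = full_complex_rhs({"B": 2.0, "W": 3.0, "C": 1.0}, 0.0, p, fp, ModelSpec("full_complex"))
        bind = 0.2 * 2.0 * 3.0
        assert out["B"] == pytest.approx(-bind + 0.1)
        assert out["W"] == pytest.approx(-bind + 0.1)
        assert out["C"] == pytest.approx(bind - 0.4)

    def test_mutant_has_no_bravo_and_no_binding(self):
        p = ModelParams(gamma=1.0, d_W=0.2)
        fp = FullModelParams(k_on=5.0, k_off=0.0, d_C=0.1)
        out = full_complex_rhs({"W": 2.0, "C": 0.5}, 0.0, p, fp, ModelSpec("full_complex", genotype="bravo"))
        assert "B" not in out
        assert out["W"] == pytest.approx(1.0 - 0.4)


class TestContainers:
    def test_grid_requires_integral_step_count(self):
        with pytest.raises(ConfigError):
            Grid1D(-10.0, 10.0, 0.3)

    def test_grid_defaults(self):
        g = Grid1D.bvp_default()
        assert (g.x_min, g.x_max, g.dx) == (-600.0, 600.0, 0.05)
        assert Grid1D.euler_default().n_nodes == 801

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigError):
            ModelParams(d_B=-1.0)

    def test_hill_exponent_at_least_one(self):
        with pytest.raises(ConfigError):
            ModelParams(n=0.5)

    def test_vi_end_position(self):
        assert ModelParams(L_QC=15.0).x_vi == pytest.approx(22.5)
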