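import numpy as np
import pandas as pd
import pytest
from helpers import breakpoint_scan

from settlehealth.synthetic import (
    DEFAULT_FEATURE_RANGES,
    EffectSpec,
    SyntheticSpec,
    balanced_piecewise,
    effect_mean,
    evaluate_effect,
    generate_feature_panel,
    generate_health_indicators,
    implied_threshold,
)

UR_RANGE = DEFAULT_FEATURE_RANGES["UR"]


class TestEvaluateEffect:
    def test_linear_is_slope_times_x(self):
        e = EffectSpec("UR", "linear", slope_below=2.0)
        assert evaluate_effect(e, 3.0) == 6.0

    def test_piecewise_continuous_at_breakpoint(self):
        e = EffectSpec("UR", "piecewise", slope_below=-1.0, slope_above=1.0,
                       breakpoint=5.0)
        eps = 1e-9
        assert evaluate_effect(e, 5.0) == 0.0
        assert abs(evaluate_effect(e, 5.0 - eps) - evaluate_effect(e, 5.0 + eps)) < 3e-9

    def test_plateau_is_flat_past_start(self):
        e = EffectSpec("UR", "plateau", slope_below=1.0, slope_above=0.5,
                       breakpoint=5.0, plateau_start=10.0)
        assert evaluate_effect(e, 12.0) == evaluate_effect(e, 15.0)

    @pytest.mark.parametrize("effect", [
        EffectSpec("UR", "linear", slope_below=1.3),
        EffectSpec("UR", "piecewise", slope_below=-2.0, slope_above=3.0, breakpoint=50.0),
        EffectSpec("UR", "plateau", slope_below=1.0, slope_above=2.0,
                   breakpoint=40.0, plateau_start=60.0),
    ])
    def test_continuity_everywhere(self, effect):
        xs = np.linspace(20.0, 90.0, 20001)
        g = np.asarray(evaluate_effect(effect, xs))
        jumps = np.abs(np.diff(g))
        # max jump bounded by max |slope| * grid step
        assert jumps.max() < 3.1 * (xs[1] - xs[0]) + 1e-12

    def test_unknown_shape_rejected(self):
        with pytest.raises(ValueError, match="unknown effect shape"):
            EffectSpec("UR", "cubic", slope_below=1.0)

    def test_plateau_needs_start_after_breakpoint(self):
        with pytest.raises(ValueError, match="plateau_start"):
            EffectSpec("UR", "plateau", slope_below=1.0, slope_above=1.0,
                       breakpoint=5.0, plateau_start=4.0)

    def test_nonfinite_input_rejected(self):
        e = EffectSpec("UR", "linear", slope_below=1.0)
        with pytest.raises(ValueError, match="finite"):
            evaluate_effect(e, np.nan)


class TestSpecValidation:
    def test_empty_effects_rejected(self):
        with pytest.raises(ValueError, match="no signal"):
            SyntheticSpec(effects=[])

    def test_effect_on_unknown_feature_rejected(self):
        with pytest.raises(ValueError, match="unknown feature"):
            SyntheticSpec(effects=[EffectSpec("nope", "linear", slope_below=1.0)])

    def test_breakpoint_outside_range_rejected(self):
        bad = EffectSpec("UR", "piecewise", slope_below=1.0, slope_above=2.0,
                         breakpoint=200.0)
        with pytest.raises(ValueError, match="outside its range"):
            SyntheticSpec(effects=[bad])

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            SyntheticSpec(noise_sd=-0.1)


class TestGeneratePanel:
    def test_seed_determinism(self):
        a = generate_feature_panel(SyntheticSpec(seed=7))
        b = generate_feature_panel(SyntheticSpec(seed=7))
        pd.testing.assert_frame_equal(a.panel, b.panel, check_exact=True)
        np.testing.assert_array_equal(a.true_index, b.true_index)

    def test_shape_and_ranges(self):
        spec = SyntheticSpec(n_units=5, n_periods=4, seed=3)
        gen = generate_feature_panel(spec)
        assert len(gen.panel) == 20
        assert gen.panel["province"].nunique() == 5
        for name, (lo, hi) in spec.feature_ranges.items():
            col = gen.panel[name]
            assert col.between(lo, hi).all()

    def test_zero_noise_outcome_equals_latent(self):
        gen = generate_feature_panel(SyntheticSpec(seed=4, noise_sd=0.0))
        np.testing.assert_array_equal(gen.panel["HLI"].to_numpy(), gen.true_index)

    def test_single_effect_latent_is_function_of_feature(self):
        eff = EffectSpec("UR", "piecewise", slope_below=-1e-3, slope_above=4e-3,
                         breakpoint=60.0)
        spec = SyntheticSpec(effects=[eff], noise_sd=0.0, seed=9)
        gen = generate_feature_panel(spec)
        expected = spec.baseline + np.asarray(
            evaluate_effect(eff, gen.panel["UR"].to_numpy()))
        np.testing.assert_allclose(gen.panel["HLI"].to_numpy(), expected, atol=1e-12)

    def test_breakpoint_scan_recovers_planted_kink(self):
        # independent oracle: least-squares scan over candidate breakpoints;
        # a sign-changing kink keeps the breakpoint sharply identifiable
        b_true = 58.0
        eff = EffectSpec("UR", "piecewise", slope_below=-2e-3, slope_above=4e-3,
                         breakpoint=b_true)
        spec = SyntheticSpec(effects=[eff], noise_sd=0.005, seed=21)
        gen = generate_feature_panel(spec)
        x = gen.panel["UR"].to_numpy()
        y = gen.panel["HLI"].to_numpy()
        grid = np.linspace(UR_RANGE[0] + 5, UR_RANGE[1] - 5, 241)
        b_hat = breakpoint_scan(x, y, grid)
        assert abs(b_hat - b_true) <= 2 * (grid[1] - grid[0]) + 0.5

    def test_correlation_knob_induces_dependence(self):
        spec = SyntheticSpec(seed=2, correlation=0.6)
        gen = generate_feature_panel(spec)
        feats = gen.panel[list(spec.feature_ranges)].to_numpy()
        r = np.corrcoef(feats, rowvar=False)
        off = r[np.triu_indices_from(r, k=1)]
        assert off.mean() > 0.3


class TestHealthIndicators:
    def test_monotone_alignment_without_noise(self):
        spec = SyntheticSpec(seed=6, indicator_noise_sd=0.0)
        panel = generate_health_indicators(spec)
        order = np.argsort(panel["latent_index"].to_numpy())
        assert (np.diff(panel["life_expectancy"].to_numpy()[order]) >= 0).all()
        for neg in ("infectious_incidence", "infectious_mortality", "human_mortality"):
            assert (np.diff(panel[neg].to_numpy()[order]) <= 0).all()

    def test_equal_latent_rows_get_equal_indicators(self):
        spec = SyntheticSpec(seed=6, indicator_noise_sd=0.0)
        panel = generate_health_indicators(spec)
        # affine construction: indicator determined by latent alone
        lat = panel["latent_index"].round(12)
        grp = panel.groupby(lat)["life_expectancy"].nunique()
        assert (grp == 1).all()

    def test_determinism(self):
        a = generate_health_indicators(SyntheticSpec(seed=8))
        b = generate_health_indicators(SyntheticSpec(seed=8))
        pd.testing.assert_frame_equal(a, b, check_exact=True)


class TestYamlSpecFiles:
    def test_roundtrip_reproduces_identical_panels(self, tmp_path):
        from settlehealth.synthetic import spec_from_yaml, spec_to_yaml

        spec = SyntheticSpec(n_units=4, n_periods=3, seed=11)
        path = tmp_path / "spec.yaml"
        spec_to_yaml(spec, path)
        loaded = spec_from_yaml(path)
        assert loaded == spec
        pd.testing.assert_frame_equal(
            generate_feature_panel(loaded).panel,
            generate_feature_panel(spec).panel,
            check_exact=True,
        )


class TestThresholdHelpers:
    def test_balanced_piecewise_has_zero_mean_and_threshold_at_breakpoint(self):
        e = balanced_piecewise("UR", 58.0, UR_RANGE, 0.05)
        assert abs(effect_mean(e, *UR_RANGE)) < 1e-6
        assert abs(implied_threshold(e, *UR_RANGE) - 58.0) < 0.02

    def test_implied_threshold_matches_direct_solve_for_hockey(self):
        # flat-then-rising: closed form x* = b + (hi-b)^2 / (2R)
        lo, hi = 0.0, 10.0
        e = EffectSpec("UR", "piecewise", slope_below=0.0, slope_above=1.0,
                       breakpoint=6.0)
        expected = 6.0 + (hi - 6.0) ** 2 / (2 * (hi - lo))
        assert abs(implied_threshold(e, lo, hi) - expected) < 5e-3
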