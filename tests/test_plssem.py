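import math

import numpy as np
import pandas as pd
import pytest

from agonet import (
    PlsModelSpec,
    bootstrap_paths,
    default_model_spec,
    fit_pls,
    quality_gates,
)
from agonet.plssem import r2_band

TWO_BLOCK = PlsModelSpec(
    blocks={"C": ("x",), "D": ("d",)}, paths=(("C", "D"),)
)

FULL_SPEC = PlsModelSpec(
    blocks={"C_IR": ("x1", "x2"), "C_WL": ("y1", "y2"), "D": ("d1", "d2")},
    paths=(("C_IR", "D"), ("C_WL", "D")),
)


def latent_sim(rng, n, g1, g2, lam=0.95, rho=0.0):
    """Two exogenous latents (correlation rho) driving one endogenous latent,
    each measured by two reflective indicators with loading lam."""
    c1 = rng.standard_normal(n)
    c2 = rho * c1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    resid = max(1.0 - g1**2 - g2**2 - 2 * rho * g1 * g2, 0.05)
    d = g1 * c1 + g2 * c2 + math.sqrt(resid) * rng.standard_normal(n)
    d = d / d.std(ddof=1)

    def ind(latent):
        return lam * latent + math.sqrt(1 - lam**2) * rng.standard_normal(n)

    return pd.DataFrame(
        {"x1": ind(c1), "x2": ind(c1), "y1": ind(c2), "y2": ind(c2),
         "d1": ind(d), "d2": ind(d)}
    )


class TestSpecValidation:
    def test_duplicate_indicator_across_latents_rejected(self):
        with pytest.raises(ValueError, match="two latents"):
            PlsModelSpec(blocks={"A": ("x",), "B": ("x",)}, paths=(("A", "B"),))

    def test_cycle_rejected(self):
        with pytest.raises(ValueError, match="acyclic"):
            PlsModelSpec(
                blocks={"A": ("x",), "B": ("y",)},
                paths=(("A", "B"), ("B", "A")),
            )

    def test_unknown_latent_in_path_rejected(self):
        with pytest.raises(ValueError, match="unknown latent"):
            PlsModelSpec(blocks={"A": ("x",)}, paths=(("A", "Z"),))

    def test_default_specs_per_age_group(self):
        piglet = default_model_spec("piglet")
        assert "ir_betweenness" not in piglet.blocks["C_IR"]
        for profile in ("fattener", "gilt"):
            assert "ir_betweenness" in default_model_spec(profile).blocks["C_IR"]


class TestFit:
    def test_single_indicator_blocks_reduce_to_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(200)
        d = 0.6 * x + 0.8 * rng.standard_normal(200)
        fit = fit_pls(pd.DataFrame({"x": x, "d": d}), TWO_BLOCK)
        r = np.corrcoef(x, d)[0, 1]
        assert fit.path_coefficients[("C", "D")] == pytest.approx(r, abs=1e-10)
        assert fit.r_squared["D"] == pytest.approx(r**2, abs=1e-10)
        assert fit.converged

    def test_duplicate_indicator_perfect_block(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        d = 0.5 * x + rng.standard_normal(100)
        frame = pd.DataFrame({"x1": x, "x2": x.copy(), "d": d})
        spec = PlsModelSpec(blocks={"C": ("x1", "x2"), "D": ("d",)},
                            paths=(("C", "D"),))
        fit = fit_pls(frame, spec)
        assert fit.loadings["x1"] == pytest.approx(1.0, abs=1e-10)
        assert fit.loadings["x2"] == pytest.approx(1.0, abs=1e-10)
        assert fit.ave["C"] == pytest.approx(1.0, abs=1e-10)

    def test_latent_scores_unit_variance(self):
        rng = np.random.default_rng(2)
        fit = fit_pls(latent_sim(rng, 300, 0.4, 0.5), FULL_SPEC)
        assert np.allclose(fit.scores.std(ddof=1), 1.0, atol=1e-10)

    def test_missing_rows_dropped(self):
        rng = np.random.default_rng(3)
        frame = latent_sim(rng, 100, 0.4, 0.5)
        frame.loc[:9, "d1"] = np.nan
        fit = fit_pls(frame, FULL_SPEC)
        assert fit.n_obs == 90

    def test_constant_indicator_rejected(self):
        rng = np.random.default_rng(4)
        frame = latent_sim(rng, 50, 0.4, 0.5)
        frame["x1"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            fit_pls(frame, FULL_SPEC)

    def test_too_few_observations_rejected(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="complete cases"):
            fit_pls(latent_sim(rng, 5, 0.4, 0.5), FULL_SPEC)

    def test_parameter_recovery(self):
        """Structural paths recovered with small bias at n = 500."""
        bias1, bias2 = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            fit = fit_pls(latent_sim(rng, 500, 0.4, 0.5), FULL_SPEC)
            bias1.append(fit.path_coefficients[("C_IR", "D")] - 0.4)
            bias2.append(fit.path_coefficients[("C_WL", "D")] - 0.5)
        assert abs(np.mean(bias1)) < 0.05
        assert abs(np.mean(bias2)) < 0.05

    def test_collinear_exogenous_latents_path_beyond_one(self):
        """Suppression under collinearity: a standardized path may exceed 1
        in magnitude and must not be clamped."""
        rng = np.random.default_rng(7)
        n = 500
        c1 = rng.standard_normal(n)
        c2 = 0.9 * c1 + math.sqrt(1 - 0.81) * rng.standard_normal(n)
        d = 2.0 * c1 - 1.5 * c2 + 0.3 * rng.standard_normal(n)
        lam = 0.97

        def ind(latent):
            return lam * latent + math.sqrt(1 - lam**2) * rng.standard_normal(n)

        frame = pd.DataFrame(
            {"x1": ind(c1), "x2": ind(c1), "y1": ind(c2), "y2": ind(c2),
             "d1": ind(d), "d2": ind(d)}
        )
        fit = fit_pls(frame, FULL_SPEC)
        paths = list(fit.path_coefficients.values())
        assert max(abs(p) for p in paths) > 1.0
        assert min(paths) < 0 < max(paths)


class TestBootstrap:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(8)
        frame = latent_sim(rng, 120, 0.4, 0.5)
        a = bootstrap_paths(frame, FULL_SPEC, n_boot=500, seed=3)
        b = bootstrap_paths(frame, FULL_SPEC, n_boot=500, seed=3)
        pd.testing.assert_frame_equal(a.replicates, b.replicates)
        assert a.p_values == b.p_values

    def test_minimum_replicates_enforced(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            bootstrap_paths(latent_sim(rng, 100, 0.4, 0.5), FULL_SPEC, n_boot=100)

    def test_strong_signal_significant(self):
        rng = np.random.default_rng(10)
        frame = latent_sim(rng, 300, 0.5, 0.6)
        boot = bootstrap_paths(frame, FULL_SPEC, n_boot=500, seed=0)
        assert all(p < 0.05 for p in boot.p_values.values())
        assert boot.n_failed == 0

    def test_null_signal_not_significant(self):
        over = 0
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            frame = latent_sim(rng, 200, 0.0, 0.0)
            boot = bootstrap_paths(frame, FULL_SPEC, n_boot=500, seed=seed)
            over += all(p > 0.05 for p in boot.p_values.values())
        assert over >= 2


class TestQuality:
    @pytest.mark.parametrize(
        "r2,band",
        [(0.8, "substantial"), (0.61, "moderate"), (0.3, "weak"),
         (0.1, "below weak")],
    )
    def test_r2_bands(self, r2, band):
        assert r2_band(r2) == band

    def test_gates_consistent_with_fit(self):
        rng = np.random.default_rng(11)
        fit = fit_pls(latent_sim(rng, 400, 0.4, 0.5), FULL_SPEC)
        report = quality_gates(fit).set_index(["criterion", "target"])
        for ind, rel in fit.indicator_reliability.items():
            row = report.loc[("indicator_reliability", ind)]
            assert row["value"] == pytest.approx(rel)
            assert row["passed"] == (rel > 0.7)
        for latent, cr in fit.composite_reliability.items():
            row = report.loc[("composite_reliability", latent)]
            assert row["passed"] == (0.6 <= cr <= 0.9)
        for latent, ave in fit.ave.items():
            assert report.loc[("ave", latent), "passed"] == (ave > 0.5)
        assert report.loc[("r_squared", "D"), "note"] in (
            "weak", "moderate", "substantial", "below weak"
        )

    def test_low_noise_fit_passes_reliability_gates(self):
        rng = np.random.default_rng(12)
        fit = fit_pls(latent_sim(rng, 400, 0.5, 0.6, lam=0.95), FULL_SPEC)
        report = quality_gates(fit)
        rel = report[report["criterion"] == "indicator_reliability"]
        assert rel["passed"].all()
        ave = report[report["criterion"] == "ave"]
        assert ave["passed"].all()
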