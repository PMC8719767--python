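"""Burden-model contracts: exact oracles, library cross-checks, recovery."""

import numpy as np
import pandas as pd
import pytest

import lingcod_burden as lb
from lingcod_burden.burden import build_burden_model


def _plain_hosts(n, sex="male", color="brown", length=50.0):
    return [
        lb.HostRecord(f"F{i}", "R1", "S1", 10.0, sex, color, length, 1.0, 0.03)
        for i in range(n)
    ]


def _one_taxon_counts(values):
    return lb.ParasiteCountTable(
        pd.DataFrame(
            {"fish_id": [f"F{i}" for i in range(len(values))],
             "taxon_id": "T1", "count": values}
        )
    )


NO_RE = lb.ModelDesign(
    include_depth=False, include_sex_color=False, nested_terms=(),
    taxon_structure="none", use_offset=False,
)


class TestWaldZ:
    @pytest.mark.parametrize(
        "estimate, se, expected",
        [
            (0.94182, 0.17238, 5.464),
            (-0.71694, 0.17404, -4.119),
            (-0.11982, 0.05441, -2.202),
            (0, 0.5, 0.0),
        ],
    )
    def test_values(self, estimate, se, expected):
        assert lb.wald_z(estimate, se) == pytest.approx(expected, abs=5e-4)

    def test_nonpositive_se(self):
        with pytest.raises(ValueError):
            lb.wald_z(1.0, 0.0)


class TestBlueToBrownRatio:
    def test_printed_coefficients_give_189(self):
        coefs = {"color[brown]": 0.07987, "sex[male]*color[brown]": -0.71694}
        assert round(lb.blue_to_brown_ratio(coefs, "male"), 2) == 1.89

    def test_null_coefficients_give_unity(self):
        coefs = {"color[brown]": 0.0, "sex[male]*color[brown]": 0.0}
        assert lb.blue_to_brown_ratio(coefs, "male") == pytest.approx(1.0)
        assert lb.blue_to_brown_ratio(coefs, "female") == pytest.approx(1.0)

    def test_log2_color_effect_halves_burden(self):
        coefs = {"color[brown]": np.log(2), "sex[male]*color[brown]": 0.0}
        assert lb.blue_to_brown_ratio(coefs, "male") == pytest.approx(0.5)

    def test_missing_term_is_specification_error(self):
        with pytest.raises(KeyError):
            lb.blue_to_brown_ratio({"color[brown]": 0.1}, "male")


class TestDegenerateFits:
    def test_intercept_only_mle_is_log_mean(self):
        fit = lb.fit_burden_model(_plain_hosts(3), _one_taxon_counts([2, 4, 6]), NO_RE)
        assert fit.fixed_effects["estimate"].iloc[0] == pytest.approx(np.log(4), abs=1e-4)

    def test_wald_z_self_consistency(self, small_dataset):
        fit = lb.fit_burden_model(
            small_dataset.hosts, small_dataset.counts,
            lb.ModelDesign(taxon_structure="reduced"),
        )
        fe = fit.fixed_effects
        np.testing.assert_allclose(fe["z"], fe["estimate"] / fe["se"], rtol=1e-10)


class TestAgainstStatsmodels:
    def test_no_re_matches_negative_binomial(self, small_dataset):
        import statsmodels.api as sm

        design = lb.ModelDesign(nested_terms=(), taxon_structure="none")
        fit = lb.fit_burden_model(
            small_dataset.hosts, small_dataset.counts, design,
            lb.FitOptions(outer_tol=1e-10, max_outer_iter=500),
        )
        model, _, _, _ = build_burden_model(small_dataset.hosts, small_dataset.counts, design)
        ref = sm.NegativeBinomial(model.y, model.X, offset=model.offset).fit(
            disp=0, maxiter=500, gtol=1e-10
        )
        np.testing.assert_allclose(
            fit.fixed_effects["estimate"], ref.params[:-1], atol=5e-3
        )
        assert fit.theta == pytest.approx(1 / ref.params[-1], rel=0.02)

    def test_theta_infinity_matches_poisson_glm(self, small_dataset):
        import statsmodels.api as sm

        design = lb.ModelDesign(nested_terms=(), taxon_structure="none")
        fit = lb.fit_burden_model(
            small_dataset.hosts, small_dataset.counts, design,
            lb.FitOptions(fix_theta=1e8, outer_tol=1e-10, max_outer_iter=500),
        )
        model, _, _, _ = build_burden_model(small_dataset.hosts, small_dataset.counts, design)
        ref = sm.GLM(model.y, model.X, family=sm.families.Poisson(), offset=model.offset).fit()
        np.testing.assert_allclose(fit.fixed_effects["estimate"], ref.params, atol=1e-4)


class TestOffsetContract:
    def test_shifting_offset_shifts_only_intercept(self, small_dataset):
        """Adding c to the log-length offset moves the intercept by -c."""
        design = lb.ModelDesign(nested_terms=(), taxon_structure="none")
        opts = lb.FitOptions(outer_tol=1e-10, max_outer_iter=500)
        base = lb.fit_burden_model(small_dataset.hosts, small_dataset.counts, design, opts)

        scaled_hosts = []
        for h in small_dataset.hosts:
            import copy

            h2 = copy.copy(h)
            h2.total_length_cm = h.total_length_cm * np.e  # offset shift c = 1
            scaled_hosts.append(h2)
        shifted = lb.fit_burden_model(scaled_hosts, small_dataset.counts, design, opts)

        b0, b0s = base.fixed_effects["estimate"].iloc[0], shifted.fixed_effects["estimate"].iloc[0]
        assert b0s == pytest.approx(b0 - 1.0, abs=2e-3)
        np.testing.assert_allclose(
            base.fixed_effects["estimate"].iloc[1:],
            shifted.fixed_effects["estimate"].iloc[1:],
            atol=2e-3,
        )


class TestTaxonEffects:
    @pytest.fixture(scope="class")
    def strong_signal_fit(self):
        cov = np.diag([0.4**2, 0.0, 0.0, 0.5**2])
        cfg = lb.GeneratorConfig(
            n_regions=2, sites_per_region=2, fish_per_site=125, n_fish=500, n_taxa=8,
            cell_probabilities=(0.35, 0.15, 0.3, 0.2),
            sd_region=0.0, sd_site=0.0, sd_fish=0.0, taxon_cov=cov,
            theta=3.0, seed=31,
        )
        ds = lb.generate_dataset(cfg)
        fit = lb.fit_burden_model(
            ds.hosts, ds.counts,
            lb.ModelDesign(nested_terms=(), taxon_structure="reduced"),
        )
        return ds, fit

    def test_one_record_per_taxon(self, strong_signal_fit):
        ds, fit = strong_signal_fit
        slopes = lb.extract_taxon_effects(fit)
        assert len(slopes) == 8
        assert set(slopes["taxon_id"]) == set(ds.counts.taxon_ids)
        assert (slopes["cond_sd"] > 0).all()
        # ordered output for the caterpillar plot
        assert slopes["total_slope"].is_monotonic_increasing

    def test_modes_track_realized_deviations(self, strong_signal_fit):
        """Conditional modes correlate with the realized taxon deviations."""
        ds, fit = strong_signal_fit
        slopes = lb.extract_taxon_effects(fit).set_index("taxon_id")
        truth = ds.truth["taxon_effects"]["sex[male]*color[brown]"]
        r = np.corrcoef(slopes.loc[truth.index, "deviation"], truth)[0, 1]
        assert r > 0.5

    def test_zero_taxon_covariance_zeroes_deviations(self):
        """Data with no taxon heterogeneity: deviations shrink to ~0."""
        cfg = lb.GeneratorConfig(
            n_regions=1, sites_per_region=1, fish_per_site=150, n_fish=150, n_taxa=4,
            cell_probabilities=(0.35, 0.15, 0.3, 0.2),
            sd_region=0.0, sd_site=0.0, sd_fish=0.0, taxon_cov=np.zeros((4, 4)),
            theta=5.0, seed=13,
        )
        ds = lb.generate_dataset(cfg)
        fit = lb.fit_burden_model(
            ds.hosts, ds.counts,
            lb.ModelDesign(nested_terms=(), taxon_structure="reduced"),
        )
        slopes = lb.extract_taxon_effects(fit)
        assert np.max(np.abs(slopes["deviation"])) < 0.05

    def test_no_taxon_term_raises(self, small_dataset):
        fit = lb.fit_burden_model(
            small_dataset.hosts, small_dataset.counts,
            lb.ModelDesign(nested_terms=(), taxon_structure="none"),
        )
        with pytest.raises(ValueError):
            lb.extract_taxon_effects(fit)


class TestNullCalibration:
    def test_wald_type_i_error_near_nominal(self):
        """Under beta_interaction = 0 the two-sided Wald test at alpha=.05
        rejects in 2-9% of 200 simulated fits."""
        design = lb.ModelDesign(nested_terms=(), taxon_structure="none")
        rejections = 0
        for sim in range(200):
            cfg = lb.GeneratorConfig(
                n_regions=1, sites_per_region=2, fish_per_site=50, n_fish=100, n_taxa=3,
                cell_probabilities=(0.35, 0.15, 0.3, 0.2),
                beta_interaction=0.0,
                sd_region=0.0, sd_site=0.0, sd_fish=0.0, taxon_cov=np.zeros((4, 4)),
                theta=2.0, seed=40_000 + sim,
            )
            ds = lb.generate_dataset(cfg)
            fit = lb.fit_burden_model(ds.hosts, ds.counts, design)
            p = float(
                fit.fixed_effects.set_index("term").loc["sex[male]*color[brown]", "p"]
            )
            rejections += p < 0.05
        assert 0.02 * 200 <= rejections <= 0.09 * 200


def test_requires_complete_grid(small_dataset):
    broken = small_dataset.counts.frame.iloc[:-1]
    with pytest.raises(ValueError, match="every .fish, taxon. pair"):
        lb.fit_burden_model(small_dataset.hosts, broken)


def test_vif_reported_and_never_aborts(small_dataset):
    # unbalanced cells can push VIF above 5; the fit must warn, not abort
    import warnings

    design = lb.ModelDesign(taxon_structure="reduced")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = lb.fit_burden_model(small_dataset.hosts, small_dataset.counts, design)
    assert fit.vif is not None and len(fit.vif) == 4
    assert (fit.vif > 0).all()
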