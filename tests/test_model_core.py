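"""Spline bases, penalized IRLS, REML selection, prediction, AIC selection."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.stats import spearmanr

import kidlb.synthetic_data as sd
from kidlb import (
    ConfigError,
    ContractError,
    DataError,
    DegenerateCovariateError,
    GeneratorConfig,
    TrueEffects,
    generate_cohort,
)
from kidlb.model_core import (
    CC2_CATEGORICAL,
    ModelSpec,
    SmoothTerm,
    aic_forward_selection,
    build_spline_basis,
    fit_penalized_additive_logistic,
    predict_probability,
    prepare_model_frame,
    select_smoothing_reml,
)


class TestSplineBasis:
    def test_partition_of_unity_in_range(self):
        rng = np.random.default_rng(0)
        x = rng.random(200)
        blk = build_spline_basis(x, n_basis=10, degree=3)
        B = blk.evaluate(x)
        assert B.shape == (200, 10)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_second_order_penalty_annihilates_linear_coefficients(self):
        x = np.linspace(0, 1, 50)
        blk = build_spline_basis(x, n_basis=8, degree=3, penalty_order=2)
        k = np.arange(8, dtype=float)
        for coefs in (np.ones(8), 2.0 + 3.0 * k):
            assert coefs @ blk.penalty_matrix @ coefs == pytest.approx(0.0, abs=1e-20)

    def test_penalty_quadform_equals_sum_of_squared_differences(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=100)
        blk = build_spline_basis(x, n_basis=8, degree=3, penalty_order=2)
        for _ in range(5):
            c = rng.normal(size=8)
            brute = float(np.sum(np.diff(c, n=2) ** 2))
            assert c @ blk.penalty_matrix @ c == pytest.approx(brute, rel=1e-12)

    def test_linear_extrapolation_beyond_training_range(self):
        x = np.linspace(10, 20, 100)
        blk = build_spline_basis(x, n_basis=10, degree=3)
        coefs = np.random.default_rng(1).normal(size=10)
        f = lambda q: blk.evaluate(np.atleast_1d(q)) @ coefs
        slope_out = (f(21.5) - f(20.5)) / 1.0
        slope_at_edge = (f(20.0) - f(19.999)) / 0.001
        assert slope_out == pytest.approx(slope_at_edge, rel=1e-2)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DegenerateCovariateError):
            build_spline_basis(np.full(10, 3.0))
        with pytest.raises(ConfigError):
            build_spline_basis(np.linspace(0, 1, 10), n_basis=3, degree=3)


class TestPenalizedFit:
    def test_unpenalized_linear_fit_matches_newton_logistic(self, set_cohort):
        cycles, embryos = set_cohort
        spec = ModelSpec(
            linear_terms=("multinucleated", "fragmentation_pct"),
            random_intercept=None,
        )
        m = fit_penalized_additive_logistic(spec, cycles, embryos, "fixed")
        frame = prepare_model_frame(cycles, embryos)
        X = sm.add_constant(
            frame[["multinucleated", "fragmentation_pct"]].to_numpy(dtype=float)
        )
        ref = sm.Logit(frame["live_birth"].to_numpy(dtype=float), X).fit(disp=0)
        assert np.max(np.abs(m.coefficients - ref.params)) < 1e-6
        assert m.converged

    def test_infinite_penalty_gives_straight_line_smooth(self, set_cohort):
        cycles, embryos = set_cohort
        spec = ModelSpec(smooth_terms=(SmoothTerm("t2"),), random_intercept=None)
        m = fit_penalized_additive_logistic(
            spec, cycles, embryos, "fixed", lambdas={"t2": 1e9}
        )
        grid = np.linspace(
            m.blocks["t2"][0].lo, m.blocks["t2"][0].hi, 60
        )
        f = m.smooth_values("t2", grid)
        slope, intercept = np.polyfit(grid, f, 1)
        assert np.max(np.abs(f - (slope * grid + intercept))) < 1e-4
        assert m.edf["t2"] == pytest.approx(2.0, abs=0.05)

    def test_penalized_deviance_never_increases_across_irls_steps(self, set_cohort):
        cycles, embryos = set_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.base_model(), cycles, embryos, "fixed"
        )
        trace = np.asarray(m.fit_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_aic_identity_holds_exactly(self, set_cohort):
        cycles, embryos = set_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.base_model(), cycles, embryos, "fixed"
        )
        assert m.aic == pytest.approx(m.deviance + 2.0 * m.edf_total, abs=1e-10)
        for name, sl in m.slices.items():
            lo = 2.0 if name in m.lambdas else 0.0
            assert m.edf[name] >= lo - 1e-8
            if name in m.lambdas:
                assert m.edf[name] <= m.blocks[name][0].n_basis + 1e-8

    def test_multinucleation_effect_recovered_on_large_cohort(self):
        """Planted -0.5 multinucleation log-odds recovered within 0.15."""
        eff = TrueEffects(beta_mn=-0.5)
        cfg = GeneratorConfig(
            n_cycles=4000, set_fraction=1.0, seed=44, true_effects=eff
        )
        cycles, embryos = generate_cohort(cfg)
        m = fit_penalized_additive_logistic(
            ModelSpec.age_model(), cycles, embryos, "reml"
        )
        beta_mn = m.coefficients[m.slices["multinucleated"]][0]
        assert beta_mn == pytest.approx(-0.5, abs=0.15)

    def test_single_class_outcome_rejected(self):
        cfg = GeneratorConfig(n_cycles=30, set_fraction=1.0, seed=1)
        cycles, embryos = generate_cohort(cfg)
        for e in embryos:
            e.live_birth = 0
        with pytest.raises(DataError, match="outcome"):
            fit_penalized_additive_logistic(
                ModelSpec.base_model(), cycles, embryos, "fixed"
            )

    def test_complete_separation_flagged_not_raised(self):
        rng = np.random.default_rng(2)
        cfg = GeneratorConfig(n_cycles=60, set_fraction=1.0, seed=2)
        cycles, embryos = generate_cohort(cfg)
        for e in embryos:
            e.live_birth = int(rng.random() < 0.4)
            e.fragmentation_pct = float(e.live_birth * 40.0)
        spec = ModelSpec(linear_terms=("fragmentation_pct",), random_intercept=None)
        m = fit_penalized_additive_logistic(spec, cycles, embryos, "fixed")
        assert m.separation_suspected


class TestRemlSelection:
    def test_linear_truth_drives_smooth_edf_to_two(self):
        eff = TrueEffects(
            f_age=lambda a: np.zeros_like(np.asarray(a, dtype=float)),
            f_t2=lambda t: -0.15 * (np.asarray(t, dtype=float) - 26.0),
            intercept=-1.4,
        )
        cfg = GeneratorConfig(
            n_cycles=3000, set_fraction=1.0, seed=13,
            random_intercept_sd=0.0, true_effects=eff,
        )
        cycles, embryos = generate_cohort(cfg)
        spec = ModelSpec(smooth_terms=(SmoothTerm("t2"),), random_intercept="cycle_id")
        m = fit_penalized_additive_logistic(spec, cycles, embryos, "reml")
        assert m.edf["t2"] == pytest.approx(2.0, abs=0.5)

    def test_null_random_intercept_variance_shrinks_to_zero(self):
        cfg = GeneratorConfig(
            n_cycles=3000, set_fraction=1.0, seed=11, random_intercept_sd=0.0
        )
        cycles, embryos = generate_cohort(cfg)
        _, sigma_u = select_smoothing_reml(ModelSpec.base_model(), cycles, embryos)
        assert sigma_u < 0.1

    def test_selection_is_deterministic(self, small_cohort):
        cycles, embryos = small_cohort
        a = select_smoothing_reml(ModelSpec.base_model(), cycles, embryos)
        b = select_smoothing_reml(ModelSpec.base_model(), cycles, embryos)
        assert a == b


class TestPrediction:
    def test_zero_coefficients_score_one_half(self, small_cohort):
        cycles, embryos = small_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.base_model(), cycles, embryos, "fixed"
        )
        m.coefficients = np.zeros_like(m.coefficients)
        scores = predict_probability(m, cycles, embryos)
        np.testing.assert_allclose(scores, 0.5)

    def test_score_increases_with_positively_weighted_covariate(self, small_cohort):
        cycles, embryos = small_cohort
        spec = ModelSpec(linear_terms=("fragmentation_pct",), random_intercept=None)
        m = fit_penalized_additive_logistic(spec, cycles, embryos, "fixed")
        m.coefficients = np.array([0.0, 0.8])
        frame = prepare_model_frame(cycles, embryos).head(10).copy()
        s_lo = m.predict_frame(frame)
        frame["fragmentation_pct"] += 5.0
        s_hi = m.predict_frame(frame)
        assert (s_hi > s_lo).all()

    def test_scoring_invariant_to_row_order(self, small_cohort):
        cycles, embryos = small_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.age_model(), cycles, embryos, "fixed"
        )
        frame = prepare_model_frame(cycles, embryos)
        perm = np.random.default_rng(0).permutation(len(frame))
        # identical design rows; tolerance covers BLAS summation-order ulps
        np.testing.assert_allclose(
            m.predict_frame(frame)[perm],
            m.predict_frame(frame.iloc[perm]),
            rtol=0, atol=1e-12,
        )

    def test_fitted_random_effects_require_known_cycles(self, small_cohort):
        cycles, embryos = small_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.base_model(), cycles, embryos, "fixed"
        )
        frame = prepare_model_frame(cycles, embryos).copy()
        s0 = m.predict_frame(frame, use_random_effect="fitted")
        assert s0.shape == (len(frame),)
        frame.loc[:, "cycle_id"] = "unknown-cycle"
        with pytest.raises(ContractError):
            m.predict_frame(frame, use_random_effect="fitted")

    def test_unseen_categorical_level_rejected(self, small_cohort):
        cycles, embryos = small_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.base_model(), cycles, embryos, "fixed"
        )
        frame = prepare_model_frame(cycles, embryos)
        frame.loc[frame.index[0], "cc2_category"] = "weird"
        with pytest.raises(DataError, match="weird"):
            m.predict_frame(frame)

    def test_serialization_round_trip_preserves_predictions(
        self, small_cohort, tmp_path
    ):
        cycles, embryos = small_cohort
        m = fit_penalized_additive_logistic(
            ModelSpec.age_model(), cycles, embryos, "fixed"
        )
        path = tmp_path / "model.json"
        m.save(path)
        from kidlb.model_core import FittedAdditiveModel

        m2 = FittedAdditiveModel.load(path)
        np.testing.assert_allclose(
            predict_probability(m, cycles, embryos),
            predict_probability(m2, cycles, embryos),
            atol=1e-12,
        )
        assert m2.train_fingerprint == m.train_fingerprint

    def test_cross_implementation_agreement_with_reference_gam(self):
        """Scores agree with statsmodels GLMGam on the covariate bulk.

        Both implementations estimate the same penalized B-spline logistic
        fit; boundary regions are excluded because the two packages use
        different basis/penalty boundary conventions (documented tolerance
        0.02 on the probability scale).
        """
        from statsmodels.gam.api import BSplines, GLMGam

        cfg = GeneratorConfig(
            n_cycles=1500, set_fraction=1.0, random_intercept_sd=0.0, seed=9
        )
        cycles, embryos = generate_cohort(cfg)
        frame = prepare_model_frame(cycles, embryos)
        y = frame["live_birth"].to_numpy(dtype=float)
        spec = ModelSpec(smooth_terms=(SmoothTerm("t2"),), random_intercept=None)
        m = fit_penalized_additive_logistic(spec, cycles, embryos, "reml")
        mine = m.predict_frame(frame)
        bs = BSplines(frame[["t2"]], df=[10], degree=[3])
        ref = GLMGam(
            y, np.ones((len(y), 1)), smoother=bs,
            family=sm.families.Binomial(), alpha=10.0,
        ).fit()
        theirs = ref.predict()
        t2 = frame["t2"].to_numpy()
        lo, hi = np.quantile(t2, [0.05, 0.95])
        bulk = (t2 >= lo) & (t2 <= hi)
        fixture = np.flatnonzero(bulk)[:50]  # 50-embryo evaluation fixture
        assert np.max(np.abs(mine[fixture] - theirs[fixture])) < 0.02


class TestForwardSelection:
    def test_duplicate_candidate_rejected(self, small_cohort):
        cycles, embryos = small_cohort
        with pytest.raises(ContractError, match="duplicates"):
            aic_forward_selection(
                ["multinucleated"], ModelSpec.base_model(), cycles, embryos
            )

    def test_empty_candidates_return_base(self, small_cohort):
        cycles, embryos = small_cohort
        base = ModelSpec.base_model()
        res = aic_forward_selection([], base, cycles, embryos, "fixed")
        assert res.spec == base and res.steps == []

    def test_true_effects_selected_null_fragmentation_excluded(self):
        cfg = GeneratorConfig(n_cycles=900, set_fraction=1.0, seed=30)
        cycles, embryos = generate_cohort(cfg)
        base = ModelSpec(random_intercept="cycle_id")
        res = aic_forward_selection(
            [SmoothTerm("t2"), CC2_CATEGORICAL, "multinucleated",
             "fragmentation_pct"],
            base, cycles, embryos, lambda_mode="fixed",
        )
        assert "t2" in res.spec.term_names
        assert "multinucleated" in res.spec.term_names
        assert "fragmentation_pct" not in res.spec.term_names

    def test_null_candidate_rarely_selected(self):
        """A zero-effect covariate joins the model in well under half of
        seeded replicates (AIC's ~16% false-inclusion rate for 1 dof)."""
        picked = 0
        n_rep = 50
        for s in range(n_rep):
            cfg = GeneratorConfig(n_cycles=300, set_fraction=1.0, seed=600 + s)
            cycles, embryos = generate_cohort(cfg)
            base = ModelSpec(
                linear_terms=("multinucleated",), random_intercept=None
            )
            res = aic_forward_selection(
                ["fragmentation_pct"], base, cycles, embryos, "fixed"
            )
            picked += "fragmentation_pct" in res.spec.term_names
        assert picked <= 0.25 * n_rep


def test_age_smooth_shape_recovery_single_replicate():
    cfg = GeneratorConfig(n_cycles=2000, set_fraction=1.0, seed=101)
    cycles, embryos = generate_cohort(cfg)
    m = fit_penalized_additive_logistic(
        ModelSpec.age_model(), cycles, embryos, "reml"
    )
    grid = np.linspace(25.5, 41.5, 50)
    rho = spearmanr(m.smooth_values("maternal_age", grid), sd.default_f_age(grid))
    assert rho.statistic >= 0.9
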