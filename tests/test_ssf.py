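import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rayssf.landscape import Landscape
from rayssf.ssf import (
    ChoiceSet,
    NonIdentifiableError,
    SelectionModel,
    build_choice_sets,
    compare_fits,
    conditional_loglik,
    fit_ssf,
    null_loglik,
    profile_ci,
)


def make_set(used_w, avail_w, stratum_id=0):
    used_w = np.atleast_1d(np.asarray(used_w, dtype=float))
    avail_w = np.atleast_2d(np.asarray(avail_w, dtype=float))
    return ChoiceSet(
        stratum_id=stratum_id,
        used_xy=np.zeros(2),
        used_w=used_w,
        avail_xy=np.zeros((len(avail_w), 2)),
        avail_w=avail_w,
        dt=3.0,
        delta_bar=1.0,
        sigma2=6.0,
    )


def random_sets(rng, n_strata=30, M=10, p=2):
    return [
        make_set(rng.standard_normal(p), rng.standard_normal((M, p)), i)
        for i in range(n_strata)
    ]


class TestConditionalLoglik:
    @pytest.mark.parametrize("form", ["exponential", "ede_residence"])
    def test_zero_beta_gives_uniform_softmax(self, rng, form):
        sets = random_sets(rng, n_strata=20, M=15)
        model = SelectionModel(form=form, beta=np.zeros(2))
        assert conditional_loglik(sets, model) == pytest.approx(
            -20 * np.log(16), rel=1e-12
        )

    def test_single_stratum_enumeration_oracle(self):
        # used w=1 vs two available w=0 at β=1: log(e / (e + 2))
        sets = [make_set([1.0], [[0.0], [0.0]])]
        model = SelectionModel(form="exponential", beta=[1.0])
        assert conditional_loglik(sets, model) == pytest.approx(
            np.log(np.e / (np.e + 2.0)), rel=1e-12
        )

    def test_ede_constant_covariates_cancel(self, rng):
        sets = [make_set([0.7, -0.3], np.tile([0.7, -0.3], (9, 1)))]
        for beta in ([0.0, 0.0], [2.0, -1.0], [-5.0, 3.0]):
            model = SelectionModel(form="ede_residence", beta=beta)
            assert conditional_loglik(sets, model) == pytest.approx(-np.log(10))

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(
        beta=st.tuples(st.floats(-3, 3), st.floats(-3, 3)),
        shift=st.floats(-50, 50),
    )
    def test_stratum_constant_shifts_cancel(self, beta, shift):
        """For the exponential form, adding a constant to every covariate
        row of a stratum shifts all η_j equally, so the conditional
        likelihood is unchanged — intercepts are not estimable."""
        rng = np.random.default_rng(4)
        sets = random_sets(rng, n_strata=5, M=6)
        model = SelectionModel(form="exponential", beta=beta)
        base = conditional_loglik(sets, model)
        shifted = [
            make_set(cs.used_w + shift, cs.avail_w + shift, cs.stratum_id)
            for cs in sets
        ]
        assert conditional_loglik(shifted, model) == pytest.approx(
            base, rel=1e-9, abs=1e-9
        )

    def test_extreme_beta_is_finite(self, rng):
        # log-sum-exp guard: no overflow at large linear predictors
        sets = random_sets(rng, n_strata=5, M=6)
        model = SelectionModel(form="exponential", beta=[200.0, -150.0])
        assert np.isfinite(conditional_loglik(sets, model))

    def test_nan_covariates_rejected(self, rng):
        sets = random_sets(rng, n_strata=3, M=4)
        sets[1].avail_w[2, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            conditional_loglik(sets, SelectionModel(form="exponential", beta=[0, 0]))


class TestFit:
    def test_flat_likelihood_raises_nonidentifiable(self):
        sets = [make_set([1.0, 2.0], np.tile([1.0, 2.0], (5, 1)), i) for i in range(4)]
        with pytest.raises(NonIdentifiableError):
            fit_ssf(sets)

    @pytest.mark.parametrize("form", ["exponential", "ede_residence"])
    def test_maximized_loglik_dominates_null(self, rng, form):
        sets = random_sets(rng, n_strata=40, M=8)
        fit = fit_ssf(sets, form=form)
        assert fit.loglik >= fit.null_loglik
        assert fit.null_loglik == pytest.approx(null_loglik(sets))

    def test_fit_recovers_planted_signal_direction(self, sim_choice_sets):
        fit = fit_ssf(sim_choice_sets, form="exponential")
        assert fit.beta[0] > 0  # simulated with β = (1, −0.5)
        assert fit.converged

    def test_covariance_symmetric_positive_definite(self, sim_choice_sets):
        fit = fit_ssf(sim_choice_sets)
        np.testing.assert_allclose(fit.cov, fit.cov.T, atol=1e-12)
        assert np.all(np.linalg.eigvalsh(fit.cov) > 0)

    def test_wald_ci_has_requested_level_shape(self, sim_choice_sets):
        fit90 = fit_ssf(sim_choice_sets, ci_level=0.90)
        fit99 = fit_ssf(sim_choice_sets, ci_level=0.99)
        assert np.all(fit99.ci_width > fit90.ci_width)
        np.testing.assert_allclose(
            (fit90.ci_upper + fit90.ci_lower) / 2, fit90.beta, atol=1e-10
        )

    def test_profile_ci_close_to_wald_on_regular_problem(self, sim_choice_sets):
        fit = fit_ssf(sim_choice_sets)
        lo, hi = profile_ci(sim_choice_sets, fit, index=0)
        assert lo == pytest.approx(fit.ci_lower[0], abs=0.15 * fit.se[0])
        assert hi == pytest.approx(fit.ci_upper[0], abs=0.15 * fit.se[0])

    def test_matches_reference_conditional_logit(self, rng):
        """Independent cross-check: statsmodels ConditionalLogit on the
        long-format data agrees to 4 significant figures."""
        statsmodels = pytest.importorskip("statsmodels.api")
        from statsmodels.discrete.conditional_models import ConditionalLogit

        sets = random_sets(rng, n_strata=60, M=12)
        # plant signal so the optimum is away from zero
        for cs in sets:
            cs.used_w += [0.8, -0.4]
        fit = fit_ssf(sets, form="exponential")

        y, X, groups = [], [], []
        for cs in sets:
            y += [1] + [0] * cs.n_avail
            X.append(np.vstack([cs.used_w, cs.avail_w]))
            groups += [cs.stratum_id] * (cs.n_avail + 1)
        ref = ConditionalLogit(np.array(y), np.vstack(X), groups=np.array(groups))
        ref_beta = ref.fit(disp=False).params
        np.testing.assert_allclose(fit.beta, ref_beta, rtol=1e-4)


class TestBuildChoiceSets:
    def test_count_contract_one_stratum_per_step(self, small_landscape, sim_track):
        from rayssf.motility import estimate_motility
        from rayssf.tracks import derive_steps

        steps = derive_steps(sim_track)
        mot = estimate_motility(steps, window_hours=np.inf)
        sets = build_choice_sets(
            steps, mot, small_landscape, M=20, rng=np.random.default_rng(1)
        )
        assert len(sets) + sets.n_strata_dropped == len(steps)
        assert all(cs.n_avail == 20 for cs in sets.sets)

    def test_same_seed_reproduces_choice_sets(self, small_landscape, sim_track):
        from rayssf.motility import estimate_motility
        from rayssf.tracks import derive_steps

        steps = derive_steps(sim_track)
        mot = estimate_motility(steps, window_hours=np.inf)
        a = build_choice_sets(steps, mot, small_landscape, M=5,
                              rng=np.random.default_rng(2))
        b = build_choice_sets(steps, mot, small_landscape, M=5,
                              rng=np.random.default_rng(2))
        for ca, cb in zip(a.sets, b.sets):
            np.testing.assert_array_equal(ca.avail_xy, cb.avail_xy)

    def test_out_of_bounds_used_point_drops_stratum(self, rng):
        from rayssf.motility import MotilitySeries
        from rayssf.tracks import Track, derive_steps

        # one excursion far outside the 10x10 landscape
        track = Track("a", [0.0, 1.0, 2.0, 3.0],
                      [(5, 5), (500, 500), (5, 5), (6, 5)])
        steps = derive_steps(track)
        scape = Landscape({"z": rng.standard_normal((10, 10))}, (0, 0), 1.0)
        mot = MotilitySeries(
            delta_bar=np.full(3, 0.05), n_window=np.ones(3, int),
            window_hours=None, window_steps=None, floor=1e-8,
            t_mid=steps.midpoint_time, dt=steps.dt,
        )
        sets = build_choice_sets(steps, mot, scape, M=4, rng=rng)
        # stratum 0 (used endpoint out of bounds) must be gone; the step
        # re-entering the landscape survives
        assert sets.n_strata_dropped >= 1
        ids = [cs.stratum_id for cs in sets.sets]
        assert 0 not in ids and 2 in ids

    def test_fully_disjoint_landscape_is_input_error(self, rng):
        from rayssf.motility import MotilitySeries
        from rayssf.tracks import Track, derive_steps

        track = Track("a", [0.0, 1.0], [(1000, 1000), (1001, 1001)])
        steps = derive_steps(track)
        scape = Landscape({"z": np.ones((5, 5))}, (0, 0), 1.0)
        mot = MotilitySeries(
            delta_bar=np.ones(1), n_window=np.ones(1, int),
            window_hours=None, window_steps=None, floor=1e-8,
            t_mid=steps.midpoint_time, dt=steps.dt,
        )
        with pytest.raises(ValueError, match="cover"):
            build_choice_sets(steps, mot, scape, M=4, rng=rng)

    def test_long_format_export_shape(self, sim_choice_sets):
        df = sim_choice_sets.to_frame()
        assert set(df["case"]) == {0, 1}
        assert df.groupby("stratum_id")["case"].sum().eq(1).all()
        assert {"forage", "terrain", "sigma2", "dt_h"} <= set(df.columns)


class TestCompareFits:
    def test_identical_fits_have_unit_ratio(self, sim_choice_sets):
        fit = fit_ssf(sim_choice_sets)
        table = compare_fits(fit, fit)
        np.testing.assert_allclose(table["ci_width_ratio"], 1.0)
        assert not table["sign_disagrees"].any()

    def test_subset_fit_reports_smaller_n(self, sim_choice_sets):
        from rayssf.ssf import ChoiceSetCollection

        full = fit_ssf(sim_choice_sets)
        half = ChoiceSetCollection(
            sets=sim_choice_sets.sets[::2],
            covariate_names=sim_choice_sets.covariate_names,
            sampler=sim_choice_sets.sampler,
            M=sim_choice_sets.M,
        )
        sub = fit_ssf(half)
        table = compare_fits(full, sub, labels=("full", "half"))
        assert table.attrs["n_strata"]["half"] == len(half)
        assert table.attrs["n_strata"]["full"] == len(sim_choice_sets)

    def test_mismatched_covariates_rejected(self, sim_choice_sets, rng):
        fit = fit_ssf(sim_choice_sets)
        other = fit_ssf(random_sets(rng, n_strata=30, M=8))
        with pytest.raises(ValueError, match="covariate"):
            compare_fits(fit, other)
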