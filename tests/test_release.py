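"""Release-model fitting, ranking and mechanistic decomposition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from buccalkinetics import (
    DegenerateCurveError,
    InvalidInputError,
    KineticFit,
    ReleaseProfile,
    aspect_ratio,
    classify_transport,
    evaluate_model,
    fit_all_models,
    fit_release_model,
    mechanism_decomposition,
    rank_models,
    truncate_at_fraction,
)
from buccalkinetics.release import MODEL_NAMES

# reference matrix-tablet power-law and Peppas-Sahlin parameters
POWERLAW_B = {"k": 0.25748, "n": 0.34963}
PEPPAS_SAHLIN_B = {"k1": 0.25062, "k2": -0.01263}
M_EXP = 0.43

RECOVERY_TRUTH = {
    "zero_order": {"k": 0.012},
    "first_order": {"k": 0.05},
    "higuchi": {"k": 0.11},
    "korsmeyer_peppas": {"k": 0.25, "n": 0.35},
    "hixson_crowell": {"k": 0.012},
    "peppas_sahlin": {"k1": 0.22, "k2": -0.011},
}


def _profile(times, model, params):
    d = np.asarray(evaluate_model(model, times, params, M_EXP))
    return ReleaseProfile(times_min=times, dose_fraction=np.clip(d, 0, 1.05))


class TestTruncation:
    def test_keeps_first_point_beyond_cutoff(self):
        t = np.array([10, 20, 30, 40, 45, 50], float)
        d = np.array([0.3, 0.5, 0.7, 0.85, 0.93, 0.97])
        res = truncate_at_fraction(ReleaseProfile(t, d), 0.9)
        assert res.cutoff_reached
        assert res.truncation_time_min == 45
        assert res.profile.times_min[-1] == 45

    def test_profile_never_reaching_cutoff_is_returned_flagged(self):
        t = np.array([10, 20, 30], float)
        d = np.array([0.3, 0.5, 0.7])
        res = truncate_at_fraction(ReleaseProfile(t, d), 0.9)
        assert not res.cutoff_reached
        assert np.array_equal(res.profile.dose_fraction, d)

    def test_cutoff_one_keeps_everything(self):
        t = np.array([10, 20, 30], float)
        d = np.array([0.3, 0.5, 1.0])
        res = truncate_at_fraction(ReleaseProfile(t, d), 1.0)
        assert res.profile.times_min.size == 3

    def test_invalid_cutoff_rejected(self):
        prof = ReleaseProfile(np.array([1.0, 2.0]), np.array([0.1, 0.2]))
        with pytest.raises(InvalidInputError):
            truncate_at_fraction(prof, 0.0)


class TestModelFitting:
    @pytest.mark.parametrize("model", MODEL_NAMES)
    def test_noiseless_recovery_of_every_model(self, model):
        t = np.linspace(3, 40, 13)
        truth = RECOVERY_TRUTH[model]
        fit = fit_release_model(_profile(t, model, truth), model)
        assert fit.converged
        for name, value in truth.items():
            assert fit.params[name] == pytest.approx(value, rel=1e-6), (model, name)

    def test_powerlaw_recovers_printed_parameters(self):
        t = np.linspace(3, 40, 13)
        fit = fit_release_model(
            _profile(t, "korsmeyer_peppas", POWERLAW_B), "korsmeyer_peppas"
        )
        assert fit.params["k"] == pytest.approx(POWERLAW_B["k"], rel=1e-6)
        assert fit.params["n"] == pytest.approx(POWERLAW_B["n"], rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_free_exponent_dominates_nested_fixed_exponent_models(self):
        # the power law nests Higuchi (n=0.5) and zero order (n=1), so
        # its least-squares r^2 can never be lower
        rng = np.random.default_rng(11)
        t = np.linspace(3, 40, 13)
        for seed in range(5):
            d = np.clip(
                0.2 * t**0.4 + rng.normal(0, 0.03, t.size), 0, 1.05
            )
            prof = ReleaseProfile(t, d)
            kp = fit_release_model(prof, "korsmeyer_peppas")
            assert kp.r2 >= fit_release_model(prof, "higuchi").r2 - 1e-9
            assert kp.r2 >= fit_release_model(prof, "zero_order").r2 - 1e-9

    def test_optimizer_matches_dense_grid_oracle(self):
        rng = np.random.default_rng(5)
        t = np.linspace(3, 40, 13)
        d = np.clip(
            np.asarray(evaluate_model("korsmeyer_peppas", t, POWERLAW_B))
            + rng.normal(0, 0.01, t.size),
            0,
            1.05,
        )
        fit = fit_release_model(ReleaseProfile(t, d), "korsmeyer_peppas")
        ks = np.linspace(0.01, 1.0, 300)
        ns = np.linspace(0.05, 1.2, 300)
        pred = ks[None, :, None] * t[None, None, :] ** ns[:, None, None]
        ssr = np.sum((pred - d[None, None, :]) ** 2, axis=-1)
        i, j = np.unravel_index(np.argmin(ssr), ssr.shape)
        dk, dn = ks[1] - ks[0], ns[1] - ns[0]
        assert abs(fit.params["k"] - ks[j]) <= 2 * dk
        assert abs(fit.params["n"] - ns[i]) <= 2 * dn
        fit_ssr = np.sum(
            (d - fit.params["k"] * t ** fit.params["n"]) ** 2
        )
        assert fit_ssr <= ssr[i, j] + 1e-12

    def test_insufficient_points_rejected(self):
        prof = ReleaseProfile(np.array([1.0, 2.0, 3.0]), np.array([0.1, 0.2, 0.3]))
        with pytest.raises(InvalidInputError):
            fit_release_model(prof, "korsmeyer_peppas")

    def test_printed_powerlaw_consistent_with_truncation_rule(self):
        # the reference power law evaluated at its truncation time sits
        # between 85% and 100% released
        d40 = evaluate_model("korsmeyer_peppas", 40.0, POWERLAW_B)
        assert 0.85 < float(d40) < 1.0


class TestRanking:
    def _fit(self, model, r2, converged=True):
        return KineticFit(
            model=model, params={"k": 0.1}, param_se={"k": 0.0}, r2=r2,
            truncation_time_min=40.0, converged=converged,
        )

    def test_sorted_by_descending_r2(self):
        fits = [
            self._fit("zero_order", 0.472),
            self._fit("korsmeyer_peppas", 0.931),
            self._fit("higuchi", 0.743),
        ]
        assert [f.model for f in rank_models(fits)] == [
            "korsmeyer_peppas", "higuchi", "zero_order",
        ]

    def test_single_fit_ranks_alone(self):
        fits = [self._fit("higuchi", 0.9)]
        assert rank_models(fits) == fits

    def test_tie_goes_to_fewer_parameters(self):
        fits = [self._fit("korsmeyer_peppas", 0.9), self._fit("higuchi", 0.9)]
        assert rank_models(fits)[0].model == "higuchi"

    def test_nonconverged_listed_last(self):
        fits = [
            self._fit("zero_order", -np.inf, converged=False),
            self._fit("higuchi", 0.5),
        ]
        ranked = rank_models(fits)
        assert ranked[-1].model == "zero_order"
        assert not ranked[-1].converged


class TestMechanismDecomposition:
    def _ps_fit(self, k1, k2):
        return KineticFit(
            model="peppas_sahlin", params={"k1": k1, "k2": k2},
            param_se={}, r2=0.98, truncation_time_min=40.0, converged=True,
            m_exponent=M_EXP,
        )

    def test_pure_fickian_limit(self):
        series = mechanism_decomposition(self._ps_fit(0.25, 0.0), [5, 20, 40])
        assert np.allclose(series.fickian_fraction, 1.0)
        assert np.allclose(series.r_over_f, 0.0)

    def test_printed_parameters_evaluate_by_direct_arithmetic(self):
        k1, k2 = PEPPAS_SAHLIN_B["k1"], PEPPAS_SAHLIN_B["k2"]
        series = mechanism_decomposition(self._ps_fit(k1, k2), [40.0])
        expected_rf = (k2 / k1) * 40.0**M_EXP
        assert series.r_over_f[0] == pytest.approx(expected_rf, rel=1e-12)
        assert series.fickian_fraction[0] == pytest.approx(
            1.0 / (1.0 + expected_rf), rel=1e-12
        )
        assert series.outside_unit_range  # k2 < 0

    def test_identity_f_times_one_plus_rf(self):
        times = np.linspace(1, 60, 25)
        for k1, k2 in [(0.25062, -0.01263), (0.2, 0.05), (0.1, 0.0)]:
            series = mechanism_decomposition(self._ps_fit(k1, k2), times)
            ident = series.fickian_fraction * (1.0 + series.r_over_f)
            assert np.all(np.abs(ident - 1.0) < 1e-12)

    def test_rf_monotonicity_follows_sign_of_k2(self):
        times = np.linspace(1, 60, 30)
        down = mechanism_decomposition(self._ps_fit(0.25, -0.01), times)
        up = mechanism_decomposition(self._ps_fit(0.25, 0.01), times)
        assert np.all(np.diff(down.r_over_f) < 0)
        assert np.all(np.diff(up.r_over_f) > 0)

    def test_degenerate_k1_rejected(self):
        with pytest.raises(DegenerateCurveError):
            mechanism_decomposition(self._ps_fit(0.0, 0.01), [10])


class TestTransportClassification:
    @pytest.mark.parametrize(
        "n,label",
        [
            (0.2996, "sub-Fickian/anomalous (diffusion-dominated)"),
            (0.5, "Fickian (Higuchi)"),
            (0.75, "anomalous transport"),
            (1.0, "Case II or super Case II"),
            (1.3, "Case II or super Case II"),
        ],
    )
    def test_labels(self, n, label):
        assert classify_transport(n) == label

    def test_nonfinite_rejected(self):
        with pytest.raises(InvalidInputError):
            classify_transport(float("nan"))


class TestAspectRatio:
    @pytest.mark.parametrize(
        "d_cm,th_mm,expected",
        [(0.65, 1.01, 6.44), (0.65, 0.88, 7.39), (1.0, 10.0, 1.0)],
    )
    def test_examples(self, d_cm, th_mm, expected):
        assert aspect_ratio(d_cm, th_mm) == pytest.approx(expected, abs=0.005)

    def test_nonpositive_rejected(self):
        with pytest.raises(InvalidInputError):
            aspect_ratio(0.0, 1.0)


class TestPipeline:
    def test_fit_all_models_truncates_and_ranks(self):
        t = np.linspace(3, 60, 15)
        d = np.clip(
            np.asarray(evaluate_model("korsmeyer_peppas", t, POWERLAW_B)), 0, 1.0
        )
        fits = fit_all_models(ReleaseProfile(t, d))
        assert fits[0].model == "korsmeyer_peppas"
        assert fits[0].r2 == pytest.approx(1.0, abs=1e-10)
        # truncated at the first point past 90% release
        assert all(f.truncation_time_min < 60 for f in fits if f.converged)


@given(
    k1=st.floats(0.05, 0.5),
    k2=st.floats(-0.05, 0.05),
    t=st.floats(0.1, 200.0),
)
@settings(max_examples=100, deadline=None)
def test_decomposition_identity_property(k1, k2, t):
    fit = KineticFit(
        model="peppas_sahlin", params={"k1": k1, "k2": k2}, param_se={},
        r2=1.0, truncation_time_min=40.0, converged=True, m_exponent=M_EXP,
    )
    series = mechanism_decomposition(fit, [t])
    assert abs(series.fickian_fraction[0] * (1 + series.r_over_f[0]) - 1) < 1e-12
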