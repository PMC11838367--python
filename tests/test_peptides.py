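"""Peptide-genotype inference tests: band classifier geometry, zero
overrides, L1 fit optimality, and end-to-end call accuracy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apolq.peptides import (
    CALL_DOSAGE,
    NoCallError,
    call_g1g2,
    call_v1,
    call_v1_table,
    evaluate_calls,
    fit_l1,
    infer_g1g2_from_peptides,
    true_carrier_dosage,
)
from apolq.simulate import (
    TRANS_FREQS,
    build_default_pool,
    default_peptide_spec,
    healthabc_spec,
    simulate_cohort,
    simulate_measurements,
    simulate_peptides,
)

from .oracles import lasso_kkt_violation


class TestCallV1:
    @pytest.mark.parametrize(
        "x,y,call,basis",
        [
            (2.0, 2.3, "GA", "band_rule"),      # inside (1.5, 3.0)
            (2.0, 0.4, "GG", "band_rule"),      # below band
            (2.0, 3.5, "AA", "band_rule"),      # above band
            (0.0, 1.2, "AA", "zero_override"),
            (1.2, 0.0, "GG", "zero_override"),
            (2.0, 1.5, "GG", "band_rule"),      # boundary y = x - 0.5
            (2.0, 3.0, "AA", "band_rule"),      # boundary y = x + 1
        ],
    )
    def test_examples(self, x, y, call, basis):
        c = call_v1(x, y)
        assert (c.call, c.basis) == (call, basis)

    def test_both_zero_is_no_call(self):
        with pytest.raises(NoCallError):
            call_v1(0.0, 0.0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-5, 5, allow_nan=False),
        st.floats(-5, 5, allow_nan=False),
    )
    def test_every_input_gets_exactly_one_call(self, x, y):
        if x == 0.0 and y == 0.0:
            return
        assert call_v1(x, y).call in ("GG", "GA", "AA")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.floats(-3, 3, allow_nan=False),
        st.floats(-3, 3, allow_nan=False),
        st.floats(-2, 2, allow_nan=False),
    )
    def test_band_membership_shift_invariant(self, x, y, c):
        """Outside the zero-override cases, the band rule depends only on
        y - x, so shifting both coordinates preserves the call."""
        pts = [(x, y), (x + c, y + c)]
        if any(xi == 0.0 or yi == 0.0 for xi, yi in pts):
            return
        assert call_v1(*pts[0]).call == call_v1(*pts[1]).call

    def test_zero_override_dominates_band(self):
        # a (0, y) point that would band-classify as GA still calls AA
        for y in np.linspace(-0.4, 0.9, 7):
            if y == 0.0:
                continue
            assert call_v1(0.0, float(y)).call == "AA"
            assert call_v1(0.0, float(y)).basis == "zero_override"


class TestFitL1:
    def test_full_shrinkage(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        y = rng.normal(size=40) + 3.0
        model = fit_l1(X, y, alpha=1e6)
        assert np.all(model.weights == 0)
        assert model.intercept == pytest.approx(y.mean(), abs=1e-9)

    def test_unpenalized_limit_matches_ols(self):
        x = np.linspace(0, 1, 30)
        y = 2.5 * x + 1.0
        model = fit_l1(pd.DataFrame({"x": x}), y, alpha=0.0)
        assert model.weights[0] == pytest.approx(2.5, abs=1e-9)

    def test_subgradient_optimality(self):
        """Random 50x18 problem at alpha=0.01: KKT violation below 1e-8."""
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 18))
        w_true = np.zeros(18)
        w_true[:4] = [0.5, -0.3, 0.2, 0.1]
        y = X @ w_true + 0.1 * rng.normal(size=50)
        model = fit_l1(pd.DataFrame(X), y, alpha=0.01)
        assert lasso_kkt_violation(X, y, model.weights, model.intercept, 0.01) < 1e-8

    def test_empty_training_set(self):
        with pytest.raises(ValueError):
            fit_l1(pd.DataFrame(columns=["a"]), np.array([]))


class TestCallG1G2:
    def _identity_model(self):
        # single feature passed through: prediction == feature value
        from apolq.peptides import L1Model

        return L1Model(np.array([1.0]), 0.0, ["f"], 0.0)

    @pytest.mark.parametrize(
        "observed,call,basis",
        [
            (6.0, "REF_REF", "band_rule"),   # above 5/3*3 = 5
            (4.5, "REF_ALT", "band_rule"),   # in [4, 5)
            (3.5, "ALT_ALT", "band_rule"),   # below 4
            (0.0, "ALT_ALT", "zero_override"),
        ],
    )
    def test_thresholds_at_prediction_three(self, observed, call, basis):
        model = self._identity_model()
        feats = pd.DataFrame({"f": [3.0]}, index=["s"])
        out = call_g1g2(model, feats, np.array([observed]))
        assert (out["call"].iloc[0], out["basis"].iloc[0]) == (call, basis)

    def test_missing_features_no_call(self):
        model = self._identity_model()
        feats = pd.DataFrame({"f": [np.nan]}, index=["s"])
        with pytest.raises(NoCallError):
            call_g1g2(model, feats, np.array([1.0]))


class TestEndToEnd:
    def test_noiseless_carrier_calls_match_truth(self, afr_pool, eur_pool):
        """With vanishing peptide noise and a tight abundance spread the
        inferred G1/G2 dosages equal the truth exactly."""
        spec = healthabc_spec()
        spec.shared_T_sd = 0.15
        pspec = default_peptide_spec(spec.baseline_mu, pep_noise_sd=0.0)
        ca = simulate_cohort(afr_pool, 60, seed=1, sample_prefix="A")
        ce = simulate_cohort(eur_pool, 120, seed=2, sample_prefix="E")
        _, Ta = simulate_measurements(ca, spec, ("Olink",), seed=3)
        _, Te = simulate_measurements(ce, spec, ("Olink",), seed=4)
        pa = simulate_peptides(ca, pspec, Ta, seed=5)
        pe = simulate_peptides(ce, pspec, Te, seed=6)
        combined = pd.concat([pe.data, pa.data])
        calls, _ = infer_g1g2_from_peptides(combined, list(pe.data.index),
                                            list(pa.data.index))
        d_hat = calls["call"].map(CALL_DOSAGE)
        truth = true_carrier_dosage(ca)
        assert (d_hat.to_numpy() == truth.to_numpy()).all()

    def test_v1_accuracy_at_reference_noise(self, afr_pool):
        """V1 band calls reach >0.95 genotype accuracy at peptide noise
        SD 0.3."""
        spec = healthabc_spec()
        pspec = default_peptide_spec(spec.baseline_mu, pep_noise_sd=0.3)
        c = simulate_cohort(afr_pool, 500, seed=7)
        _, T = simulate_measurements(c, spec, ("Olink",), seed=8)
        peps = simulate_peptides(c, pspec, T, seed=9)
        calls = call_v1_table(peps.data)
        d_hat = calls["call"].map(CALL_DOSAGE)
        truth = pd.Series(c.dosage("V1"), index=c.sample_ids)
        res = evaluate_calls(calls["call"], truth, labels=("GG", "GA", "AA"))
        assert res["accuracy"] > 0.95
        assert (d_hat == truth).mean() > 0.95


class TestEvaluateCalls:
    def test_identity_confusion(self):
        idx = ["a", "b", "c"]
        calls = pd.Series(["REF_REF", "REF_ALT", "ALT_ALT"], index=idx)
        truth = pd.Series([0, 1, 2], index=idx)
        res = evaluate_calls(calls, truth)
        mat = res["confusion"]
        assert mat.loc[0, "REF_REF"] == 1
        assert mat.loc[1, "REF_ALT"] == 1
        assert mat.loc[2, "ALT_ALT"] == 1
        assert res["accuracy"] == 1.0
        assert res["carrier_sensitivity"] == 1.0
        assert res["carrier_specificity"] == 1.0

    def test_all_no_call(self):
        idx = ["a", "b"]
        calls = pd.Series(["NO_CALL", "NO_CALL"], index=idx)
        truth = pd.Series([0, 1], index=idx)
        res = evaluate_calls(calls, truth)
        assert res["confusion"]["NO_CALL"].sum() == 2
        assert np.isnan(res["accuracy"])

    def test_id_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_calls(pd.Series(["REF_REF"], index=["a"]),
                           pd.Series([0], index=["b"]))
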