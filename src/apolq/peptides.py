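"""Genotype inference from allele-specific tryptic peptides.

Two classifiers over log2 sample/bridge peptide ratios, where an exact
0.0 is the "not detected" sentinel:

* V1 (rs2239785): the SELEDNIRR / LEDNIRR peptides carry the reference
  (G) and alternative (A) alleles respectively.  Calls use a diagonal
  band in the (x, y) = (SELEDNIRR, LEDNIRR) plane — heterozygotes sit
  near y = x, homozygotes near one axis — with exact zeros overriding
  the band.

* G1/G2: the LNILNNNYK peptide spans both variant positions and only
  exists on haplotypes carrying the reference allele at both.  An
  L1-penalized model trained on a reference panel (Europeans, virtually
  all non-carriers) predicts its expected abundance from the other 18
  APOL1 peptides; the shortfall of the observed value below prediction
  grades the carrier dosage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso

from .simulate import PEPTIDE_G1G2, PEPTIDE_V1_ALT, PEPTIDE_V1_REF, PhasedCohort

V1_CALLS = ("GG", "GA", "AA")
G1G2_CALLS = ("REF_REF", "REF_ALT", "ALT_ALT")


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str
    basis: str  # band_rule | zero_override | no_call


class NoCallError(ValueError):
    pass


def call_v1(x: float, y: float) -> GenotypeCall:
    """V1 genotype from x = SELEDNIRR (REF peptide), y = LEDNIRR (ALT).

    Zero overrides dominate: an undetected ALT peptide means G/G, an
    undetected REF peptide means A/A.  Otherwise the band
    x - 0.5 < y < x + 1 calls a heterozygote; boundary values fall to the
    homozygous side.  Both peptides undetected is a no-call.
    """
    if x == 0.0 and y == 0.0:
        raise NoCallError("both V1 peptides undetected")
    if y == 0.0:
        return GenotypeCall("", "GG", "zero_override")
    if x == 0.0:
        return GenotypeCall("", "AA", "zero_override")
    if x - 0.5 < y < x + 1.0:
        return GenotypeCall("", "GA", "band_rule")
    if y <= x - 0.5:
        return GenotypeCall("", "GG", "band_rule")
    return GenotypeCall("", "AA", "band_rule")


def call_v1_table(peptides: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for sid, row in peptides.iterrows():
        try:
            c = call_v1(float(row[PEPTIDE_V1_REF]), float(row[PEPTIDE_V1_ALT]))
            rows.append({"sample_id": sid, "call": c.call, "basis": c.basis})
        except NoCallError:
            rows.append({"sample_id": sid, "call": "NO_CALL", "basis": "no_call"})
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class L1Model:
    weights: np.ndarray
    intercept: float
    feature_names: list[str]
    alpha: float
    training_ids: list[str] = field(default_factory=list)

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        X = features[self.feature_names].to_numpy(dtype=float)
        if np.isnan(X).any():
            raise NoCallError("missing feature values")
        return X @ self.weights + self.intercept


def fit_l1(features: pd.DataFrame, target: np.ndarray, alpha: float = 0.01) -> L1Model:
    """L1-penalized least squares (objective (1/2n)||y - Xw - b||^2 +
    alpha*||w||_1, intercept unpenalized, features unstandardized), fit by
    coordinate descent via scikit-learn's Lasso."""
    if len(features) == 0:
        raise ValueError("empty training set")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    X = features.to_numpy(dtype=float)
    y = np.asarray(target, dtype=float)
    if alpha == 0:
        # unpenalized limit: plain least squares
        Xd = np.column_stack([X, np.ones(len(y))])
        coefs, *_ = np.linalg.lstsq(Xd, y, rcond=None)
        w, b = coefs[:-1], coefs[-1]
    else:
        model = Lasso(alpha=alpha, fit_intercept=True, tol=1e-12, max_iter=200_000)
        model.fit(X, y)
        w, b = model.coef_, float(model.intercept_)
    return L1Model(np.asarray(w, float), float(b), list(features.columns), alpha,
                   list(features.index.astype(str)))


def call_g1g2(model: L1Model, features: pd.DataFrame, observed: np.ndarray) -> pd.DataFrame:
    """G1/G2 carrier calls from predicted (x) vs observed (y) LNILNNNYK.

    y < 5/3*x - 1 calls ALT/ALT, y < 5/3*x calls REF/ALT, otherwise
    REF/REF; an exactly-zero observation overrides to ALT/ALT.
    """
    x = model.predict(features)
    y = np.asarray(observed, dtype=float)
    calls, bases = [], []
    for xi, yi in zip(x, y):
        if yi == 0.0:
            calls.append("ALT_ALT")
            bases.append("zero_override")
        elif yi < (5.0 / 3.0) * xi - 1.0:
            calls.append("ALT_ALT")
            bases.append("band_rule")
        elif yi < (5.0 / 3.0) * xi:
            calls.append("REF_ALT")
            bases.append("band_rule")
        else:
            calls.append("REF_REF")
            bases.append("band_rule")
    return pd.DataFrame(
        {"call": calls, "basis": bases, "predicted": x, "observed": y},
        index=features.index,
    )


def infer_g1g2_from_peptides(
    peptides: pd.DataFrame,
    train_ids: list[str],
    test_ids: list[str],
    alpha: float = 0.01,
) -> tuple[pd.DataFrame, L1Model]:
    """End-to-end G1/G2 inference: train the L1 predictor of LNILNNNYK on
    the reference panel, then classify the analysis samples."""
    feats = [c for c in peptides.columns if c != PEPTIDE_G1G2]
    model = fit_l1(peptides.loc[train_ids, feats], peptides.loc[train_ids, PEPTIDE_G1G2], alpha)
    calls = call_g1g2(model, peptides.loc[test_ids, feats],
                      peptides.loc[test_ids, PEPTIDE_G1G2].to_numpy())
    return calls, model


CALL_DOSAGE = {"REF_REF": 0, "REF_ALT": 1, "ALT_ALT": 2, "GG": 0, "GA": 1, "AA": 2}


def evaluate_calls(
    calls: pd.Series,
    truth_dosage: pd.Series,
    labels: tuple[str, ...] = G1G2_CALLS,
) -> dict:
    """Confusion matrix (truth dosage x called class, with an explicit
    no-call row) plus genotype accuracy and carrier sensitivity/specificity."""
    if not calls.index.equals(truth_dosage.index):
        raise ValueError("call and truth sample ids do not match")
    classes = list(labels) + ["NO_CALL"]
    mat = pd.DataFrame(0, index=[0, 1, 2], columns=classes)
    for sid in calls.index:
        c = calls[sid] if calls[sid] in classes else "NO_CALL"
        mat.loc[int(truth_dosage[sid]), c] += 1
    called = calls.map(lambda c: CALL_DOSAGE.get(c, np.nan))
    ok = called.notna()
    acc = float((called[ok] == truth_dosage[ok]).mean()) if ok.any() else np.nan
    true_carrier = truth_dosage >= 1
    called_carrier = called >= 1
    sens = (
        float(called_carrier[ok & true_carrier].mean()) if (ok & true_carrier).any() else np.nan
    )
    spec = (
        float((~called_carrier[ok & ~true_carrier]).mean())
        if (ok & ~true_carrier).any()
        else np.nan
    )
    return {"confusion": mat, "accuracy": acc, "carrier_sensitivity": sens,
            "carrier_specificity": spec}


def true_carrier_dosage(cohort: PhasedCohort) -> pd.Series:
    """True G1+G2 risk-allele dosage (G1M as the G1 proxy)."""
    d = cohort.dosage("G1M") + cohort.dosage("G2")
    return pd.Series(d, index=cohort.sample_ids)
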