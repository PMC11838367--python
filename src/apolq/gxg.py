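"""Genetic-interaction (GxG) testing.

Two complementary designs: a product-term regression
y ~ v1 + v2 + v1*v2 + covariates whose interaction coefficient tests
deviation from additivity, and a stratified contrast that fits
y ~ v1 + covariates separately in carriers and non-carriers of a
modifier variant and compares the two slopes with
t = (beta1 - beta2) / sqrt(se1^2 + se2^2) on n1 + n2 - 4 degrees of
freedom.  For modifiers that never share a haplotype with the target
(G1/G2), only heterozygous carriers enter the carrier stratum, since in
modifier homozygotes the target is necessarily monomorphic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .assoc import CovariateSet, _ols


@dataclass
class InteractionRecord:
    v1: str
    v2: str
    protein: str
    interaction_beta: float
    interaction_se: float
    interaction_p: float
    n: int
    flagged: bool = False


@dataclass
class StratifiedContrast:
    beta1: float  # effect of v1 where the modifier is absent
    beta2: float  # effect of v1 in modifier carriers
    se1: float
    se2: float
    n1: int
    n2: int
    t: float
    df: int
    p: float
    carrier_rule: str


def _design(d: np.ndarray, covariates: CovariateSet | None, n: int) -> np.ndarray:
    C = covariates.to_matrix(n) if covariates is not None else np.empty((n, 0))
    return np.column_stack([np.ones(n), d, C]) if d.ndim == 1 else np.column_stack(
        [np.ones(n)] + [d[:, j] for j in range(d.shape[1])] + [C]
    )


def interaction_test(
    d1: np.ndarray,
    d2: np.ndarray,
    phenotype: np.ndarray,
    covariates: CovariateSet | None = None,
    v1: str = "v1",
    v2: str = "v2",
    protein: str = "protein",
) -> InteractionRecord:
    """Product-term interaction regression; the record is flagged (with NaN
    statistics) when the design is collinear."""
    d1 = np.asarray(d1, float)
    d2 = np.asarray(d2, float)
    y = np.asarray(phenotype, float)
    n = len(y)
    X = _design(np.column_stack([d1, d2, d1 * d2]), covariates, n)
    ok = ~(np.isnan(X).any(axis=1) | np.isnan(y))
    try:
        beta, se, df = _ols(y[ok], X[ok])
    except np.linalg.LinAlgError:
        return InteractionRecord(v1, v2, protein, np.nan, np.nan, np.nan, int(ok.sum()), True)
    tstat = beta[3] / se[3]
    p = 2.0 * t_dist.sf(abs(tstat), df)
    return InteractionRecord(v1, v2, protein, float(beta[3]), float(se[3]), float(p),
                             int(ok.sum()))


def _stratum_fit(d, y, covariates, mask, name, min_extra=3):
    d_s, y_s = d[mask], y[mask]
    n_s = int(mask.sum())
    if n_s == 0:
        raise ValueError(f"stratum {name!r} is empty")
    if np.ptp(d_s) == 0:
        raise ValueError(f"variant is monomorphic in stratum {name!r}")
    C = covariates.to_matrix(len(d)) if covariates is not None else np.empty((len(d), 0))
    C_s = C[mask]
    # constant covariate columns within a stratum carry no information
    keep = [j for j in range(C_s.shape[1]) if np.ptp(C_s[:, j]) > 0]
    X = np.column_stack([np.ones(n_s), d_s, C_s[:, keep]])
    if n_s < X.shape[1] + min_extra - 1:
        raise ValueError(f"stratum {name!r} too small for the model")
    beta, se, _ = _ols(y_s, X)
    return float(beta[1]), float(se[1]), n_s


def stratified_contrast(
    d_target: np.ndarray,
    d_modifier: np.ndarray,
    phenotype: np.ndarray,
    covariates: CovariateSet | None = None,
    carrier_rule: str = "het_only",
) -> StratifiedContrast:
    """Stratified effect-difference test.

    Stratum 1 contains modifier non-carriers; stratum 2 contains carriers
    per ``carrier_rule`` ("het_only" admits heterozygotes only, the right
    choice when modifier homozygotes force the target monomorphic;
    "het_or_hom" admits any carrier).
    """
    if carrier_rule not in ("het_only", "het_or_hom"):
        raise ValueError("carrier_rule must be het_only or het_or_hom")
    d = np.asarray(d_target, float)
    dm = np.asarray(d_modifier, float)
    y = np.asarray(phenotype, float)
    absent = dm == 0
    present = (dm == 1) if carrier_rule == "het_only" else (dm >= 1)
    b1, s1, n1 = _stratum_fit(d, y, covariates, absent, "modifier-absent")
    b2, s2, n2 = _stratum_fit(d, y, covariates, present, "modifier-present")
    tstat = (b1 - b2) / np.sqrt(s1**2 + s2**2)
    df = n1 + n2 - 4
    p = 2.0 * t_dist.sf(abs(tstat), df)
    return StratifiedContrast(b1, b2, s1, s2, n1, n2, float(tstat), int(df), float(p),
                              carrier_rule)


def panel_scan(
    dosage: np.ndarray,
    protein_panel: pd.DataFrame,
    covariates: CovariateSet | None = None,
    correction: str = "bonferroni",
) -> pd.DataFrame:
    """Single-variant association against a panel of proteins with
    Bonferroni adjustment, ranked by p-value.

    All proteins share one design matrix, so the scan is a single batched
    least-squares solve.
    """
    if correction != "bonferroni":
        raise ValueError("only bonferroni correction is implemented")
    if protein_panel.shape[1] < 1:
        raise ValueError("panel must contain at least one protein")
    d = np.asarray(dosage, float)
    n, n_prot = protein_panel.shape
    X = _design(d, covariates, n)
    Y = protein_panel.to_numpy(dtype=float)
    XtXinv = np.linalg.inv(X.T @ X)
    B = XtXinv @ X.T @ Y
    resid = Y - X @ B
    df = n - X.shape[1]
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(XtXinv[1, 1] * sigma2)
    tstat = B[1] / se
    p = 2.0 * t_dist.sf(np.abs(tstat), df)
    out = pd.DataFrame(
        {
            "protein": protein_panel.columns,
            "beta": B[1],
            "se": se,
            "p": p,
            "p_adj": np.minimum(1.0, p * n_prot),
        }
    ).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, n_prot + 1)
    out["significant"] = out["p_adj"] < 0.05
    return out
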