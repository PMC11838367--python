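"""Additive-model pQTL association scanning.

Each variant is tested with two ordinary-least-squares fits sharing the
same covariates: the inverse-normal-transformed phenotype provides the
test statistic and p-value, while an untransformed fit provides the
per-allele effect on the raw measurement scale (the reporting
convention for the published estimates this package emulates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata, t as t_dist


@dataclass
class AssocRecord:
    """One variant-protein association; raw- and transformed-scale betas."""

    variant_id: str
    beta_int: float
    beta_raw: float
    se_int: float
    se_raw: float
    p: float
    n: int
    adjusted_for: list[str] = field(default_factory=list)
    flagged: bool = False


@dataclass
class CovariateSet:
    """Covariate table builder: age, sex, genotype PCs, protein-expression
    PCs and any extra columns (e.g. blood-pressure set or HPR copy number).
    Missing values are mean-imputed; constant columns are dropped."""

    age: np.ndarray | None = None
    sex: np.ndarray | None = None
    genotype_pcs: np.ndarray | None = None
    expression_pcs: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def to_matrix(self, n: int) -> np.ndarray:
        cols = []
        if self.age is not None:
            cols.append(("age", np.asarray(self.age, float)))
        if self.sex is not None:
            cols.append(("sex", np.asarray(self.sex, float)))
        if self.genotype_pcs is not None:
            g = np.atleast_2d(np.asarray(self.genotype_pcs, float))
            for k in range(g.shape[1]):
                cols.append((f"gPC{k + 1}", g[:, k]))
        if self.expression_pcs is not None:
            e = np.atleast_2d(np.asarray(self.expression_pcs, float))
            for k in range(e.shape[1]):
                cols.append((f"ePC{k + 1}", e[:, k]))
        for name, v in self.extra.items():
            cols.append((name, np.asarray(v, float)))
        out = []
        for name, v in cols:
            if len(v) != n:
                raise ValueError(f"covariate {name} has length {len(v)}, expected {n}")
            v = v.copy()
            miss = np.isnan(v)
            if miss.all():
                raise ValueError(f"covariate {name} is entirely missing")
            if miss.any():
                v[miss] = v[~miss].mean()
            if np.ptp(v) == 0:
                continue  # constant after imputation carries no information
            out.append(v)
        if not out:
            return np.empty((n, 0))
        return np.column_stack(out)


def inverse_normal(values: np.ndarray) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset,
    Phi^-1((rank - 3/8) / (n + 1/4)); ties share average ranks and missing
    values stay missing."""
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    n = ok.sum()
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    out = np.full(v.shape, np.nan)
    ranks = rankdata(v[ok], method="average")
    out[ok] = norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def compute_pcs(matrix: np.ndarray, k: int) -> np.ndarray:
    """Top-k principal-component scores of a samples x features matrix
    (SVD of the column-centered matrix; each component is oriented so its
    largest-magnitude loading is positive)."""
    X = np.asarray(matrix, dtype=float)
    n, m = X.shape
    if k > min(n - 1, m):
        raise ValueError(f"k={k} too large for a {n}x{m} matrix")
    if k == 0:
        return np.empty((n, 0))
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :k] * S[:k]
    for j in range(k):
        lead = Vt[j, np.argmax(np.abs(Vt[j]))]
        if lead < 0:
            scores[:, j] = -scores[:, j]
    return scores


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS coefficients, standard errors and residual df; raises
    np.linalg.LinAlgError on singular designs."""
    n, p = X.shape
    XtX = X.T @ X
    # reject numerically singular designs explicitly
    if np.linalg.cond(XtX) > 1e12:
        raise np.linalg.LinAlgError("singular design")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = n - p
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(np.linalg.inv(XtX)) * sigma2)
    return beta, se, df


def assoc_scan(
    dosages: pd.DataFrame,
    phenotype: np.ndarray,
    covariates: CovariateSet | None = None,
    adjust_variants: list[str] | None = None,
    report_ref_allele: list[str] | None = None,
) -> list[AssocRecord]:
    """Per-variant additive association scan.

    For each variant two OLS fits are run with intercept, covariates and
    any conditioning variants: (a) on the inverse-normal phenotype for
    beta_int and the two-sided t-test p-value, and (b) on the raw
    phenotype for beta_raw.  Variants listed in ``report_ref_allele`` get
    their betas sign-flipped to the reference-allele orientation.
    Collinear designs yield a flagged record rather than an exception.
    """
    y_raw = np.asarray(phenotype, dtype=float)
    if np.nanstd(y_raw) == 0:
        raise ValueError("phenotype is constant")
    n = len(y_raw)
    y_int = inverse_normal(y_raw)
    C = covariates.to_matrix(n) if covariates is not None else np.empty((n, 0))
    adjust_variants = adjust_variants or []
    adj = (
        dosages[adjust_variants].to_numpy(dtype=float)
        if adjust_variants
        else np.empty((n, 0))
    )
    flip = set(report_ref_allele or [])
    base = np.column_stack([np.ones(n), C, adj])
    records = []
    for v in dosages.columns:
        if v in adjust_variants:
            continue
        d = dosages[v].to_numpy(dtype=float)
        X = np.column_stack([d, base])
        ok = ~(np.isnan(X).any(axis=1) | np.isnan(y_raw))
        sign = -1.0 if v in flip else 1.0
        try:
            b_int, se_int, df = _ols(y_int[ok], X[ok])
            b_raw, se_raw, _ = _ols(y_raw[ok], X[ok])
        except np.linalg.LinAlgError:
            records.append(
                AssocRecord(v, np.nan, np.nan, np.nan, np.nan, np.nan, int(ok.sum()),
                            list(adjust_variants), flagged=True)
            )
            continue
        tstat = b_int[0] / se_int[0]
        p = 2.0 * t_dist.sf(abs(tstat), df)
        records.append(
            AssocRecord(
                v,
                sign * b_int[0],
                sign * b_raw[0],
                se_int[0],
                se_raw[0],
                float(p),
                int(ok.sum()),
                list(adjust_variants),
            )
        )
    return records


def records_to_frame(records: list[AssocRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [r.variant_id for r in records],
            "beta_raw": [r.beta_raw for r in records],
            "beta_int": [r.beta_int for r in records],
            "se_int": [r.se_int for r in records],
            "se_raw": [r.se_raw for r in records],
            "p": [r.p for r in records],
            "n": [r.n for r in records],
            "adjusted_for": [",".join(r.adjusted_for) for r in records],
            "flagged": [r.flagged for r in records],
        }
    )


def define_cis_window(
    gene_start: int, gene_end: int, strand: str, pad: int = 200_000
) -> tuple[int, int]:
    """Closed 1-based cis window: pad upstream of the TSS to pad downstream
    of the TES, identical physical interval on either strand, clipped at 1."""
    if pad < 0:
        raise ValueError("pad must be >= 0")
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    return max(1, gene_start - pad), gene_end + pad
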