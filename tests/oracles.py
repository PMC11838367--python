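"""Independent reference implementations used to validate the package's
estimators.  These are deliberately written by different means than the
code they check: exact rational enumeration, dense numerical quadrature,
Monte-Carlo rejection sampling, and convex-optimality (KKT) conditions.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import norm


def hwe_exact_enumeration(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Hardy-Weinberg exact p-value by full enumeration in exact rational
    arithmetic over all heterozygote counts compatible with the allele
    counts."""
    n = n_hom_ref + n_het + n_hom_alt
    na = 2 * n_hom_ref + n_het  # ref allele count
    nb = 2 * n_hom_alt + n_het
    probs = {}
    total = Fraction(0)
    for het in range(min(na, nb) + 1):
        if (na - het) % 2:
            continue
        hr = (na - het) // 2
        ha = (nb - het) // 2
        if hr < 0 or ha < 0:
            continue
        # conditional probability up to the shared normalizer:
        # n! / (hr! het! ha!) * 2^het
        w = Fraction(
            comb(n, hr) * comb(n - hr, het) * 2**het
        )
        probs[het] = w
        total += w
    p_obs = probs[n_het]
    tail = sum(w for w in probs.values() if w <= p_obs)
    return float(Fraction(tail, total))


def finemap_quadrature(X, y, tau, pi, max_k, grid_half_width=2.0, grid_points=601):
    """Posterior over causal configurations by dense trapezoid quadrature
    of the marginal likelihood integral (unit residual variance), for
    small panels.  Returns (configs, posterior probabilities)."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, m = X.shape
    g = np.linspace(-grid_half_width, grid_half_width, grid_points)
    log_prior_odds = np.log(pi) - np.log1p(-pi)
    configs, logml = [], []
    yty = y @ y
    for k in range(max_k + 1):
        for idx in combinations(range(m), k):
            if k == 0:
                val = -0.5 * yty
            else:
                Xs = X[:, list(idx)]
                G = Xs.T @ Xs
                b = Xs.T @ y
                grids = np.meshgrid(*([g] * k), indexing="ij")
                B = np.stack([gr.ravel() for gr in grids], axis=1)  # (npts, k)
                quad = np.einsum("ij,jk,ik->i", B, G, B)
                loglik = -0.5 * (yty - 2 * B @ b + quad)
                logpri = norm.logpdf(B / tau).sum(axis=1) - k * np.log(tau)
                f = np.exp(loglik + logpri - (loglik + logpri).max())
                integral = f.reshape([grid_points] * k)
                for _ in range(k):
                    integral = np.trapezoid(integral, g, axis=-1)
                val = np.log(integral) + (loglik + logpri).max()
            configs.append(idx)
            logml.append(val + k * log_prior_odds)
    logml = np.array(logml)
    w = np.exp(logml - logml.max())
    return configs, w / w.sum()


def power_monte_carlo(n_cases, n_controls, p0, odds_ratio, alpha, n_reps, seed):
    """Rejection rate of the two-sided pooled two-proportion z-test under
    the alternative, by direct simulation."""
    rng = np.random.default_rng(seed)
    p1 = odds_ratio * p0 / (1 - p0 + odds_ratio * p0)
    x1 = rng.binomial(n_cases, p1, size=n_reps)
    x0 = rng.binomial(n_controls, p0, size=n_reps)
    ph1 = x1 / n_cases
    ph0 = x0 / n_controls
    pbar = (x1 + x0) / (n_cases + n_controls)
    se = np.sqrt(pbar * (1 - pbar) * (1 / n_cases + 1 / n_controls))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, (ph1 - ph0) / se, 0.0)
    crit = norm.ppf(1 - alpha / 2)
    return float(np.mean(np.abs(z) > crit))


def lasso_kkt_violation(X, y, w, b, alpha):
    """Maximum violation of the subgradient optimality conditions of
    (1/2n)||y - Xw - b||^2 + alpha*||w||_1 with unpenalized intercept."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = len(y)
    r = y - X @ w - b
    grad = -(X.T @ r) / n
    viol = 0.0
    for j, wj in enumerate(w):
        if wj != 0:
            viol = max(viol, abs(grad[j] + alpha * np.sign(wj)))
        else:
            viol = max(viol, max(0.0, abs(grad[j]) - alpha))
    viol = max(viol, abs(r.mean()))  # intercept stationarity
    return viol
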