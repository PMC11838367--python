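"""Cross-platform effect comparison and the case-control power calculation.

Effect estimates from different proteomic platforms (or studies) are
compared by a two-sample z heterogeneity test on (beta, SE) pairs, by the
Pearson correlation of allele-harmonized effect vectors, and by sign
concordance counts.  The power calculation is the two-proportion z-test
for a difference in high-risk (recessive) genotype frequency between
cases and controls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class HetTest:
    beta_a: float
    se_a: float
    beta_b: float
    se_b: float
    z: float
    p: float


def heterogeneity_test(beta_a: float, se_a: float, beta_b: float, se_b: float) -> HetTest:
    """z = (beta_a - beta_b)/sqrt(se_a^2 + se_b^2), two-sided normal p."""
    if se_a <= 0 or se_b <= 0:
        raise ValueError("standard errors must be positive")
    z = (beta_a - beta_b) / np.sqrt(se_a**2 + se_b**2)
    return HetTest(beta_a, se_a, beta_b, se_b, float(z), float(2.0 * norm.sf(abs(z))))


def effect_correlation(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    variant_subset: list[str] | None = None,
) -> dict:
    """Pearson correlation of harmonized effect vectors.

    Variants are matched on (chrom, pos); when the ref/alt alleles are
    swapped between the two tables the second beta is flipped.  Variants
    with mismatched or strand-ambiguous (A/T, C/G) allele pairs are
    dropped with a note in the output.
    """
    required = {"variant_id", "chrom", "pos", "ref", "alt", "beta"}
    for df, name in ((stats_a, "a"), (stats_b, "b")):
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"stats_{name} missing columns {sorted(missing)}")
    a = stats_a.set_index(["chrom", "pos"])
    b = stats_b.set_index(["chrom", "pos"])
    shared = a.index.intersection(b.index)
    betas_a, betas_b, used, dropped = [], [], [], []
    for key in shared:
        ra, rb = a.loc[key], b.loc[key]
        if variant_subset is not None and ra["variant_id"] not in variant_subset:
            continue
        if (str(ra["ref"]), str(ra["alt"])) in AMBIGUOUS_PAIRS:
            dropped.append(ra["variant_id"])
            continue
        if (ra["ref"], ra["alt"]) == (rb["ref"], rb["alt"]):
            flip = 1.0
        elif (ra["ref"], ra["alt"]) == (rb["alt"], rb["ref"]):
            flip = -1.0
        else:
            dropped.append(ra["variant_id"])
            continue
        betas_a.append(float(ra["beta"]))
        betas_b.append(flip * float(rb["beta"]))
        used.append(ra["variant_id"])
    if len(used) < 3:
        raise ValueError("need at least 3 shared, harmonizable variants")
    va = np.array(betas_a)
    vb = np.array(betas_b)
    r = float(np.corrcoef(va, vb)[0, 1])
    signs = np.sign(va) == np.sign(vb)
    table = pd.DataFrame({"variant_id": used, "beta_a": va, "beta_b": vb,
                          "sign_concordant": signs})
    return {
        "pearson_r": r,
        "n_shared": len(used),
        "n_concordant": int(signs.sum()),
        "n_discordant": int((~signs).sum()),
        "dropped": dropped,
        "table": table,
    }


def risk_allele_freq(n_hom_risk: int, n_het: int, n_total: int) -> float:
    """(2 x risk homozygotes + heterozygotes) / (2 x total individuals)."""
    if n_total == 0:
        raise ValueError("n_total must be positive")
    if n_hom_risk + n_het > n_total:
        raise ValueError("carrier counts exceed total")
    return (2 * n_hom_risk + n_het) / (2 * n_total)


@dataclass
class PowerInput:
    n_cases: int
    n_controls: int
    risk_genotype_freq_controls: float
    odds_ratio: float
    alpha: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.risk_genotype_freq_controls < 1.0:
            raise ValueError("control genotype frequency must be in (0,1)")
        if self.odds_ratio <= 0:
            raise ValueError("odds ratio must be > 0")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")


def power_two_proportion(
    inp: PowerInput, pooled_null_se: bool = True, method: str = "normal"
) -> float:
    """Power of the two-sided two-proportion z-test for a difference in
    high-risk genotype frequency between cases and controls.

    The case-group frequency follows from the control frequency p0 by the
    exact odds transform p1 = OR*p0 / (1 - p0 + OR*p0).  With
    ``method="normal"`` (default) the usual closed form is returned: the
    rejection threshold uses the pooled-proportion SE under the null
    (switchable to all-unpooled) and both tails are integrated under a
    normal alternative.  With ``method="exact"`` the rejection
    probability of the pooled z-test is computed by enumerating the
    binomial count distributions directly — preferable when one group is
    small (tens of cases), where the normal approximation to the count
    distribution can be off by a few percent.
    """
    p0 = inp.risk_genotype_freq_controls
    p1 = inp.odds_ratio * p0 / (1.0 - p0 + inp.odds_ratio * p0)
    n1, n0 = inp.n_cases, inp.n_controls
    z_crit = norm.ppf(1 - inp.alpha / 2)
    if method == "exact":
        return _power_exact(n1, n0, p1, p0, z_crit)
    if method != "normal":
        raise ValueError("method must be 'normal' or 'exact'")
    se_alt = np.sqrt(p1 * (1 - p1) / n1 + p0 * (1 - p0) / n0)
    if pooled_null_se:
        pbar = (n1 * p1 + n0 * p0) / (n1 + n0)
        se_null = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
    else:
        se_null = se_alt
    if se_alt == 0:
        return 1.0
    delta = abs(p1 - p0)
    power = norm.cdf((delta - z_crit * se_null) / se_alt) + norm.cdf(
        (-delta - z_crit * se_null) / se_alt
    )
    return float(power)


def _power_exact(n1: int, n0: int, p1: float, p0: float, z_crit: float) -> float:
    """Exact rejection probability of the pooled two-proportion z-test,
    by summation over both binomial count distributions."""
    from scipy.stats import binom

    x0 = np.arange(n0 + 1)
    pmf0 = binom.pmf(x0, n0, p0)
    ph0 = x0 / n0
    total = 0.0
    pmf1 = binom.pmf(np.arange(n1 + 1), n1, p1)
    for x1 in range(n1 + 1):
        ph1 = x1 / n1
        pbar = (x1 + x0) / (n1 + n0)
        se = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n0))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = np.where(se > 0, (ph1 - ph0) / se, 0.0)
        total += pmf1[x1] * pmf0[np.abs(z) > z_crit].sum()
    return float(total)
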