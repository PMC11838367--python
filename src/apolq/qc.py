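"""Genotype quality control.

Variant-level filters (imputation INFO score, minor allele count), the
exact conditional Hardy-Weinberg test, imputed-versus-sequenced
concordance checks specialised to the G1/G2 haplotype structure, and
randomized greedy relatedness pruning.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2


@dataclass
class QCThresholds:
    info_min: float = 0.6
    mac_min: int = 10
    kinship_max: float = 0.125
    hwe_report_only: bool = True

    def __post_init__(self):
        if not 0.0 <= self.info_min <= 1.0:
            raise ValueError("info_min must be in [0,1]")
        if self.mac_min < 0:
            raise ValueError("mac_min must be >= 0")


def filter_variants(
    dosages: pd.DataFrame,
    info: dict[str, float] | pd.Series | None = None,
    thresholds: QCThresholds | None = None,
) -> list[str]:
    """Variants passing MAC and (where an INFO score exists) INFO filters.

    Variants without an INFO entry are treated as directly sequenced and
    only MAC-filtered.  Missing genotypes are excluded pairwise from the
    allele counts.
    """
    thresholds = thresholds or QCThresholds()
    if info is None:
        info = {}
    elif isinstance(info, pd.Series):
        info = info.to_dict()
    kept = []
    for v in dosages.columns:
        col = dosages[v].to_numpy(dtype=float)
        ok = ~np.isnan(col)
        alt = col[ok].sum()
        mac = min(alt, 2 * ok.sum() - alt)
        if mac < thresholds.mac_min:
            continue
        score = info.get(v)
        if score is not None and score < thresholds.info_min:
            continue
        kept.append(v)
    return kept


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    P-value is the summed probability of all heterozygote counts (with the
    same allele counts) whose conditional probability does not exceed that
    of the observed count.  The conditional distribution of the het count
    given allele counts is evaluated in log space, so extreme deviations at
    large n are handled without underflow.
    """
    counts = (n_hom_ref, n_het, n_hom_alt)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_ref + n_het, 2 * n_hom_alt + n_het)
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    homr = (n_rare - hets) // 2
    homc = n - hets - homr
    # log P(het | allele counts) up to a constant
    logp = (
        hets * np.log(2.0)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
    )
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = np.searchsorted(hets, n_het)
    p_obs = p[obs]
    return float(min(1.0, p[p <= p_obs * (1 + 1e-12)].sum()))


def hwe_chi2_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-df chi-square Hardy-Weinberg test (provided for comparison; the
    exact test is the default and is reliable at extreme deviations)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        raise ValueError("at least one genotype required")
    p = (2 * n_hom_ref + n_het) / (2 * n)
    q = 1 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    if np.any(exp == 0):
        return 1.0
    stat = ((obs - exp) ** 2 / exp).sum()
    return float(chi2.sf(stat, 1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    ok = ~np.isnan(col)
    c = col[ok]
    return int((c == 0).sum()), int((c == 1).sum()), int((c == 2).sum())


@dataclass
class ConcordanceReport:
    het_in_truth: dict[str, int] = field(default_factory=dict)
    het_truth_called_hom: dict[str, int] = field(default_factory=dict)
    discordant_pairs: int = 0
    impossible_combo_count: int = 0
    hwe_p_truth: dict[str, float] = field(default_factory=dict)
    hwe_p_test: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v in self.het_in_truth:
            rows.append(
                {
                    "variant_id": v,
                    "het_in_truth": self.het_in_truth[v],
                    "het_truth_called_hom": self.het_truth_called_hom[v],
                    "hwe_p_truth": self.hwe_p_truth[v],
                    "hwe_p_test": self.hwe_p_test[v],
                }
            )
        return pd.DataFrame(rows)


def concordance(
    truth: pd.DataFrame,
    test: pd.DataFrame,
    g1m: str,
    g1g: str,
    g2: str,
) -> ConcordanceReport:
    """Compare a trusted genotype matrix against a test (e.g. imputed) one.

    Counts het-in-truth samples called homozygous in the test matrix,
    samples with discordant G1M/G1G genotypes (the two sites ride on one
    haplotype class, so their genotypes should agree), and impossible
    G1-homozygous-with-G2-carrier combinations, which mutual exclusion of
    G1 and G2 haplotypes forbids.
    """
    if list(truth.index) != list(test.index):
        raise ValueError("truth and test matrices must cover the same samples")
    rep = ConcordanceReport()
    for v in (g1m, g1g, g2):
        t = truth[v].to_numpy(dtype=float)
        s = test[v].to_numpy(dtype=float)
        het = t == 1
        rep.het_in_truth[v] = int(het.sum())
        rep.het_truth_called_hom[v] = int((het & ((s == 0) | (s == 2))).sum())
        rep.hwe_p_truth[v] = hwe_exact_test(*_genotype_counts(t))
        rep.hwe_p_test[v] = hwe_exact_test(*_genotype_counts(s))
    tm = test[g1m].to_numpy(dtype=float)
    tg = test[g1g].to_numpy(dtype=float)
    t2 = test[g2].to_numpy(dtype=float)
    rep.discordant_pairs = int((tm != tg).sum())
    rep.impossible_combo_count = int(
        (((tm == 2) | (tg == 2)) & (t2 >= 1)).sum() + ((t2 == 2) & ((tm >= 1) | (tg >= 1))).sum()
    )
    return rep


def prune_related(
    pairs: list[tuple[str, str, float]],
    threshold: float = 0.125,
    seed: int = 0,
) -> set[str]:
    """Randomized greedy relatedness pruning.

    Qualifying pairs (kinship above threshold) are visited in seeded random
    order; whenever both members are still present one of them, chosen
    uniformly at random, is removed.  No qualifying pair survives intact.
    This deliberately mirrors a light-touch "drop one per pair" filter, not
    a minimum vertex cover.
    """
    for _, _, pi in pairs:
        if not 0.0 <= pi <= 1.0:
            raise ValueError("pi_hat must be in [0,1]")
    qualifying = [(a, b) for a, b, pi in pairs if pi > threshold]
    rng = random.Random(seed)
    rng.shuffle(qualifying)
    removed: set[str] = set()
    for a, b in qualifying:
        if a in removed or b in removed:
            continue
        removed.add(a if rng.random() < 0.5 else b)
    return removed
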