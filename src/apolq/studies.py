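"""Replication-style simulation studies.

Each function simulates cohorts whose generating parameters are the
published effect estimates, runs the corresponding estimator from this
package, and returns the recovered quantity.  They are the package's
end-to-end exercises: parameter recovery here demonstrates that the
estimators measure what the generative model encodes, at the cohort
sizes of the original studies.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .assoc import assoc_scan
from .finemap import FinemapConfig, enumerate_posterior, posterior_effect
from .gxg import stratified_contrast
from .peptides import CALL_DOSAGE, infer_g1g2_from_peptides
from .simulate import (
    TRANS_FREQS,
    EffectSpec,
    KKSSpec,
    afr_stratified_spec,
    afr_table2_spec,
    build_default_pool,
    default_peptide_spec,
    eur_table2_spec,
    healthabc_spec,
    simulate_cohort,
    simulate_measurements,
    simulate_peptides,
)

G2_ID = "rs71785313"
G1M_ID = "rs60910145"
V1_ID = "rs2239785"


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate sub-seeds below 2^31."""
    return np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32) >> 1


def finemap_posterior_g2(
    n_reps: int = 50, n: int = 828, seed: int = 0, max_k: int = 3
) -> float:
    """Mean fine-mapped posterior per-allele G2 effect (raw NPX) on the
    Olink channel across simulated African-ancestry cohorts whose
    generating cis effects are the published Olink estimates."""
    pool = build_default_pool("AFR")
    spec = afr_table2_spec()
    seeds = _sub_seeds(seed, 2 * n_reps)
    vals = []
    for r in range(n_reps):
        cohort = simulate_cohort(pool, n, TRANS_FREQS["AFR"], seed=int(seeds[2 * r]))
        meas, _ = simulate_measurements(cohort, spec, ("Olink",), seed=int(seeds[2 * r + 1]))
        y = meas["Olink"].data["APOL1"].to_numpy()
        dos = cohort.dosage_matrix([v.variant_id for v in cohort.pool.panel])
        dos = dos.loc[:, dos.std() > 0]
        res = enumerate_posterior(dos, y, None, FinemapConfig(max_k=max_k))
        vals.append(posterior_effect(res, G2_ID))
    return float(np.mean(vals))


def stratified_g1g2(
    n_reps: int = 200, n: int = 828, seed: int = 0
) -> tuple[float, float]:
    """Mean stratified Olink estimates across simulated AFR cohorts with
    the published stratum effects: (G2 effect in the G1-absent stratum,
    G1 effect in the G2-heterozygote stratum)."""
    pool = build_default_pool("AFR")
    spec = afr_stratified_spec()
    seeds = _sub_seeds(seed, 2 * n_reps)
    b_g2_no_g1, b_g1_in_g2 = [], []
    for r in range(n_reps):
        cohort = simulate_cohort(pool, n, TRANS_FREQS["AFR"], seed=int(seeds[2 * r]))
        meas, _ = simulate_measurements(cohort, spec, ("Olink",), seed=int(seeds[2 * r + 1]))
        y = meas["Olink"].data["APOL1"].to_numpy()
        sc_g2 = stratified_contrast(cohort.dosage("G2"), cohort.dosage("G1M"), y,
                                    carrier_rule="het_only")
        sc_g1 = stratified_contrast(cohort.dosage("G1M"), cohort.dosage("G2"), y,
                                    carrier_rule="het_only")
        b_g2_no_g1.append(sc_g2.beta1)
        b_g1_in_g2.append(sc_g1.beta2)
    return float(np.mean(b_g2_no_g1)), float(np.mean(b_g1_in_g2))


def soma_g2_marginal(n_reps: int = 100, n: int = 461, seed: int = 0) -> float:
    """Mean marginal per-allele G2 effect on the SomaLogic channel across
    simulated AASK-sized AFR cohorts (published aptamer epitope effect is
    negative)."""
    pool = build_default_pool("AFR")
    spec = afr_table2_spec()
    seeds = _sub_seeds(seed, 2 * n_reps)
    vals = []
    for r in range(n_reps):
        cohort = simulate_cohort(pool, n, TRANS_FREQS["AFR"], seed=int(seeds[2 * r]))
        meas, _ = simulate_measurements(cohort, spec, ("SomaLogic",),
                                        seed=int(seeds[2 * r + 1]))
        y = meas["SomaLogic"].data["APOL1"].to_numpy()
        rec = assoc_scan(cohort.dosage_matrix([G2_ID]), y)[0]
        vals.append(rec.beta_raw)
    return float(np.mean(vals))


def peptide_pipeline_beta(
    n_reps: int = 100,
    n_afr: int = 194,
    n_eur: int = 366,
    seed: int = 0,
    pep_noise_sd: float = 0.3,
) -> float:
    """End-to-end peptide pipeline: simulate a mixed cohort, train the L1
    predictor of the G1/G2-spanning peptide on the European samples, call
    African-ancestry genotypes, and regress the Olink channel on the
    inferred carrier dosage.  Returns the mean recovered per-allele
    carrier effect."""
    pool_a = build_default_pool("AFR")
    pool_e = build_default_pool("EUR")
    spec = healthabc_spec()
    pspec = default_peptide_spec(spec.baseline_mu, pep_noise_sd)
    seeds = _sub_seeds(seed, 6 * n_reps)
    betas = []
    for r in range(n_reps):
        s = seeds[6 * r : 6 * r + 6]
        ca = simulate_cohort(pool_a, n_afr, TRANS_FREQS["AFR"], seed=int(s[0]),
                             sample_prefix="A")
        ce = simulate_cohort(pool_e, n_eur, TRANS_FREQS["EUR"], seed=int(s[1]),
                             sample_prefix="E")
        ma, Ta = simulate_measurements(ca, spec, ("Olink",), seed=int(s[2]))
        _, Te = simulate_measurements(ce, spec, ("Olink",), seed=int(s[3]))
        pa = simulate_peptides(ca, pspec, Ta, seed=int(s[4]))
        pe = simulate_peptides(ce, pspec, Te, seed=int(s[5]))
        combined = pd.concat([pe.data, pa.data])
        calls, _ = infer_g1g2_from_peptides(combined, list(pe.data.index),
                                            list(pa.data.index))
        d_hat = calls["call"].map(CALL_DOSAGE).to_numpy(float)
        y = ma["Olink"].data["APOL1"].to_numpy()
        X = np.column_stack([np.ones(len(y)), d_hat])
        betas.append(np.linalg.lstsq(X, y, rcond=None)[0][1])
    return float(np.mean(betas))


def eur_v1_effect(platform: str, n: int, seed: int = 0) -> float:
    """Marginal per-G-allele (reference orientation) V1 effect in one
    large simulated European cohort on the requested platform."""
    pool = build_default_pool("EUR")
    spec = eur_table2_spec()
    seeds = _sub_seeds(seed, 2)
    cohort = simulate_cohort(pool, n, TRANS_FREQS["EUR"], seed=int(seeds[0]))
    meas, _ = simulate_measurements(cohort, spec, (platform,), seed=int(seeds[1]))
    y = meas[platform].data["APOL1"].to_numpy()
    rec = assoc_scan(cohort.dosage_matrix([V1_ID]), y, report_ref_allele=[V1_ID])[0]
    return float(rec.beta_raw)


def correlation_spec(target_r: float = 0.39) -> EffectSpec:
    """Effect spec with no genetic effects and platform noise solved so the
    model-implied Olink-MS correlation sigma_T^2/(sigma_T^2+sigma^2)
    equals ``target_r`` at sigma_T = 1."""
    sigma = float(np.sqrt(1.0 / target_r - 1.0))
    return EffectSpec(
        epitope_effects={"Olink": {}, "MS": {}},
        v2_effect_on_T=0.0,
        hpr_effect_on_T=0.0,
        shared_T_sd=1.0,
        noise_sd={"Olink": sigma, "MS": sigma},
        kks=KKSSpec(lof_penalty={}, kng1_cofactor=0.0, olink_gain=0.0),
    )


def olink_ms_correlation(
    n_reps: int = 200, n: int = 560, seed: int = 0, target_r: float = 0.39
) -> tuple[float, float]:
    """Sample Olink-MS Pearson correlations under the calibrated-noise
    model; returns (mean R, fraction of replicates within +/-0.10 of the
    target)."""
    pool = build_default_pool("AFR")
    spec = correlation_spec(target_r)
    seeds = _sub_seeds(seed, 2 * n_reps)
    rs = []
    for r in range(n_reps):
        cohort = simulate_cohort(pool, n, {}, seed=int(seeds[2 * r]))
        meas, _ = simulate_measurements(cohort, spec, ("Olink", "MS"),
                                        seed=int(seeds[2 * r + 1]))
        rs.append(np.corrcoef(meas["Olink"].data["APOL1"],
                              meas["MS"].data["APOL1"])[0, 1])
    rs = np.array(rs)
    return float(rs.mean()), float(np.mean(np.abs(rs - target_r) <= 0.10))


def realized_v1_freq(n: int = 50_000, seed: int = 0) -> float:
    """Realized V1 alternative-allele frequency in one simulated European
    cohort drawn from the default pool."""
    pool = build_default_pool("EUR")
    cohort = simulate_cohort(pool, n, {}, seed=int(_sub_seeds(seed, 1)[0]))
    return float(cohort.dosage("V1").mean() / 2.0)
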