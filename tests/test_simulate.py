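"""Generator tests: allele frequencies, haplotype structure, platform
effect model, peptide layer, and imputation-artifact injection."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom

from apolq.simulate import (
    TRANS_FREQS,
    EffectSpec,
    HaplotypePool,
    KKSSpec,
    VariantDef,
    afr_table2_spec,
    build_default_pool,
    corrupt_imputation,
    default_peptide_spec,
    simulate_cohort,
    simulate_measurements,
    simulate_peptides,
)

EXPECTED_FREQS = {
    "AFR": {"G1M": 0.22, "G1G": 0.22, "G2": 0.14, "M1": 0.03, "V1": 0.35, "V2": 0.16},
    "EUR": {"V1": 0.81, "V2": 0.11},
}


@pytest.mark.parametrize("ancestry", ["AFR", "EUR"])
def test_pool_marginal_frequencies(ancestry, afr_pool, eur_pool):
    pool = afr_pool if ancestry == "AFR" else eur_pool
    mf = pool.marginal_frequencies()
    by_label = {v.label: mf[v.variant_id] for v in pool.panel}
    for label, expected in EXPECTED_FREQS[ancestry].items():
        assert by_label[label] == pytest.approx(expected, abs=1e-6)
    if ancestry == "EUR":
        assert by_label["G1M"] < 1e-3 and by_label["G2"] < 1e-3


def test_pool_has_ld_proxies(afr_pool):
    """At least 10 background variants, with proxies of G1/G2/V1 in
    substantial haplotype-level LD (0 < r < 1)."""
    pool = afr_pool
    bg = [v for v in pool.panel if v.role == "cis_background"]
    assert len(bg) >= 10
    H, f = pool.haplotypes.astype(float), pool.frequencies
    mu = f @ H
    cov = (H - mu).T * f @ (H - mu)
    sd = np.sqrt(np.diag(cov))
    corr = cov / np.outer(sd, sd)
    for causal in ("G1M", "G2", "V1"):
        i = pool.index_of(causal)
        proxies = [abs(corr[i, pool.index_of(v.variant_id)]) for v in bg]
        best = max(proxies)
        assert 0.5 < best < 1.0 - 1e-9, f"no partial-LD proxy for {causal}"


@pytest.mark.parametrize("ancestry", ["AFR", "EUR"])
def test_mutual_exclusion_in_pool(ancestry, afr_pool, eur_pool):
    pool = afr_pool if ancestry == "AFR" else eur_pool
    g1 = pool.haplotypes[:, pool.index_of("G1M")]
    g2 = pool.haplotypes[:, pool.index_of("G2")]
    assert int(np.max(g1 * g2)) == 0


def test_pool_invariant_rejects_g1_g2_cooccurrence():
    panel = [
        VariantDef("a", "22", 1, "A", "G", "cis_coding", "G1M"),
        VariantDef("b", "22", 2, "A", "G", "cis_coding", "G2"),
    ]
    with pytest.raises(ValueError, match="never co-occur"):
        HaplotypePool(panel, np.array([[1, 1]]), np.array([1.0]))


def test_degenerate_single_haplotype_pool():
    panel = [VariantDef(f"v{i}", "22", i + 1, "A", "G", "cis_background") for i in range(3)]
    pool = HaplotypePool(panel, np.array([[1, 0, 1]]), np.array([1.0]))
    cohort = simulate_cohort(pool, 5, seed=0)
    assert (cohort.dosage("v0") == 2).all()
    assert (cohort.dosage("v1") == 0).all()
    assert (cohort.dosage("v2") == 2).all()


def test_sample_frequencies_converge(afr_pool):
    """Realized frequencies at n=50,000 match pool marginals within 3
    binomial SDs (and G2 within +/-0.005 of 0.14)."""
    cohort = simulate_cohort(afr_pool, 50_000, TRANS_FREQS["AFR"], seed=42)
    mf = afr_pool.marginal_frequencies()
    dos = cohort.dosage_matrix([v.variant_id for v in afr_pool.panel])
    realized = dos.mean() / 2.0
    sds = np.sqrt(mf * (1 - mf) / (2 * 50_000))
    assert (np.abs(realized - mf) <= 3 * sds + 1e-12).all()
    assert abs(realized["rs71785313"] - 0.14) < 0.005


def test_g1_g2_negative_ld(afr_pool):
    """Mutual exclusion implies negative dosage correlation, matching the
    haplotype-frequency closed form r = -sqrt(p1 p2 / ((1-p1)(1-p2)))."""
    cohort = simulate_cohort(afr_pool, 50_000, seed=7)
    r = np.corrcoef(cohort.dosage("G1M"), cohort.dosage("G2"))[0, 1]
    p1, p2 = 0.22, 0.14
    expected = -np.sqrt(p1 * p2 / ((1 - p1) * (1 - p2)))
    assert r < 0
    assert r == pytest.approx(expected, abs=0.02)


def test_seeded_determinism(afr_pool):
    spec = afr_table2_spec()
    out = []
    for _ in range(2):
        c = simulate_cohort(afr_pool, 200, TRANS_FREQS["AFR"], seed=5)
        meas, T = simulate_measurements(c, spec, seed=6)
        peps = simulate_peptides(c, default_peptide_spec(), T, seed=7)
        out.append((c.hap_index_pairs, meas["Olink"].data, peps.data))
    assert np.array_equal(out[0][0], out[1][0])
    pd.testing.assert_frame_equal(out[0][1], out[1][1])
    pd.testing.assert_frame_equal(out[0][2], out[1][2])


def test_degenerate_noise_platforms_identical(afr_pool):
    spec = EffectSpec(
        epitope_effects={"Olink": {}, "SomaLogic": {}, "MS": {}},
        kks=KKSSpec(lof_penalty={}, kng1_cofactor=0.0, olink_gain=0.0),
        noise_sd={"Olink": 0.0, "SomaLogic": 0.0, "MS": 0.0},
        shared_T_sd=0.0,
        v2_effect_on_T=0.3,
    )
    c = simulate_cohort(afr_pool, 100, seed=1)
    meas, T = simulate_measurements(c, spec, seed=2)
    np.testing.assert_allclose(meas["Olink"].data["APOL1"], meas["MS"].data["APOL1"])
    np.testing.assert_allclose(meas["SomaLogic"].data["APOL1"], meas["MS"].data["APOL1"])


def test_epitope_effects_recovered_by_ols(afr_pool):
    """Per-allele G2 slopes at n=20,000 recover +1.33 (Olink), -0.44
    (SomaLogic) and ~0 (MS)."""
    spec = afr_table2_spec()
    c = simulate_cohort(afr_pool, 20_000, TRANS_FREQS["AFR"], seed=11)
    meas, _ = simulate_measurements(c, spec, seed=12)
    d = c.dosage("G2")
    X = np.column_stack([np.ones(len(d)), d, c.dosage("G1M")])
    slopes = {}
    for p in ("Olink", "SomaLogic", "MS"):
        y = meas[p].data["APOL1"].to_numpy()
        slopes[p] = np.linalg.lstsq(X, y, rcond=None)[0][1]
    assert slopes["Olink"] == pytest.approx(1.33, abs=0.06)
    assert slopes["SomaLogic"] == pytest.approx(-0.44, abs=0.06)
    assert abs(slopes["MS"]) < 0.05


def test_platform_sign_pattern(afr_pool):
    """Marginal G2 slopes: positive on Olink, negative on SomaLogic, and
    indistinguishable from zero on MS at n=5,000."""
    spec = afr_table2_spec()
    c = simulate_cohort(afr_pool, 5_000, TRANS_FREQS["AFR"], seed=21)
    meas, _ = simulate_measurements(c, spec, seed=22)
    d = c.dosage("G2")
    X = np.column_stack([np.ones(len(d)), d])
    XtXinv = np.linalg.inv(X.T @ X)
    for p, check in (("Olink", "pos"), ("SomaLogic", "neg"), ("MS", "null")):
        y = meas[p].data["APOL1"].to_numpy()
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        resid = y - X @ beta
        se = np.sqrt(XtXinv[1, 1] * resid @ resid / (len(y) - 2))
        if check == "pos":
            assert beta[1] > 0
        elif check == "neg":
            assert beta[1] < 0
        else:
            assert abs(beta[1]) < 2 * se


def test_kks_full_lof_abolishes_partner_effect(afr_pool):
    """With lambda_F12 = 1, the Olink-KLKB1 slope within the F12
    LOF-homozygote stratum is ~0."""
    spec = afr_table2_spec()
    spec.kks = KKSSpec(lof_penalty={"F12": 1.0, "KLKB1": 0.9}, kng1_cofactor=0.0,
                       olink_gain=1.0)
    spec.noise_sd["Olink"] = 0.3
    c = simulate_cohort(afr_pool, 30_000, TRANS_FREQS["AFR"], seed=31)
    meas, _ = simulate_measurements(c, spec, ("Olink",), seed=32)
    y = meas["Olink"].data["APOL1"].to_numpy()
    d_f12_lof = 2.0 - c.dosage("F12")
    d_klkb1_lof = 2.0 - c.dosage("KLKB1")
    hom = d_f12_lof == 2
    X = np.column_stack([np.ones(hom.sum()), d_klkb1_lof[hom]])
    slope = np.linalg.lstsq(X, y[hom], rcond=None)[0][1]
    assert abs(slope) < 0.03


class TestPeptides:
    def _cohort(self, afr_pool, n=400, seed=3):
        return simulate_cohort(afr_pool, n, seed=seed)

    def test_compound_het_gives_exact_zero(self, afr_pool):
        c = self._cohort(afr_pool, 2000)
        spec = default_peptide_spec()
        T = np.full(c.n, 3.0)
        peps = simulate_peptides(c, spec, T, seed=4).data
        haps = c.haplotype_alleles()
        r = ((haps[:, :, c.pool.index_of("G1M")] == 0)
             & (haps[:, :, c.pool.index_of("G2")] == 0)).sum(axis=1)
        assert (r == 0).any(), "cohort should contain compound carriers"
        assert (peps.loc[r == 0, "LNILNNNYK"] == 0.0).all()
        assert (peps.loc[r > 0, "LNILNNNYK"] != 0.0).all()

    def test_v1_allele_specific_construction(self, afr_pool):
        c = self._cohort(afr_pool)
        spec = default_peptide_spec(pep_noise_sd=0.0)
        T = np.full(c.n, 3.0)
        peps = simulate_peptides(c, spec, T, seed=5).data
        d_v1 = c.dosage("V1")
        homref = d_v1 == 0
        j = spec.peptide_ids.index("SELEDNIRR")
        assert (peps.loc[homref, "LEDNIRR"] == 0.0).all()
        np.testing.assert_allclose(peps.loc[homref, "SELEDNIRR"], 3.0 + spec.offsets[j])

    def test_single_vs_double_copy_differ_by_one_log2_unit(self, afr_pool):
        c = self._cohort(afr_pool, 2000)
        spec = default_peptide_spec(pep_noise_sd=0.0)
        T = np.full(c.n, 3.0)
        peps = simulate_peptides(c, spec, T, seed=6).data
        d_v1 = c.dosage("V1")
        v_het = peps.loc[d_v1 == 1, "SELEDNIRR"].iloc[0]
        v_hom = peps.loc[d_v1 == 0, "SELEDNIRR"].iloc[0]
        assert v_hom - v_het == pytest.approx(1.0, abs=1e-12)

    def test_required_peptides_enforced(self):
        with pytest.raises(ValueError, match="LNILNNNYK"):
            from apolq.simulate import PeptideSpec

            PeptideSpec(["SELEDNIRR", "LEDNIRR"], np.zeros(2))


class TestCorruptImputation:
    def test_rate_zero_is_identity(self, afr_pool):
        c = simulate_cohort(afr_pool, 500, seed=8)
        truth = c.dosage_matrix([v.variant_id for v in afr_pool.panel])
        pd.testing.assert_frame_equal(corrupt_imputation(c, 0.0, seed=9), truth)

    def test_rate_one_saturates(self, afr_pool):
        c = simulate_cohort(afr_pool, 500, seed=8)
        out = corrupt_imputation(c, 1.0, seed=9)
        assert (out["rs60910145"] != 1).all()
        assert (out["rs73885319"] != 1).all()

    def test_corruption_count_within_binomial_interval(self, afr_pool):
        """At rate 0.2 the number of converted het calls falls in the
        binomial 99% interval (the published artifact was 73 of 351)."""
        c = simulate_cohort(afr_pool, 1000, seed=10)
        truth = c.dosage("G1M")
        out = corrupt_imputation(c, 0.2, seed=11)
        n_het = int((truth == 1).sum())
        converted = int(((truth == 1) & (out["rs60910145"] == 2)).sum())
        lo, hi = binom.ppf([0.005, 0.995], n_het, 0.2)
        assert lo <= converted <= hi
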