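"""Seeded end-to-end orchestration: simulate -> qc -> scan -> finemap ->
gxg -> peptides -> compare.

One top-level seed deterministically derives a sub-seed per stage (by
hashing the stage name), so adding or dropping a stage never perturbs the
randomness of the others, and re-running an identical configuration
reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, finemap as fm, gxg as gxg_mod, io, peptides as pep, platform as plat
from . import qc as qc_mod
from .simulate import (
    TRANS_FREQS,
    EffectSpec,
    afr_stratified_spec,
    afr_table2_spec,
    build_default_pool,
    default_peptide_spec,
    eur_table2_spec,
    healthabc_spec,
    simulate_cohort,
    simulate_covariates,
    simulate_measurements,
    simulate_peptides,
)

log = logging.getLogger("apolq")

STAGE_ORDER = ["simulate", "qc", "scan", "finemap", "gxg", "peptides", "compare"]

EFFECT_PROFILES = {
    "afr_table2": afr_table2_spec,
    "afr_stratified": afr_stratified_spec,
    "eur_table2": eur_table2_spec,
    "healthabc": healthabc_spec,
}

CONFIG_KEYS = {
    "ancestry",
    "n_samples",
    "effect_profile",
    "seed",
    "output_dir",
    "stages",
    "qc",
    "finemap",
    "n_reference_eur",
}


@dataclass
class RunConfig:
    ancestry: str = "AFR"
    n_samples: int = 828
    effect_profile: str = "afr_table2"
    seed: int = 0
    output_dir: str = "apolq_run"
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    qc: qc_mod.QCThresholds = field(default_factory=qc_mod.QCThresholds)
    finemap: fm.FinemapConfig = field(default_factory=fm.FinemapConfig)
    n_reference_eur: int = 366  # EUR panel size for peptide-based inference

    def __post_init__(self):
        if self.ancestry not in ("AFR", "EUR"):
            raise ValueError("ancestry must be AFR or EUR")
        if self.effect_profile not in EFFECT_PROFILES:
            raise ValueError(f"unknown effect profile {self.effect_profile!r}")
        if self.stages != STAGE_ORDER[: len(self.stages)]:
            raise ValueError(
                f"stages must be a prefix of {STAGE_ORDER}, got {self.stages}"
            )
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = io.load_yaml_config(path, CONFIG_KEYS)
        qc_raw = raw.pop("qc", {})
        fm_raw = raw.pop("finemap", {})
        return cls(
            qc=qc_mod.QCThresholds(**qc_raw),
            finemap=fm.FinemapConfig(**fm_raw),
            **raw,
        )


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage sub-seed below 2^31."""
    return (zlib.crc32(f"{stage}:{seed}".encode()) ^ seed) & 0x7FFFFFFF


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stage prefix, returning a manifest of outputs
    (file, stage, checksum, seed)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    spec: EffectSpec = EFFECT_PROFILES[config.effect_profile]()
    state: dict = {}

    def record(stage: str, path: Path):
        manifest.append(
            {
                "file": str(path),
                "stage": stage,
                "sha256": _sha256(path),
                "seed": stage_seed(config.seed, stage),
            }
        )

    for stage in config.stages:
        seed = stage_seed(config.seed, stage)
        if stage == "simulate":
            pool = build_default_pool(config.ancestry)
            cohort = simulate_cohort(
                pool, config.n_samples, TRANS_FREQS[config.ancestry], seed=seed
            )
            meas, T = simulate_measurements(cohort, spec, seed=seed + 1)
            pspec = default_peptide_spec(spec.baseline_mu)
            peps = simulate_peptides(cohort, pspec, T, seed=seed + 2)
            cov = simulate_covariates(cohort.n, seed=seed + 3)
            cov.index = pd.Index(cohort.sample_ids)
            state.update(cohort=cohort, meas=meas, T=T, peps=peps, cov=cov, pspec=pspec)
            record(stage, io.write_vcf(cohort, out / "genotypes.vcf"))
            for p, ms in meas.items():
                record(stage, io.write_tsv(ms.data, out / f"{p.lower()}.tsv"))
            record(stage, io.write_tsv(peps.data, out / "peptides.tsv"))
            record(stage, io.write_tsv(cov, out / "covariates.tsv"))
            log.info("simulate: %d samples, %d cis variants", cohort.n, len(pool.panel))
            continue
        if "cohort" not in state:
            raise ValueError(f"stage {stage!r} requires upstream simulate outputs")
        cohort = state["cohort"]
        dosages = cohort.dosage_matrix([v.variant_id for v in cohort.pool.panel])
        covset = assoc.CovariateSet(
            age=state["cov"]["age"].to_numpy(), sex=state["cov"]["sex"].to_numpy()
        )
        olink = state["meas"]["Olink"].data["APOL1"].to_numpy()
        if stage == "qc":
            kept = qc_mod.filter_variants(dosages, thresholds=config.qc)
            rows = []
            for v in dosages.columns:
                counts = qc_mod._genotype_counts(dosages[v].to_numpy(float))
                rows.append(
                    {"variant_id": v, "kept": v in kept,
                     "hwe_p": qc_mod.hwe_exact_test(*counts)}
                )
            report = pd.DataFrame(rows).set_index("variant_id")
            state["kept"] = kept
            record(stage, io.write_tsv(report, out / "qc_report.tsv", "variant_id"))
            log.info("qc: kept %d of %d variants", len(kept), dosages.shape[1])
        elif stage == "scan":
            kept = state.get("kept", list(dosages.columns))
            recs = assoc.assoc_scan(dosages[kept], olink, covset)
            state["scan"] = assoc.records_to_frame(recs)
            record(stage, io.write_tsv(state["scan"].set_index("variant_id"),
                                       out / "scan_olink.tsv", "variant_id"))
            log.info("scan: %d variants tested", len(recs))
        elif stage == "finemap":
            kept = state.get("kept", list(dosages.columns))
            res = fm.enumerate_posterior(dosages[kept], olink, covset, config.finemap)
            table = pd.DataFrame(
                {"pip": res.pip, "posterior_beta_raw": res.posterior_beta_raw}
            )
            record(stage, io.write_tsv(table, out / "finemap.tsv", "variant_id"))
            record(stage, io.write_json(
                {"top_configs": [{"config": list(c), "posterior": p}
                                 for c, p in res.top_configs]},
                out / "finemap_top_configs.json"))
            log.info("finemap: max PIP %.3f", res.pip.max())
        elif stage == "gxg":
            rec = gxg_mod.interaction_test(
                cohort.dosage("KLKB1"), cohort.dosage("F12"), olink, covset,
                "rs3733402", "rs1801020", "APOL1",
            )
            try:
                sc = gxg_mod.stratified_contrast(
                    cohort.dosage("G2"), cohort.dosage("G1M"), olink, covset, "het_only"
                )
                strat = {"beta1": sc.beta1, "beta2": sc.beta2, "t": sc.t,
                         "df": sc.df, "p": sc.p}
            except ValueError as err:  # e.g. too few carriers in a EUR cohort
                strat = {"error": str(err)}
            record(stage, io.write_json(
                {"interaction": {"v1": rec.v1, "v2": rec.v2, "beta": rec.interaction_beta,
                                 "se": rec.interaction_se, "p": rec.interaction_p},
                 "stratified_G2_by_G1": strat},
                out / "gxg.json"))
        elif stage == "peptides":
            v1_calls = pep.call_v1_table(state["peps"].data)
            ref_pool = build_default_pool("EUR")
            ref = simulate_cohort(ref_pool, config.n_reference_eur,
                                  TRANS_FREQS["EUR"], seed=seed, sample_prefix="R")
            _, T_ref = simulate_measurements(ref, spec, seed=seed + 1)
            ref_peps = simulate_peptides(ref, state["pspec"], T_ref, seed=seed + 2)
            combined = pd.concat([ref_peps.data, state["peps"].data])
            calls, _ = pep.infer_g1g2_from_peptides(
                combined, list(ref_peps.data.index), list(state["peps"].data.index)
            )
            table = v1_calls.rename(columns={"call": "v1_call", "basis": "v1_basis"})
            table["g1g2_call"] = calls["call"]
            table["g1g2_basis"] = calls["basis"]
            state["pep_calls"] = table
            record(stage, io.write_tsv(table, out / "peptide_calls.tsv"))
            log.info("peptides: %d samples called", len(table))
        elif stage == "compare":
            ms = state["meas"]["MS"].data["APOL1"].to_numpy()
            g2 = dosages[[cohort.pool.panel[cohort.pool.index_of("G2")].variant_id]]
            rec_o = assoc.assoc_scan(g2, olink, covset)[0]
            rec_m = assoc.assoc_scan(g2, ms, covset)[0]
            het = plat.heterogeneity_test(rec_o.beta_raw, rec_o.se_raw,
                                          rec_m.beta_raw, rec_m.se_raw)
            r = float(np.corrcoef(olink, ms)[0, 1])
            record(stage, io.write_json(
                {"g2_olink_beta": rec_o.beta_raw, "g2_ms_beta": rec_m.beta_raw,
                 "heterogeneity_z": het.z, "heterogeneity_p": het.p,
                 "olink_ms_pearson_r": r},
                out / "compare.json"))
        else:  # pragma: no cover - guarded by RunConfig validation
            raise ValueError(f"unknown stage {stage!r}")
    io.write_json({"outputs": manifest}, out / "manifest.json")
    return {"outputs": manifest}
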