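"""File-format plumbing: VCF 4.2 genotypes, TSV tables, YAML configs,
JSON reports.  Every writer here has a matching reader so pipeline
outputs are re-readable by the modules that consume them."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .simulate import PhasedCohort

_CHROM_ORDER = {c: i for i, c in enumerate([str(k) for k in range(1, 23)] + ["X", "Y"])}


def write_vcf(cohort: PhasedCohort, path: str | Path) -> Path:
    """Write the cohort as VCF 4.2: phased GT for the cis panel, unphased
    GT for the independent trans loci."""
    path = Path(path)
    records = []
    haps = cohort.haplotype_alleles()
    for j, v in enumerate(cohort.pool.panel):
        gts = [f"{haps[i, 0, j]}|{haps[i, 1, j]}" for i in range(cohort.n)]
        records.append((v.chrom, v.pos, v.variant_id, v.ref_allele, v.alt_allele, gts))
    for name, vdef in cohort.trans_defs.items():
        dos = cohort.trans_genotypes[name]
        gts = [["0/0", "0/1", "1/1"][d] for d in dos]
        records.append((vdef.chrom, vdef.pos, vdef.variant_id, vdef.ref_allele,
                        vdef.alt_allele, gts))
    records.sort(key=lambda r: (_CHROM_ORDER.get(r[0], 99), r[1]))
    contigs = sorted({r[0] for r in records}, key=lambda c: _CHROM_ORDER.get(c, 99))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(cohort.sample_ids) + "\n")
        for chrom, pos, vid, ref, alt, gts in records:
            fh.write(f"{chrom}\t{pos}\t{vid}\t{ref}\t{alt}\t.\t.\t.\tGT\t")
            fh.write("\t".join(gts) + "\n")
    return path


def read_vcf_dosages(path: str | Path) -> pd.DataFrame:
    """Samples x variants alt-dosage matrix from GT (DS honoured when GT is
    absent); missing genotypes become NaN."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols, ids = [], []
    for rec in vcf:
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
        gts = np.array(rec.genotypes, dtype=object)
        if len(gts):
            a = np.array([[g[0], g[1]] for g in gts], dtype=float)
            a[a < 0] = np.nan
            dos = a.sum(axis=1)
        else:
            dos = np.asarray(rec.format("DS"), dtype=float).ravel()
        ids.append(vid)
        cols.append(dos)
    return pd.DataFrame(np.column_stack(cols), index=samples, columns=ids)


def write_tsv(df: pd.DataFrame, path: str | Path, index_label: str = "sample_id") -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=True, index_label=index_label, na_rep="NA")
    return path


def read_tsv(path: str | Path, index_col: int | str = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=["NA"])


def read_kinship_pairs(path: str | Path) -> list[tuple[str, str, float]]:
    """3-column TSV (idA, idB, pi_hat), no header required."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError("kinship file needs 3 columns: idA, idB, pi_hat")
    return [(str(a), str(b), float(p)) for a, b, p in df.iloc[:, :3].itertuples(index=False)]


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
    return path


def load_yaml_config(path: str | Path, allowed_keys: set[str]) -> dict:
    """YAML config loader that rejects unknown keys by name."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    unknown = set(cfg) - allowed_keys
    if unknown:
        raise ValueError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return cfg
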