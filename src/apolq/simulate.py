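"""Synthetic multi-platform pQTL cohorts at the APOL1 locus.

The generator draws phased haplotypes from an explicit pool of discrete
haplotype classes, which gives exact control over allele frequencies,
linkage-disequilibrium proxies, and the structural constraint that the
G1 and G2 kidney-risk alleles never occur on the same haplotype.  On top
of the genotypes it simulates a shared latent plasma APOL1 abundance that
three proteomic platforms (Olink, SomaLogic, mass spectrometry) observe
with platform-specific coding-variant ("epitope") artifacts, a
multiplicative kallikrein-kinin-system (KKS) activity term that only the
antibody-based Olink channel sees, and a tryptic-peptide layer with
allele-specific peptides usable for genotype inference.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

PLATFORMS = ("Olink", "SomaLogic", "MS")

#: which allele of each trans KKS locus is the (partial) loss-of-function
#: allele; trans genotypes are stored as ALT-allele dosages.
KKS_LOF_IS_ALT = {"F12": False, "KLKB1": False, "KNG1": False}


@dataclass(frozen=True)
class VariantDef:
    """One variant in the simulated panel (1-based GRCh38 coordinates)."""

    variant_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    role: str  # cis_coding | cis_regulatory | cis_background | trans_kks | trans_hpr | cn
    label: str | None = None

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


@dataclass
class HaplotypePool:
    """Discrete haplotype classes over a cis variant panel.

    ``haplotypes`` is a (n_classes, n_variants) 0/1 array (1 = alternative
    allele); ``frequencies`` are the class probabilities.
    """

    panel: list[VariantDef]
    haplotypes: np.ndarray
    frequencies: np.ndarray

    def __post_init__(self):
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        ids = [v.variant_id for v in self.panel]
        if len(set(ids)) != len(ids):
            raise ValueError("variant_id values must be unique within a panel")
        if self.haplotypes.shape != (len(self.frequencies), len(self.panel)):
            raise ValueError("haplotypes shape inconsistent with panel/frequencies")
        if (self.frequencies < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(self.frequencies.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")
        g1 = [i for i, v in enumerate(self.panel) if (v.label or "").startswith("G1")]
        g2 = [i for i, v in enumerate(self.panel) if v.label == "G2"]
        for i in g1:
            for j in g2:
                if np.any((self.haplotypes[:, i] == 1) & (self.haplotypes[:, j] == 1)):
                    raise ValueError("G1 and G2 must never co-occur on a haplotype")

    def index_of(self, key: str) -> int:
        """Panel index of a variant by label or variant_id."""
        for i, v in enumerate(self.panel):
            if v.label == key or v.variant_id == key:
                return i
        raise KeyError(f"variant {key!r} not in panel")

    def marginal_frequencies(self) -> pd.Series:
        freq = self.frequencies @ self.haplotypes
        return pd.Series(freq, index=[v.variant_id for v in self.panel])


@dataclass
class PhasedCohort:
    """Per-individual haplotype pairs plus independent trans genotypes."""

    sample_ids: list[str]
    pool: HaplotypePool
    hap_index_pairs: np.ndarray  # (n, 2) indices into pool.haplotypes
    trans_genotypes: dict[str, np.ndarray] = field(default_factory=dict)
    trans_defs: dict[str, VariantDef] = field(default_factory=dict)
    cn_values: np.ndarray | None = None

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def haplotype_alleles(self) -> np.ndarray:
        """(n, 2, m) array of phased alleles over the cis panel."""
        return self.pool.haplotypes[self.hap_index_pairs]

    def dosage(self, key: str) -> np.ndarray:
        """0/1/2 alt-allele dosage of a cis or trans variant."""
        if key in self.trans_genotypes:
            return self.trans_genotypes[key].astype(float)
        j = self.pool.index_of(key)
        haps = self.pool.haplotypes[:, j]
        return (haps[self.hap_index_pairs[:, 0]] + haps[self.hap_index_pairs[:, 1]]).astype(float)

    def dosage_matrix(self, keys: list[str] | None = None) -> pd.DataFrame:
        if keys is None:
            keys = [v.variant_id for v in self.pool.panel] + list(self.trans_genotypes)
        cols = {}
        for k in keys:
            if k in self.trans_genotypes:
                cols[k] = self.trans_genotypes[k].astype(float)
            else:
                j = self.pool.index_of(k)
                cols[self.pool.panel[j].variant_id] = self.dosage(k)
        return pd.DataFrame(cols, index=self.sample_ids)


@dataclass
class MeasurementSet:
    """Sample x analyte matrix for one platform, log-scale values."""

    platform: str
    data: pd.DataFrame


# ---------------------------------------------------------------------------
# default variant panel and haplotype pools
# ---------------------------------------------------------------------------

CIS_VARIANTS = [
    VariantDef("rs6000220", "22", 36253920, "C", "T", "cis_regulatory", "V2"),
    VariantDef("rs2239785", "22", 36265284, "G", "A", "cis_coding", "V1"),
    VariantDef("rs73885316", "22", 36265628, "C", "A", "cis_coding", "M1"),
    VariantDef("rs73885319", "22", 36265860, "A", "G", "cis_coding", "G1G"),
    VariantDef("rs60910145", "22", 36265988, "T", "G", "cis_coding", "G1M"),
    VariantDef("rs71785313", "22", 36265995, "AATAATT", "A", "cis_coding", "G2"),
]

TRANS_VARIANTS = {
    "KLKB1": VariantDef("rs3733402", "4", 186236880, "G", "A", "trans_kks", "KLKB1"),
    "F12": VariantDef("rs1801020", "5", 177409531, "A", "G", "trans_kks", "F12"),
    "KNG1": VariantDef("rs5030062", "3", 186743735, "A", "C", "trans_kks", "KNG1"),
    "HPR": VariantDef("rs9930957", "16", 72063148, "T", "C", "trans_hpr", "HPR"),
}

#: alternative-allele frequencies of the trans loci by ancestry
TRANS_FREQS = {
    "AFR": {"KLKB1": 0.74, "F12": 0.55, "KNG1": 0.30, "HPR": 0.30},
    "EUR": {"KLKB1": 0.51, "F12": 0.75, "KNG1": 0.42, "HPR": 0.30},
}


def _background_defs(n: int) -> list[VariantDef]:
    # evenly spread filler positions around the APOL1 gene body
    return [
        VariantDef(f"bg{k:02d}", "22", 36254500 + 600 * k, "A", "C", "cis_background", f"bg{k:02d}")
        for k in range(1, n + 1)
    ]


def _cross_blocks(panel: list[VariantDef], blocks) -> HaplotypePool:
    """Cross independent blocks of haplotype classes into one explicit pool.

    Each block is a list of (frequency, set-of-labels) class definitions;
    classes from different blocks combine multiplicatively.
    """
    idx = {v.label: i for i, v in enumerate(panel)}
    haps, freqs = [], []
    for combo in itertools.product(*blocks):
        f = 1.0
        vec = np.zeros(len(panel), dtype=np.int8)
        for cf, labels in combo:
            f *= cf
            for lab in labels:
                vec[idx[lab]] = 1
        if f > 0:
            haps.append(vec)
            freqs.append(f)
    freqs = np.array(freqs)
    return HaplotypePool(panel, np.array(haps), freqs / freqs.sum())


def build_default_pool(ancestry: str, g1_discordant_frac: float = 0.0) -> HaplotypePool:
    """Default haplotype pool with published allele frequencies.

    The pool carries the six annotated APOL1 variants plus 20 background
    variants; twelve of the latter tag the G1/G2 haplotype classes, four
    tag V1/V2, and four segregate independently, so that LD proxies of
    each causal variant exist.  G1M and G1G ride on the same haplotype
    class; ``g1_discordant_frac`` moves that fraction of G1 haplotypes to
    a G1M-only class to emulate imputation artifacts.
    """
    if ancestry not in ("AFR", "EUR"):
        raise ValueError("ancestry must be 'AFR' or 'EUR'")
    panel = CIS_VARIANTS + _background_defs(20)
    G1 = {"G1G", "G1M"}
    # low-frequency "leak" classes put each tagging proxy on some wild-type
    # haplotypes too, so no background variant is perfectly collinear with
    # the causal variant it tags (r < 1, as for real LD proxies)
    leak = [
        (0.02, {"bg01"}),
        (0.03, {"bg03"}),
        (0.05, {"bg04"}),
        (0.10, {"bg06"}),
        (0.02, {"bg07"}),
        (0.03, {"bg09"}),
        (0.05, {"bg10"}),
        (0.08, {"bg12"}),
        (0.62, set()),
    ]
    if ancestry == "AFR":
        core = [
            (0.16, G1 | {"bg01", "bg02", "bg03", "bg04", "bg06"}),
            (0.06, G1 | {"bg01", "bg04", "bg05"}),
            (0.10, {"G2", "bg07", "bg08", "bg09", "bg10", "bg12"}),
            (0.04, {"G2", "bg07", "bg10", "bg11"}),
            (0.64, set()),
        ]
        v1_block = [
            (0.30, {"V1", "bg13", "bg14"}),
            (0.05, {"V1", "bg13"}),
            (0.03, {"bg13"}),
            (0.62, set()),
        ]
        v2_block = [
            (0.13, {"V2", "bg15", "bg16"}),
            (0.03, {"V2", "bg15"}),
            (0.02, {"bg15"}),
            (0.82, set()),
        ]
        m1_block = [(0.03, {"M1"}), (0.97, set())]
    else:
        p_g1, p_g2 = 5.3e-5, 4.6e-5
        core = [
            (p_g1, G1 | {"bg01", "bg02", "bg03"}),
            (p_g2, {"G2", "bg07", "bg08", "bg09"}),
            (1.0 - p_g1 - p_g2, set()),
        ]
        v1_block = [
            (0.78, {"V1", "bg13", "bg14"}),
            (0.03, {"V1", "bg13"}),
            (0.02, {"bg13"}),
            (0.17, set()),
        ]
        v2_block = [
            (0.09, {"V2", "bg15", "bg16"}),
            (0.02, {"V2", "bg15"}),
            (0.02, {"bg15"}),
            (0.87, set()),
        ]
        m1_block = [(1.4e-4, {"M1"}), (1 - 1.4e-4, set())]
    indep = [
        [(0.25, {"bg17"}), (0.75, set())],
        [(0.10, {"bg18"}), (0.90, set())],
        [(0.05, {"bg19"}), (0.95, set())],
        [(0.40, {"bg20"}), (0.60, set())],
    ]
    blocks = [core, leak, v1_block, v2_block, m1_block]
    if g1_discordant_frac > 0:
        blocks[0] = [
            c
            for grp in (
                [((1 - g1_discordant_frac) * f, labs), (g1_discordant_frac * f, labs - {"G1G"})]
                if "G1M" in labs
                else [(f, labs)]
                for f, labs in core
            )
            for c in grp
        ]
    return _cross_blocks(panel, blocks + indep)


def simulate_cohort(
    pool: HaplotypePool,
    n: int,
    trans_freqs: dict[str, float] | None = None,
    seed: int = 0,
    cn_params: tuple[float, float] | None = None,
    sample_prefix: str = "S",
) -> PhasedCohort:
    """Draw a phased cohort: two i.i.d. haplotypes per individual from the
    pool, binomial(2, freq) trans genotypes, and optional Gaussian copy
    number values."""
    if len(pool.frequencies) == 0:
        raise ValueError("empty haplotype pool")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    pairs = rng.choice(len(pool.frequencies), size=(n, 2), p=pool.frequencies)
    trans, tdefs = {}, {}
    for name, f in (trans_freqs or {}).items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"trans frequency for {name} out of [0,1]")
        trans[name] = rng.binomial(2, f, size=n).astype(np.int8)
        if name in TRANS_VARIANTS:
            tdefs[name] = TRANS_VARIANTS[name]
    cn = None
    if cn_params is not None:
        cn = rng.normal(cn_params[0], cn_params[1], size=n)
    ids = [f"{sample_prefix}{i:06d}" for i in range(n)]
    return PhasedCohort(ids, pool, pairs, trans, tdefs, cn)


# ---------------------------------------------------------------------------
# effect model
# ---------------------------------------------------------------------------


@dataclass
class StratumInteraction:
    """Per-allele effect of ``target`` that depends on carrier status of
    ``modifier`` (the stratified-epistasis parameterization)."""

    modifier: str
    carrier_rule: str  # het_only | het_or_hom
    target: str
    effect_absent: float
    effect_present: float


@dataclass
class KKSSpec:
    """Multiplicative kallikrein-kinin activity: either protease gene at
    full loss of function abolishes the pathway; kininogen acts as a
    cofactor scaling."""

    lof_penalty: dict[str, float] = field(default_factory=lambda: {"F12": 0.9, "KLKB1": 0.9})
    kng1_cofactor: float = 0.3
    olink_gain: float = 0.5

    def __post_init__(self):
        for g, lam in self.lof_penalty.items():
            if not 0.0 <= lam <= 1.0:
                raise ValueError(f"lof penalty for {g} must be in [0,1]")


@dataclass
class EffectSpec:
    """Generative parameters for the latent abundance and platform channels
    (all effects in per-alternative-allele NPX/log2 units)."""

    baseline_mu: float = 3.0
    v2_effect_on_T: float = -0.2
    hpr_effect_on_T: float = 0.3
    epitope_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    stratum_interactions: list[StratumInteraction] = field(default_factory=list)
    kks: KKSSpec = field(default_factory=KKSSpec)
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {"Olink": 1.0, "SomaLogic": 1.0, "MS": 0.5}
    )
    shared_T_sd: float = 0.4

    def __post_init__(self):
        if self.shared_T_sd < 0:
            raise ValueError("shared_T_sd must be >= 0")
        for p, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise sd for {p} must be >= 0")


def afr_table2_spec() -> EffectSpec:
    """African-ancestry effect spec with the published additive per-allele
    epitope effects (Olink from UKB AFR, SomaLogic from AASK; V1 effects
    are stored per alternative A allele, hence the sign flips relative to
    the published per-G-allele values)."""
    return EffectSpec(
        epitope_effects={
            "Olink": {"G1": 0.28, "G2": 1.33, "V1": -0.18},
            "SomaLogic": {"G1": -0.10, "G2": -0.44, "V1": 0.33},
            "MS": {},
        }
    )


def afr_stratified_spec() -> EffectSpec:
    """AFR spec with the published G1/G2 stratified (epistatic) Olink
    effects instead of plain additive ones.

    The three published stratified slopes (G2 effect 1.212 in the
    G1-absent stratum, G1 effect 0.287 / 0.066 in the G2-absent /
    G2-heterozygote strata) are jointly consistent with a single
    product-term surface with interaction coefficient
    0.066 - 0.287 = -0.221; encoding the interaction once, on the G2
    effect, with a constant per-allele G1 effect of 0.287 reproduces all
    three slopes without double counting.
    """
    spec = afr_table2_spec()
    spec.epitope_effects["Olink"]["G1"] = 0.287
    spec.stratum_interactions = [
        StratumInteraction("G1", "het_only", "G2", 1.212, 1.212 - 0.221),
    ]
    return spec


def eur_table2_spec() -> EffectSpec:
    """European-ancestry spec: V1 epitope effects per alternative allele
    from the UKB EUR (Olink) and deCODE (SomaLogic) estimates."""
    return EffectSpec(
        epitope_effects={
            "Olink": {"G1": 0.28, "G2": 1.33, "V1": -0.32},
            "SomaLogic": {"G1": -0.10, "G2": -0.44, "V1": 0.38},
            "MS": {},
        }
    )


def healthabc_spec() -> EffectSpec:
    """Health-ABC-like spec: G1 and G2 are indistinguishable at the peptide
    level and share one Olink carrier-allele effect; MS sees none."""
    return EffectSpec(
        epitope_effects={
            "Olink": {"G1": 0.59, "G2": 0.59, "V1": -0.27},
            "MS": {},
        }
    )


def _resolve(cohort: PhasedCohort, key: str) -> np.ndarray:
    """Dosage lookup treating 'G1' as an alias of the G1M proxy variant."""
    if key == "G1":
        key = "G1M"
    return cohort.dosage(key)


def kks_activity(cohort: PhasedCohort, kks: KKSSpec) -> np.ndarray:
    """Multiplicative KKS pathway activity from the trans genotypes."""
    act = np.ones(cohort.n)
    for gene, lam in kks.lof_penalty.items():
        if gene in cohort.trans_genotypes:
            d_alt = cohort.trans_genotypes[gene].astype(float)
            d_lof = d_alt if KKS_LOF_IS_ALT[gene] else 2.0 - d_alt
            act *= 1.0 - lam * d_lof / 2.0
    if "KNG1" in cohort.trans_genotypes:
        d_alt = cohort.trans_genotypes["KNG1"].astype(float)
        d_fun = d_alt if KKS_LOF_IS_ALT["KNG1"] else 2.0 - d_alt
        act *= 1.0 + kks.kng1_cofactor * d_fun / 2.0
    return act


def _epitope_sum(cohort: PhasedCohort, spec: EffectSpec, platform: str) -> np.ndarray:
    delta = spec.epitope_effects.get(platform, {})
    total = np.zeros(cohort.n)
    per_variant = {v: np.full(cohort.n, eff) for v, eff in delta.items()}
    if platform == "Olink":
        for si in spec.stratum_interactions:
            d_mod = _resolve(cohort, si.modifier)
            if si.carrier_rule == "het_only":
                present = d_mod == 1
            elif si.carrier_rule == "het_or_hom":
                present = d_mod >= 1
            else:
                raise ValueError(f"unknown carrier rule {si.carrier_rule!r}")
            per_variant[si.target] = np.where(present, si.effect_present, si.effect_absent)
    for v, eff in per_variant.items():
        total += eff * _resolve(cohort, v)
    return total


def simulate_measurements(
    cohort: PhasedCohort,
    spec: EffectSpec,
    platforms: tuple[str, ...] = PLATFORMS,
    seed: int = 0,
) -> tuple[dict[str, MeasurementSet], np.ndarray]:
    """Simulate platform channels from a shared latent abundance.

    Returns (per-platform MeasurementSet dict, latent T vector).  The MS
    channel reads T directly; Olink adds epitope effects plus the KKS gain;
    SomaLogic adds its own (typically opposite-signed) epitope effects.
    """
    for p in platforms:
        if p not in PLATFORMS:
            raise ValueError(f"unknown platform {p!r}")
        if p != "MS" and p not in spec.epitope_effects:
            raise ValueError(f"platform {p!r} requested without an epitope-effect map")
    rng = np.random.default_rng(seed)
    T = spec.baseline_mu + rng.normal(0.0, spec.shared_T_sd, cohort.n)
    if "V2" in [v.label for v in cohort.pool.panel]:
        T = T + spec.v2_effect_on_T * cohort.dosage("V2")
    if "HPR" in cohort.trans_genotypes:
        T = T + spec.hpr_effect_on_T * cohort.trans_genotypes["HPR"]
    out = {}
    for p in PLATFORMS:  # fixed draw order keeps seeding stable across subsets
        eps = rng.normal(0.0, spec.noise_sd.get(p, 1.0), cohort.n)
        if p not in platforms:
            continue
        y = T + eps
        if p != "MS":
            y = y + _epitope_sum(cohort, spec, p)
        if p == "Olink":
            y = y + spec.kks.olink_gain * kks_activity(cohort, spec.kks)
        out[p] = MeasurementSet(p, pd.DataFrame({"APOL1": y}, index=cohort.sample_ids))
    return out, T


# ---------------------------------------------------------------------------
# peptide layer
# ---------------------------------------------------------------------------

PEPTIDE_G1G2 = "LNILNNNYK"
PEPTIDE_V1_REF = "SELEDNIRR"
PEPTIDE_V1_ALT = "LEDNIRR"


@dataclass
class PeptideSpec:
    """19 APOL1 tryptic peptides on the log2 sample/bridge-ratio scale;
    exact 0.0 is the 'not detected' sentinel."""

    peptide_ids: list[str]
    offsets: np.ndarray
    pep_noise_sd: float = 0.3
    zero_sentinel: float = 0.0

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        for pep in (PEPTIDE_G1G2, PEPTIDE_V1_REF, PEPTIDE_V1_ALT):
            if self.peptide_ids.count(pep) != 1:
                raise ValueError(f"peptide {pep} must appear exactly once")
        if len(self.offsets) != len(self.peptide_ids):
            raise ValueError("offsets must align with peptide_ids")
        if self.pep_noise_sd < 0:
            raise ValueError("pep_noise_sd must be >= 0")


def default_peptide_spec(baseline_mu: float = 3.0, pep_noise_sd: float = 0.3) -> PeptideSpec:
    """Offsets map the NPX-scale latent to bridge ratios centred near
    -0.75, the regime the genotype-calling thresholds were designed for;
    the G1/G2-spanning peptide sits exactly at the centre.  The V1 ALT
    peptide runs 0.25 units above the REF peptide, placing V1
    heterozygotes (y - x near +0.25) at the midpoint of the asymmetric
    calling band x - 0.5 < y < x + 1."""
    other = [f"APOL1_pep{k:02d}" for k in range(1, 17)]
    ids = [PEPTIDE_G1G2, PEPTIDE_V1_REF, PEPTIDE_V1_ALT] + other
    jitter = np.concatenate([[0.0, 0.0, 0.25], np.linspace(-0.15, 0.15, 16)])
    return PeptideSpec(ids, -baseline_mu - 0.75 + jitter, pep_noise_sd)


def simulate_peptides(
    cohort: PhasedCohort,
    spec: PeptideSpec,
    T: np.ndarray,
    seed: int = 0,
) -> MeasurementSet:
    """Simulate the peptide table.

    Allele-specific peptides scale with the number of carrying haplotypes
    (log2(c/2) relative to the two-copy level) and are exactly 0 when no
    haplotype carries them: LNILNNNYK requires the reference allele at
    both G1M and G2 on the same haplotype; SELEDNIRR / LEDNIRR carry the
    V1 reference / alternative allele respectively.
    """
    rng = np.random.default_rng(seed)
    haps = cohort.haplotype_alleles()
    i_g1m = cohort.pool.index_of("G1M")
    i_g2 = cohort.pool.index_of("G2")
    i_v1 = cohort.pool.index_of("V1")
    # per-sample carrying-haplotype counts
    r_g1g2 = ((haps[:, :, i_g1m] == 0) & (haps[:, :, i_g2] == 0)).sum(axis=1)
    v1_alt = haps[:, :, i_v1].sum(axis=1)
    counts = {
        PEPTIDE_G1G2: r_g1g2,
        PEPTIDE_V1_REF: 2 - v1_alt,
        PEPTIDE_V1_ALT: v1_alt,
    }
    cols = {}
    for j, pep in enumerate(spec.peptide_ids):
        eps = rng.normal(0.0, spec.pep_noise_sd, cohort.n)
        val = T + spec.offsets[j] + eps
        if pep in counts:
            c = counts[pep]
            with np.errstate(divide="ignore"):
                val = np.where(c > 0, val + np.log2(np.maximum(c, 1) / 2.0), spec.zero_sentinel)
        cols[pep] = val
    return MeasurementSet("peptide", pd.DataFrame(cols, index=cohort.sample_ids))


# ---------------------------------------------------------------------------
# imputation-artifact injection
# ---------------------------------------------------------------------------


def corrupt_imputation(
    cohort: PhasedCohort, het_to_hom_rate: float, seed: int = 0
) -> pd.DataFrame:
    """Return an 'imputed' dosage matrix in which each heterozygous G1M or
    G1G call independently becomes homozygous-alternative with the given
    rate, creating the Hardy-Weinberg and haplotype-consistency violations
    a QC layer should detect."""
    if not 0.0 <= het_to_hom_rate <= 1.0:
        raise ValueError("rate must be in [0,1]")
    rng = np.random.default_rng(seed)
    dos = cohort.dosage_matrix([v.variant_id for v in cohort.pool.panel])
    out = dos.copy()
    for v in cohort.pool.panel:
        if (v.label or "") in ("G1M", "G1G"):
            col = out[v.variant_id].to_numpy().copy()
            het = col == 1
            flip = het & (rng.random(len(col)) < het_to_hom_rate)
            col[flip] = 2
            out[v.variant_id] = col
    return out


def simulate_covariates(n: int, seed: int = 0) -> pd.DataFrame:
    """Age and sex covariates (age in years, sex coded 0/1)."""
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "age": rng.normal(57.0, 8.0, n).round(1),
            "sex": rng.integers(0, 2, n).astype(float),
        }
    )
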