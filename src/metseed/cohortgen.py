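"""Seeded synthetic-data generators for the full analysis pipeline.

Three generators emulate the statistical structure of a radiation-exposed
papillary thyroid carcinoma (PTC) cohort with paired primary-tumor (PT) and
cervical lymph-node metastasis (cLNM/"met") samples:

* :func:`generate_cohort` — clinical/exposure/driver/outcome rows for a
  cohort of subjects, with cLNM arising from either a logistic model with
  per-driver-category log-odds or an excess-odds-ratio (EOR) dose-response
  model (odds multiplied by ``1 + theta1*dose_Gy``).
* :func:`generate_paired_variants` — paired met/PT somatic SNV call sets
  with known clone structure (trunk clonal shared, shared subclonal,
  private clonal/subclonal per sample), observed through binomial read
  sampling at a configurable depth and a multi-caller sensitivity model.
* :func:`generate_counts` — negative-binomial gene (or miRNA) count
  matrices with spiked tissue effects, batch structure, and an optional
  shared latent factor mediating the tissue effect of a block of genes
  (for conditional-adjustment analyses).

Randomness policy: every generator derives an independent substream from
the root seed via ``numpy.random.SeedSequence(seed, spawn_key=(STREAM,))``
with a fixed per-generator stream id, so adding a call to one generator
never perturbs the output of another.
"""
from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CohortConfig",
    "PairedConfig",
    "PairedTruth",
    "CountsConfig",
    "generate_cohort",
    "generate_paired_variants",
    "generate_counts",
    "driver_evidence_tables",
    "POLYCLONAL_MIN_SHARED_SUBCLONAL",
]

# Shared subclonal SNVs at or above this count mark a pair as polyclonally
# seeded; below it, private clonal mutations are read as sampling bias.
POLYCLONAL_MIN_SHARED_SUBCLONAL = 10

_STREAMS = {"cohort": 1, "pairs": 2, "counts": 3}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(int(seed), spawn_key=(_STREAMS[stream],))
    )


# Calibration defaults: driver-category frequencies and per-category cLNM
# probabilities of the 428 driver-designated tumors in the reference cohort.
DEFAULT_CATEGORY_PROBS = {
    "BRAF_mutation": 194 / 428,
    "other_mutation": 58 / 428,
    "RET_fusion": 73 / 428,
    "other_RTK_fusion": 64 / 428,
    "other_fusion": 39 / 428,
}
DEFAULT_CLNM_PROBS = {
    "BRAF_mutation": 73 / 194,
    "other_mutation": 3 / 58,
    "RET_fusion": 52 / 73,
    "other_RTK_fusion": 41 / 64,
    "other_fusion": 4 / 39,
}
# Representative driver gene per category, used when emitting per-sample
# driver evidence for the designation stage.
CATEGORY_GENES = {
    "BRAF_mutation": ("BRAF", "mutation"),
    "other_mutation": ("NRAS", "mutation"),
    "RET_fusion": ("RET", "fusion"),
    "other_RTK_fusion": ("NTRK1", "fusion"),
    "other_fusion": ("BRAF", "fusion"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Configuration of the clinical-cohort generator.

    Defaults are calibrated to the reference cohort: 440 subjects, 18.4%
    unexposed, exposed thyroid doses lognormal with mean ~247 mGy (range
    capped at 8800 mGy), and the observed driver-category mix with its
    per-category cLNM frequencies.
    """

    n_subjects: int = 440
    sex_ratio_female: float = 0.761
    age_mean: float = 28.0
    age_sd: float = 7.0
    age_min: float = 10.0
    age_max: float = 45.6
    frac_unexposed: float = 81 / 440
    dose_lognorm_mu: float = 4.789  # ln mGy; mean ~= 247 mGy with sigma 1.2
    dose_lognorm_sigma: float = 1.2
    dose_min_mGy: float = 11.0
    dose_max_mGy: float = 8800.0
    driver_category_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PROBS)
    )
    clnm_model: str = "logistic"  # or "eor"
    # logistic model: per-category probabilities (converted to log-odds)
    clnm_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLNM_PROBS)
    )
    coef_male: float = 0.0
    coef_age_per_decade: float = 0.0
    # eor model: odds = baseline_odds * (1 + theta1 * truncated dose in Gy)
    eor_baseline_odds: float = 0.3
    eor_theta1_per_Gy: float = 1.5
    dose_truncation_mGy: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        probs = dict(self.driver_category_probs)
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"driver_category_probs sums to {total}, not 1")
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability for {name} outside [0,1]: {p}")
        if not 0.0 <= self.sex_ratio_female <= 1.0:
            raise ValueError("sex_ratio_female outside [0,1]")
        if not 0.0 <= self.frac_unexposed <= 1.0:
            raise ValueError("frac_unexposed outside [0,1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.clnm_model not in ("logistic", "eor"):
            raise ValueError(f"unknown clnm_model {self.clnm_model!r}")
        if self.clnm_model == "logistic":
            for name, p in dict(self.clnm_probs).items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"clnm prob for {name} outside [0,1]")


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, dict]:
    """Simulate a clinical cohort table plus a truth sidecar.

    Returns ``(subjects, truth)`` where ``subjects`` has the columns the
    epidemiology stage ingests (id, sex, age_at_ptc, exposed, dose_mGy,
    driver_category, driver_gene, driver_mechanism, clnm, n_stage,
    m_stage, tumor_size_cat, multifocal) and ``truth`` records the
    generative coefficients.
    """
    config.validate()
    rng = _rng(config.seed, "cohort")
    n = config.n_subjects

    sex = np.where(rng.random(n) < config.sex_ratio_female, "F", "M")
    age = np.clip(
        rng.normal(config.age_mean, config.age_sd, n), config.age_min, config.age_max
    )
    exposed = rng.random(n) >= config.frac_unexposed
    dose = np.zeros(n)
    n_exp = int(exposed.sum())
    raw = rng.lognormal(config.dose_lognorm_mu, config.dose_lognorm_sigma, n_exp)
    dose[exposed] = np.clip(raw, config.dose_min_mGy, config.dose_max_mGy)

    cats = list(config.driver_category_probs)
    probs = np.array([config.driver_category_probs[c] for c in cats])
    cat_idx = rng.choice(len(cats), size=n, p=probs / probs.sum())
    category = np.array(cats)[cat_idx]

    size_cat = rng.choice(["<=1.0", ">1.0-2.0", ">2.0"], size=n, p=[0.35, 0.4, 0.25])
    multifocal = rng.random(n) < 0.18

    if config.clnm_model == "logistic":
        logit = np.array(
            [_logit(config.clnm_probs.get(c, 0.5)) for c in category]
        )
        logit += np.where(sex == "M", config.coef_male, 0.0)
        logit += config.coef_age_per_decade * (age - config.age_mean) / 10.0
        p_clnm = 1.0 / (1.0 + np.exp(-logit))
    else:
        dose_gy = np.minimum(dose, config.dose_truncation_mGy) / 1000.0
        odds = config.eor_baseline_odds * (1.0 + config.eor_theta1_per_Gy * dose_gy)
        p_clnm = odds / (1.0 + odds)
    clnm = rng.random(n) < p_clnm

    # Nodal stage: split cLNM into central (N1a) / lateral (N1b) compartments
    # at the reference cohort's observed ratio.
    n1b = clnm & (rng.random(n) < 91 / 178)
    n_stage = np.where(~clnm, "N0", np.where(n1b, "N1b", "N1a"))

    genes = np.array([CATEGORY_GENES[c][0] for c in category])
    mechs = np.array([CATEGORY_GENES[c][1] for c in category])

    subjects = pd.DataFrame(
        {
            "id": [f"S{i:05d}" for i in range(n)],
            "sex": sex,
            "age_at_ptc": np.round(age, 2),
            "exposed": exposed,
            "dose_mGy": np.round(dose, 1),
            "driver_category": category,
            "driver_gene": genes,
            "driver_mechanism": mechs,
            "clnm": clnm,
            "n_stage": n_stage,
            "m_stage": "M0",
            "tumor_size_cat": size_cat,
            "multifocal": multifocal,
        }
    )
    truth = {
        "config": dataclasses.asdict(config),
        "p_clnm_mean": float(np.mean(p_clnm)),
        "model": config.clnm_model,
    }
    return subjects, truth


def _logit(p: float) -> float:
    p = min(max(p, 1e-12), 1 - 1e-12)
    return math.log(p / (1.0 - p))


# ---------------------------------------------------------------------------
# Paired met/PT variant generator
# ---------------------------------------------------------------------------

CLONE_CLASSES = (
    "trunk_shared_clonal",
    "shared_subclonal",
    "private_met_clonal",
    "private_met_subclonal",
    "private_pt_clonal",
    "private_pt_subclonal",
)


@dataclass(frozen=True)
class PairedConfig:
    """Clone structure and observation model for one met/PT pair.

    Depth defaults to the study's mean whole-genome sequencing depth
    (89X).  Per-caller sensitivity simulates the multi-caller consensus:
    each true variant is seen independently by each caller, and injected
    false positives carry single-caller support so the two-caller rule
    has a measurable effect.
    """

    n_trunk_clonal: int = 30
    n_shared_subclonal: int = 12
    n_private_met_clonal: int = 5
    n_private_met_subclonal: int = 15
    n_private_pt_clonal: int = 5
    n_private_pt_subclonal: int = 15
    purity_met: float = 0.7
    purity_pt: float = 0.7
    depth: int = 89
    subclonal_ccf_range: tuple[float, float] = (0.2, 0.5)
    callers: tuple[str, ...] = ("mutect2", "strelka2", "svaba")
    caller_sensitivity: float = 0.95
    n_false_positives: int = 4
    n_contigs: int = 10
    contig_length: int = 10_000_000
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "n_trunk_clonal",
            "n_shared_subclonal",
            "n_private_met_clonal",
            "n_private_met_subclonal",
            "n_private_pt_clonal",
            "n_private_pt_subclonal",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("purity_met", "purity_pt"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")


@dataclass
class PairedTruth:
    """Generator truth for one pair: per-variant labels and seeding verdict."""

    variants: pd.DataFrame  # key, clone_class, true_ccf_met, true_ccf_pt
    purity_met: float
    purity_pt: float
    depth: int
    seeding_truth: str  # "polyclonal" | "sampling_bias"

    @property
    def n_shared_subclonal(self) -> int:
        return int((self.variants["clone_class"] == "shared_subclonal").sum())


def expected_vaf(ccf, purity, local_cn: float = 2.0, multiplicity: float = 1.0):
    """Expected variant allele fraction of a variant in a tumor sample.

    ``vaf = ccf * purity * multiplicity / (purity * CN_t + (1 - purity) * 2)``
    — tumor cells contribute ``CN_t`` copies (``multiplicity`` mutated),
    admixed normal cells contribute two reference copies.
    """
    return (
        np.asarray(ccf) * purity * multiplicity / (purity * local_cn + (1 - purity) * 2)
    )


def generate_paired_variants(
    config: PairedConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PairedTruth]:
    """Simulate paired met/PT SNV call sets plus their truth record.

    Returns ``(met_calls, pt_calls, truth)``.  Call tables have one row
    per variant observed in that sample with columns: sample_id, chrom,
    pos, ref, alt, vtype, callers (``;``-joined), alt_reads_tumor,
    ref_reads_tumor, alt_reads_normal, vaf.  A variant enters a sample's
    table when it has at least one alternate read there; caller labels
    are drawn per the sensitivity model.
    """
    config.validate()
    rng = _rng(config.seed, "pairs")

    counts = {
        "trunk_shared_clonal": config.n_trunk_clonal,
        "shared_subclonal": config.n_shared_subclonal,
        "private_met_clonal": config.n_private_met_clonal,
        "private_met_subclonal": config.n_private_met_subclonal,
        "private_pt_clonal": config.n_private_pt_clonal,
        "private_pt_subclonal": config.n_private_pt_subclonal,
    }
    n_true = sum(counts.values())
    lo, hi = config.subclonal_ccf_range

    rows = []
    for clone_class, n in counts.items():
        for _ in range(n):
            sub_ccf = rng.uniform(lo, hi)
            in_met = clone_class.startswith(("trunk", "shared", "private_met"))
            in_pt = clone_class.startswith(("trunk", "shared", "private_pt"))
            clonal = clone_class.endswith("clonal") and "subclonal" not in clone_class
            ccf = 1.0 if clonal else sub_ccf
            rows.append(
                {
                    "clone_class": clone_class,
                    "true_ccf_met": ccf if in_met else 0.0,
                    "true_ccf_pt": ccf if in_pt else 0.0,
                }
            )
    truth_df = pd.DataFrame(
        rows, columns=["clone_class", "true_ccf_met", "true_ccf_pt"]
    )

    # Unique loci on the miniature genome.
    n_loci = n_true + config.n_false_positives * 2
    contigs = rng.integers(1, config.n_contigs + 1, n_loci)
    pos = rng.integers(1, config.contig_length + 1, n_loci)
    keys = [f"chr{c}:{p}" for c, p in zip(contigs, pos)]
    bases = np.array(list("ACGT"))
    refs = bases[rng.integers(0, 4, n_loci)]
    alts = np.array(
        [rng.choice([b for b in "ACGT" if b != r]) for r in refs]
    )
    truth_df["chrom"] = [f"chr{c}" for c in contigs[:n_true]]
    truth_df["pos"] = pos[:n_true]
    truth_df["ref"] = refs[:n_true]
    truth_df["alt"] = alts[:n_true]
    truth_df["key"] = [k for k in keys[:n_true]]

    seeding = (
        "polyclonal"
        if counts["shared_subclonal"] >= POLYCLONAL_MIN_SHARED_SUBCLONAL
        else "sampling_bias"
    )

    def observe(sample: str, purity: float, ccf_col: str) -> pd.DataFrame:
        out = []
        for i, rec in truth_df.iterrows():
            ccf = rec[ccf_col]
            if ccf <= 0:
                continue
            vaf_exp = float(expected_vaf(ccf, purity))
            alt_reads = int(rng.binomial(config.depth, vaf_exp))
            if alt_reads == 0:
                continue
            seen = rng.random(len(config.callers)) < config.caller_sensitivity
            if not seen.any():
                seen[rng.integers(len(config.callers))] = True
            out.append(
                {
                    "sample_id": sample,
                    "chrom": rec["chrom"],
                    "pos": int(rec["pos"]),
                    "ref": rec["ref"],
                    "alt": rec["alt"],
                    "vtype": "SNV",
                    "callers": ";".join(
                        c for c, s in zip(config.callers, seen) if s
                    ),
                    "alt_reads_tumor": alt_reads,
                    "ref_reads_tumor": config.depth - alt_reads,
                    "alt_reads_normal": 0,
                    "vaf": alt_reads / config.depth,
                    "is_false_positive": False,
                }
            )
        return pd.DataFrame(out)

    met = observe("met", config.purity_met, "true_ccf_met")
    pt = observe("pt", config.purity_pt, "true_ccf_pt")

    # Injected artifacts: single-caller support, low VAF, not in truth.
    fp_rows = []
    fp_keys = keys[n_true:]
    fp_contigs = contigs[n_true:]
    fp_pos = pos[n_true:]
    fp_refs, fp_alts = refs[n_true:], alts[n_true:]
    for j in range(config.n_false_positives * 2):
        sample = "met" if j % 2 == 0 else "pt"
        alt_reads = int(rng.integers(2, 6))
        fp_rows.append(
            {
                "sample_id": sample,
                "chrom": f"chr{fp_contigs[j]}",
                "pos": int(fp_pos[j]),
                "ref": fp_refs[j],
                "alt": fp_alts[j],
                "vtype": "SNV",
                "callers": str(rng.choice(config.callers)),
                "alt_reads_tumor": alt_reads,
                "ref_reads_tumor": config.depth - alt_reads,
                "alt_reads_normal": 0,
                "vaf": alt_reads / config.depth,
                "is_false_positive": True,
            }
        )
    if fp_rows:
        fp = pd.DataFrame(fp_rows)
        met = pd.concat([met, fp[fp["sample_id"] == "met"]], ignore_index=True)
        pt = pd.concat([pt, fp[fp["sample_id"] == "pt"]], ignore_index=True)

    truth = PairedTruth(
        variants=truth_df[
            ["key", "chrom", "pos", "ref", "alt", "clone_class", "true_ccf_met", "true_ccf_pt"]
        ],
        purity_met=config.purity_met,
        purity_pt=config.purity_pt,
        depth=config.depth,
        seeding_truth=seeding,
    )
    return met, pt, truth


# ---------------------------------------------------------------------------
# Count-matrix generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountsConfig:
    """Negative-binomial count-matrix generator configuration.

    ``spike_table`` lists ``(gene_id, tissue_log2fc)`` pairs: those genes
    get a direct met-vs-PT effect of the stated magnitude on the log2
    scale.  ``shared_factor_genes`` (with ``factor_gene`` as the focal
    member) instead load on one latent factor that itself shifts with
    tissue, so their marginal tissue effect disappears once the focal
    gene's expression is adjusted for.  Spiked and factor genes use an
    elevated base mean (``spike_base_mean``) so the effects are
    resolvable at realistic sequencing depth, mirroring the strongly
    expressed loci where large fold changes are observed in practice.
    """

    n_genes: int = 2000
    n_met: int = 45
    n_pt: int = 130
    library_size_mu: float = math.log(1.0)  # relative library-size lognormal
    library_size_sigma: float = 0.25
    dispersion: float = 0.1
    base_mean_log_mu: float = math.log(50.0)
    base_mean_log_sigma: float = 1.0
    spike_table: tuple[tuple[str, float], ...] = ()
    spike_base_mean: float = 200.0
    batch_levels: int = 2
    batch_log2fc_sd: float = 0.2
    factor_gene: str | None = None
    shared_factor_genes: tuple[str, ...] = ()
    factor_tissue_shift: float = 3.4
    factor_sd: float = 1.0
    factor_loading_focal: float = 1.0
    factor_loading_others: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        gene_ids = {f"G{i:04d}" for i in range(self.n_genes)}
        for g, _ in self.spike_table:
            if g not in gene_ids:
                raise ValueError(f"spiked gene {g} not among generated gene ids")
        for g in self.shared_factor_genes:
            if g not in gene_ids:
                raise ValueError(f"factor gene {g} not among generated gene ids")


def generate_counts(
    config: CountsConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a genes x samples count matrix.

    Returns ``(counts, metadata, truth_effects)``: integer counts indexed
    by gene id with sample-id columns; per-sample metadata (tissue, batch,
    sex, age); and the per-gene true direct tissue log2FC table.
    """
    config.validate()
    rng = _rng(config.seed, "counts")
    n_s = config.n_met + config.n_pt
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    samples = [f"M{i:03d}" for i in range(config.n_met)] + [
        f"P{i:03d}" for i in range(config.n_pt)
    ]
    tissue = np.array([1] * config.n_met + [0] * config.n_pt)

    meta = pd.DataFrame(
        {
            "sample_id": samples,
            "tissue": np.where(tissue == 1, "met", "pt"),
            "batch": [f"B{i % config.batch_levels}" for i in range(n_s)],
            "sex": np.where(rng.random(n_s) < 0.76, "F", "M"),
            "age": np.round(np.clip(rng.normal(28, 7, n_s), 10, 46), 1),
        }
    ).set_index("sample_id")

    base = np.exp(rng.normal(config.base_mean_log_mu, config.base_mean_log_sigma, config.n_genes))
    spike_fc = dict(config.spike_table)
    direct_l2fc = np.array([spike_fc.get(g, 0.0) for g in genes])
    special = np.array(
        [g in spike_fc or g in config.shared_factor_genes or g == config.factor_gene for g in genes]
    )
    base[special] = config.spike_base_mean

    lib = np.exp(rng.normal(config.library_size_mu, config.library_size_sigma, n_s))

    batch_idx = np.array([i % config.batch_levels for i in range(n_s)])
    batch_l2 = rng.normal(0.0, config.batch_log2fc_sd, (config.n_genes, config.batch_levels))
    # identifiability: first batch level is the reference
    batch_l2[:, 0] = 0.0

    log2_mu = (
        np.log2(base)[:, None]
        + direct_l2fc[:, None] * tissue[None, :]
        + batch_l2[:, batch_idx]
    )

    if config.factor_gene is not None:
        latent = config.factor_tissue_shift * tissue + rng.normal(0.0, config.factor_sd, n_s)
        loadings = np.zeros(config.n_genes)
        gene_pos = {g: i for i, g in enumerate(genes)}
        loadings[gene_pos[config.factor_gene]] = config.factor_loading_focal
        for g in config.shared_factor_genes:
            if g != config.factor_gene:
                loadings[gene_pos[g]] = config.factor_loading_others
        log2_mu = log2_mu + loadings[:, None] * latent[None, :]

    mu = np.exp2(log2_mu) * lib[None, :]
    r = 1.0 / config.dispersion  # NB shape so that var = mu + dispersion*mu^2
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene"), columns=samples)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "direct_tissue_log2fc": direct_l2fc,
            "factor_loading": (
                loadings if config.factor_gene is not None else np.zeros(config.n_genes)
            ),
        }
    ).set_index("gene")
    return counts_df, meta, truth


# ---------------------------------------------------------------------------
# Driver evidence for the designation stage
# ---------------------------------------------------------------------------


def driver_evidence_tables(
    subjects: pd.DataFrame, seed: int = 0, passengers_per_sample: int = 3
) -> dict[str, dict[str, pd.DataFrame]]:
    """Emit per-subject met/PT driver evidence (variant + fusion tables).

    Both members of each pair carry evidence for the subject's truth
    driver, alongside passenger variants (synonymous or in unlisted
    genes) that candidate filtering must discard.  Returns a mapping
    ``subject_id -> {"met_variants", "pt_variants", "met_fusions",
    "pt_fusions"}``.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(4,)))
    passenger_genes = ["TTN", "MUC16", "OBSCN", "AHNAK2", "FLG"]
    passenger_cons = ["synonymous", "intron", "missense"]
    out: dict[str, dict[str, pd.DataFrame]] = {}
    for _, row in subjects.iterrows():
        gene = row["driver_gene"]
        mech = row["driver_mechanism"]
        var_rows, fus_rows = [], []
        if mech == "mutation":
            var_rows.append(
                {"gene": gene, "consequence": "missense", "protein_change": "p.V600E"}
            )
        else:
            partner = "CCDC6" if gene == "RET" else "ETV6"
            fus_rows.append({"gene_a": partner, "gene_b": gene, "source": "rna"})
        for _ in range(passengers_per_sample):
            var_rows.append(
                {
                    "gene": str(rng.choice(passenger_genes)),
                    "consequence": str(rng.choice(passenger_cons)),
                    "protein_change": "",
                }
            )
        variants = pd.DataFrame(var_rows)
        fusions = pd.DataFrame(fus_rows, columns=["gene_a", "gene_b", "source"])
        out[row["id"]] = {
            "met_variants": variants.copy(),
            "pt_variants": variants.copy(),
            "met_fusions": fusions.copy(),
            "pt_fusions": fusions.copy(),
        }
    return out
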