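"""Tumor purity, cancer cell fraction (CCF), and metastasis-seeding inference.

Purity is estimated from the clonal variant-allele-fraction (VAF) peak: in a
copy-neutral diploid genome a fully clonal heterozygous variant has expected
VAF = purity / 2, so purity = 2 x the location of the clonal VAF peak found by
kernel density estimation.  CCF converts VAF to the fraction of tumor cells
carrying a variant given purity and local copy number; variants with
CCF >= 0.6 are called clonal.  Paired met/PT call sets are partitioned into
shared / private-met / private-PT by locus, crossed with clonality, and the
shared-subclonal count drives the seeding verdict: >= 10 shared subclonal
SNVs indicate polyclonal seeding, otherwise the dominance of private clonal
mutations is read as within-tumor sampling bias that obscures the seeding
pattern.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

__all__ = [
    "PurityEstimate",
    "PairedClassification",
    "SeedingCall",
    "estimate_purity",
    "compute_ccf",
    "ccf_table",
    "classify_paired",
    "infer_seeding",
    "CLONAL_CCF_MIN",
    "PURITY_QC_MIN",
    "POLYCLONAL_MIN_SHARED_SUBCLONAL",
]

CLONAL_CCF_MIN = 0.6
PURITY_QC_MIN = 0.20
POLYCLONAL_MIN_SHARED_SUBCLONAL = 10


@dataclass(frozen=True)
class PurityEstimate:
    purity: float
    peak_vaf: float
    method: str  # "vaf_peak" | "provided"
    qc_pass: bool

    @classmethod
    def provided(cls, purity: float) -> "PurityEstimate":
        if not 0.0 < purity <= 1.0:
            raise ValueError(f"purity must be in (0,1], got {purity}")
        return cls(purity, purity / 2.0, "provided", purity >= PURITY_QC_MIN)


def estimate_purity(
    vafs,
    bandwidth: float = 0.02,
    min_variants: int = 20,
    vaf_max: float = 0.6,
    min_peak_mass: float = 0.05,
    grid_points: int = 601,
) -> PurityEstimate:
    """Estimate purity as twice the clonal VAF peak.

    A Gaussian KDE (absolute bandwidth on the VAF scale) is evaluated on
    [0, ``vaf_max``]; the search window excludes the LOH/homozygous range
    above ``vaf_max``.  Among local density maxima whose basin of
    attraction holds at least ``min_peak_mass`` of the variants, the peak
    at the highest VAF is taken as the clonal peak — subclonal clusters
    sit at lower VAF than the clonal one.
    """
    vafs = np.asarray(vafs, dtype=float)
    vafs = vafs[np.isfinite(vafs)]
    if len(vafs) < min_variants:
        raise ValueError(
            f"need >= {min_variants} VAFs to locate the clonal peak "
            f"(got {len(vafs)}); supply a purity estimate instead"
        )
    if np.ptp(vafs) < 1e-12:  # degenerate: all mass at one value
        peak = float(vafs[0])
        purity = min(1.0, 2.0 * peak)
        return PurityEstimate(purity, peak, "vaf_peak", purity >= PURITY_QC_MIN)

    kde = gaussian_kde(vafs, bw_method=bandwidth / vafs.std(ddof=1))
    grid = np.linspace(0.0, vaf_max, grid_points)
    dens = kde(grid)

    interior = np.arange(1, len(grid) - 1)
    is_max = (dens[interior] >= dens[interior - 1]) & (dens[interior] > dens[interior + 1])
    peaks = interior[is_max]
    if len(peaks) == 0:
        peaks = np.array([int(np.argmax(dens))])

    # Basin boundaries: local minima between consecutive peaks.
    boundaries = [0.0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        valley = left + int(np.argmin(dens[left : right + 1]))
        boundaries.append(grid[valley])
    boundaries.append(np.inf)

    in_window = vafs[vafs <= vaf_max]
    qualifying = []
    for i, pk in enumerate(peaks):
        lo, hi = boundaries[i], boundaries[i + 1]
        mass = np.mean((vafs >= lo) & (vafs < hi)) if len(vafs) else 0.0
        if mass >= min_peak_mass:
            qualifying.append(pk)
    if not qualifying:
        qualifying = [peaks[int(np.argmax(dens[peaks]))]]

    peak_vaf = float(grid[qualifying[-1]])  # highest-VAF qualifying peak
    purity = min(1.0, 2.0 * peak_vaf)
    return PurityEstimate(purity, peak_vaf, "vaf_peak", purity >= PURITY_QC_MIN)


def compute_ccf(vaf, purity, local_cn_tumor=2.0, multiplicity=1.0):
    """Cancer cell fraction from VAF, purity, and local copy state.

    ``ccf_raw = vaf * (purity*CN_t + (1-purity)*2) / (purity*multiplicity)``,
    clamped to [0, 1].  With the diploid defaults (CN 2, multiplicity 1)
    this reduces to ``2*vaf/purity``.  Vectorized over ``vaf``.
    """
    purity = float(purity)
    if not 0.0 < purity <= 1.0:
        raise ValueError(f"purity must be in (0,1], got {purity}")
    local_cn_tumor = np.asarray(local_cn_tumor, dtype=float)
    multiplicity = np.asarray(multiplicity, dtype=float)
    if np.any(local_cn_tumor < 1) or np.any(multiplicity < 1):
        raise ValueError("local_cn_tumor and multiplicity must be >= 1")
    raw = np.asarray(vaf, dtype=float) * (
        purity * local_cn_tumor + (1.0 - purity) * 2.0
    ) / (purity * multiplicity)
    return np.clip(raw, 0.0, 1.0)


def ccf_table(
    calls: pd.DataFrame,
    purity: float,
    cn_col: str | None = None,
    mult_col: str | None = None,
) -> pd.DataFrame:
    """Annotate a kept-call table with ccf_raw / ccf_hat / clonal columns.

    ``ccf_raw`` records the pre-clamp value as a diagnostic; clonality is
    ``ccf_hat >= 0.6`` (inclusive).
    """
    out = calls.copy()
    cn = out[cn_col] if cn_col else 2.0
    mult = out[mult_col] if mult_col else 1.0
    vaf = out["vaf"].to_numpy(dtype=float)
    purity_f = float(purity)
    raw = vaf * (purity_f * np.asarray(cn, dtype=float) + (1 - purity_f) * 2.0) / (
        purity_f * np.asarray(mult, dtype=float)
    )
    out["ccf_raw"] = raw
    out["ccf_hat"] = np.clip(raw, 0.0, 1.0)
    out["clonal"] = out["ccf_hat"] >= CLONAL_CCF_MIN
    return out


@dataclass
class PairedClassification:
    """Shared/private x clonal/subclonal partition of a met/PT variant union."""

    variants: pd.DataFrame  # key, status, clonal_met, clonal_pt, label
    counts: dict[str, int]
    fractions: dict[str, float]
    shared_clonality_rule: str

    @property
    def n_shared_subclonal(self) -> int:
        return self.counts.get("shared_subclonal", 0)


def _keys(df: pd.DataFrame) -> pd.Series:
    return (
        df["chrom"].astype(str)
        + ":"
        + df["pos"].astype(int).astype(str)
        + ":"
        + df["ref"].astype(str)
        + ">"
        + df["alt"].astype(str)
    )


def classify_paired(
    met_ccf: pd.DataFrame,
    pt_ccf: pd.DataFrame,
    shared_clonality: str = "both",
    rescue_min_alt: int = 0,
) -> PairedClassification:
    """Classify the union of two kept call sets as shared / private x clonality.

    Variants are matched on (chrom, pos, ref, alt).  A shared variant is
    "shared clonal" iff clonal in both samples (``shared_clonality='both'``,
    the conservative default) or in at least one (``'either'``); private
    variants take their clonality from the sample carrying them.  With
    ``rescue_min_alt > 0``, a variant private to one sample is reclassified
    shared when the other sample shows at least that many alternate reads
    at the locus (requires an ``alt_reads_tumor`` lookup in both tables).
    """
    if shared_clonality not in ("both", "either"):
        raise ValueError("shared_clonality must be 'both' or 'either'")
    met = met_ccf.copy()
    pt = pt_ccf.copy()
    met["key"] = _keys(met)
    pt["key"] = _keys(pt)
    for name, df in (("met", met), ("pt", pt)):
        if df["key"].duplicated().any():
            dups = df.loc[df["key"].duplicated(), "key"].tolist()
            raise ValueError(f"duplicate variant keys in {name} sample: {dups}")

    met_idx = met.set_index("key")
    pt_idx = pt.set_index("key")
    shared_keys = set(met_idx.index) & set(pt_idx.index)
    private_met = set(met_idx.index) - shared_keys
    private_pt = set(pt_idx.index) - shared_keys

    if rescue_min_alt > 0:
        for key in list(private_met):
            alt = pt_idx["alt_reads_tumor"].get(key, 0) if "alt_reads_tumor" in pt_idx else 0
            if alt >= rescue_min_alt:
                private_met.discard(key)
                shared_keys.add(key)
        for key in list(private_pt):
            alt = met_idx["alt_reads_tumor"].get(key, 0) if "alt_reads_tumor" in met_idx else 0
            if alt >= rescue_min_alt:
                private_pt.discard(key)
                shared_keys.add(key)

    rows = []
    for key in sorted(shared_keys | private_met | private_pt):
        in_met = key in met_idx.index
        in_pt = key in pt_idx.index
        cl_met = bool(met_idx.at[key, "clonal"]) if in_met else None
        cl_pt = bool(pt_idx.at[key, "clonal"]) if in_pt else None
        if key in shared_keys:
            status = "shared"
            avail = [c for c in (cl_met, cl_pt) if c is not None]
            clonal = all(avail) if shared_clonality == "both" else any(avail)
        elif key in private_met:
            status, clonal = "private_met", bool(cl_met)
        else:
            status, clonal = "private_pt", bool(cl_pt)
        rows.append(
            {
                "key": key,
                "status": status,
                "clonal_met": cl_met,
                "clonal_pt": cl_pt,
                "label": f"{status}_{'clonal' if clonal else 'subclonal'}",
            }
        )
    variants = pd.DataFrame(
        rows, columns=["key", "status", "clonal_met", "clonal_pt", "label"]
    )
    labels = [
        f"{s}_{c}"
        for s in ("shared", "private_met", "private_pt")
        for c in ("clonal", "subclonal")
    ]
    counts = {lab: int((variants["label"] == lab).sum()) for lab in labels}
    total = max(len(variants), 1)
    fractions = {lab: counts[lab] / total for lab in labels}
    return PairedClassification(variants, counts, fractions, shared_clonality)


@dataclass(frozen=True)
class SeedingCall:
    verdict: str  # "polyclonal" | "indeterminate_sampling_bias"
    n_shared_subclonal: int
    n_private_clonal_met: int
    n_private_clonal_pt: int


def infer_seeding(pc: PairedClassification) -> SeedingCall:
    """Seeding verdict from a paired classification (SNVs only).

    Polyclonal iff the shared-subclonal count reaches 10; otherwise the
    verdict is indeterminate, with the private-clonal counts reported as
    evidence of within-tumor sampling bias.
    """
    n_ss = pc.counts.get("shared_subclonal", 0)
    verdict = (
        "polyclonal"
        if n_ss >= POLYCLONAL_MIN_SHARED_SUBCLONAL
        else "indeterminate_sampling_bias"
    )
    return SeedingCall(
        verdict=verdict,
        n_shared_subclonal=n_ss,
        n_private_clonal_met=pc.counts.get("private_met_clonal", 0),
        n_private_clonal_pt=pc.counts.get("private_pt_clonal", 0),
    )
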