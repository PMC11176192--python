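"""Consensus filtering of multi-caller somatic calls and genome-level metrics.

Simple somatic variants (SSVs: SNVs, small insertions/deletions, multi-base
substitutions) are kept only with evidence from at least two independent
calling algorithms.  Structural variants (SVs) additionally require read
support (>= 4 tumor alternate reads, <= 1 normal alternate read), VAF >= 0.05,
and breakpoints outside declared exclusion regions (centromeres, telomeres,
hotspots).  Downstream metrics: mutation burden per megabase, SSV type
fractions, and fraction of genome altered (FGA) from copy-number segments.

Conventions: variant positions are 1-based (VCF); segments and exclusion
regions are 0-based half-open (BED).  All filters are pure — input tables
are never mutated, and kept + rejected partition the input.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExclusionRegions",
    "consensus_filter_ssv",
    "filter_sv",
    "mutation_burden",
    "ssv_type_fractions",
    "fraction_genome_altered",
    "merge_intervals",
    "split_callers",
]

SSV_TYPES = ("SNV", "insertion", "deletion", "MBS")
MIN_CALLERS = 2
SV_MIN_ALT_TUMOR = 4
SV_MAX_ALT_NORMAL = 1
SV_MIN_VAF = 0.05


def split_callers(value) -> frozenset:
    """Normalize a caller annotation (set, list, or ';'-joined str) to a frozenset."""
    if isinstance(value, str):
        parts = [v.strip() for v in value.split(";") if v.strip()]
        return frozenset(parts)
    if value is None:
        return frozenset()
    return frozenset(value)


@dataclass
class ExclusionRegions:
    """Per-chromosome 0-based half-open intervals excluded from SV calling."""

    intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        for chrom, ivs in self.intervals.items():
            for start, end in ivs:
                if end <= start:
                    raise ValueError(
                        f"degenerate exclusion interval {chrom}:{start}-{end}"
                    )

    @classmethod
    def from_bed(cls, path) -> "ExclusionRegions":
        df = pd.read_csv(
            path, sep="\t", header=None, usecols=[0, 1, 2],
            names=["chrom", "start", "end"], comment="#",
        )
        out: dict[str, list[tuple[int, int]]] = {}
        for _, r in df.iterrows():
            out.setdefault(str(r["chrom"]), []).append((int(r["start"]), int(r["end"])))
        return cls(out)

    def contains(self, chrom: str, pos_1based: int) -> bool:
        """True if the 1-based position falls inside an excluded interval."""
        z = pos_1based - 1
        return any(s <= z < e for s, e in self.intervals.get(chrom, ()))


def consensus_filter_ssv(calls: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition SSV calls into (kept, rejected-with-reason) tables.

    A call is kept iff it has evidence from >= 2 callers and no external
    artifact flag (optional ``flags`` column; non-empty means an upstream
    artifact filter fired).  Empty caller annotations are a validation
    error.  ``rejected`` carries a ``reject_reason`` column.
    """
    calls = calls.copy()
    caller_sets = calls["callers"].map(split_callers)
    if (caller_sets.map(len) == 0).any():
        bad = calls.index[caller_sets.map(len) == 0].tolist()
        raise ValueError(f"calls with empty caller set at index {bad}")

    reasons = pd.Series("", index=calls.index, dtype=object)
    reasons[caller_sets.map(len) < MIN_CALLERS] = "single_caller"
    if "flags" in calls.columns:
        flagged = calls["flags"].fillna("").astype(str).str.len() > 0
        reasons[flagged & (reasons == "")] = "external_flag"

    kept = calls[reasons == ""].copy()
    rejected = calls[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    return kept, rejected


def filter_sv(
    svs: pd.DataFrame, regions: ExclusionRegions | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition SV calls into (kept, rejected-with-reason) tables.

    Keep iff: >= 2 algorithms, alt_reads_tumor >= 4, alt_reads_normal <= 1,
    vaf >= 0.05 (inclusive bounds), and neither breakpoint inside an
    exclusion interval.  Expected columns: chrom_a, pos_a, chrom_b, pos_b
    (1-based), algorithms, alt_reads_tumor, alt_reads_normal, vaf.
    """
    regions = regions or ExclusionRegions()
    svs = svs.copy()
    for col in ("pos_a", "pos_b"):
        if (svs[col] < 1).any():
            raise ValueError(f"malformed breakpoint: {col} < 1")

    reasons = pd.Series("", index=svs.index, dtype=object)
    algos = svs["algorithms"].map(split_callers)
    reasons[algos.map(len) < MIN_CALLERS] = "single_algorithm"

    def mark(mask, reason):
        reasons[mask & (reasons == "")] = reason

    mark(svs["alt_reads_tumor"] < SV_MIN_ALT_TUMOR, "low_tumor_support")
    mark(svs["alt_reads_normal"] > SV_MAX_ALT_NORMAL, "normal_support")
    mark(svs["vaf"] < SV_MIN_VAF, "low_vaf")
    in_excl = svs.apply(
        lambda r: regions.contains(str(r["chrom_a"]), int(r["pos_a"]))
        or regions.contains(str(r["chrom_b"]), int(r["pos_b"])),
        axis=1,
    )
    mark(in_excl, "excluded_region")

    kept = svs[reasons == ""].copy()
    rejected = svs[reasons != ""].copy()
    rejected["reject_reason"] = reasons[reasons != ""]
    return kept, rejected


def mutation_burden(kept_calls: pd.DataFrame | int, callable_mb: float) -> float:
    """Mutations per callable megabase."""
    if callable_mb <= 0:
        raise ValueError("callable span must be positive")
    n = kept_calls if isinstance(kept_calls, (int, np.integer)) else len(kept_calls)
    return n / callable_mb


def ssv_type_fractions(kept_calls: pd.DataFrame) -> dict[str, float]:
    """Fraction of kept SSVs of each type; fractions sum to 1."""
    if len(kept_calls) == 0:
        raise ValueError("cannot compute type fractions of an empty call set")
    counts = kept_calls["vtype"].value_counts()
    unknown = set(counts.index) - set(SSV_TYPES)
    if unknown:
        raise ValueError(f"unknown SSV types: {sorted(unknown)}")
    total = len(kept_calls)
    return {t: counts.get(t, 0) / total for t in SSV_TYPES}


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, as a sorted non-overlapping list."""
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def fraction_genome_altered(
    segments: pd.DataFrame, genome_spans: dict[str, int]
) -> float:
    """Merged altered span divided by total genome span.

    Overlapping segments are unioned per chromosome before summing so no
    base is counted twice and the result stays in [0, 1].  Segments are
    0-based half-open with columns chrom, start, end.
    """
    total = sum(genome_spans.values())
    if total <= 0:
        raise ValueError("genome spans must be positive")
    altered = 0
    for chrom, grp in segments.groupby("chrom"):
        if chrom not in genome_spans:
            raise ValueError(f"segment on undeclared chromosome {chrom}")
        span = genome_spans[chrom]
        ivs = list(zip(grp["start"].astype(int), grp["end"].astype(int)))
        for s, e in ivs:
            if e <= s:
                raise ValueError(f"degenerate segment {chrom}:{s}-{e}")
            if s < 0 or e > span:
                raise ValueError(f"segment {chrom}:{s}-{e} beyond chromosome end {span}")
        altered += sum(e - s for s, e in merge_intervals(ivs))
    return altered / total
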