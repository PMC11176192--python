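"""Driver identification and per-sample final-driver designation.

Candidate mutation drivers are protein-altering variants (frameshift,
missense, nonsense, splice-site) in a configurable known-driver gene list;
candidate fusion drivers are structural variants or RNA fusion transcripts
touching a listed fusion gene (the partner need not be listed).  When a
sample has several candidates the final driver is the one most recurrently
altered across the cohort, with exact ties broken lexicographically and
flagged.  Secondary events (MYC amplification, TERT-promoter mutation) are
annotated but never designated as the driver.
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "DriverGeneLists",
    "CandidateDriver",
    "FinalDriver",
    "find_candidates",
    "designate_final",
    "paired_concordance",
    "categorize",
    "DEFAULT_CATEGORY_MAP",
    "ANALYSIS_GROUPING",
    "PROTEIN_ALTERING",
]

PROTEIN_ALTERING = frozenset({"frameshift", "missense", "nonsense", "splice_site"})
SECONDARY_EVENT_GENES = frozenset({"MYC", "TERT"})

RTK_GENES = frozenset({"NTRK1", "NTRK3", "ALK", "LTK", "MET", "FGFR2"})
RAS_GENES = frozenset({"NRAS", "HRAS", "KRAS"})

#: gene/mechanism -> fine-grained driver category
DEFAULT_CATEGORY_MAP = {
    ("BRAF", "mutation"): "BRAF_mutation",
    ("BRAF", "fusion"): "BRAF_fusion",
    ("RET", "fusion"): "RET_fusion",
    **{(g, "fusion"): "other_RTK_fusion" for g in RTK_GENES},
    **{(g, "mutation"): "RAS_mutation" for g in RAS_GENES},
}

#: fine category -> 5-level analysis grouping used in cohort crosstabs
#: (BRAF fusions fold into other_fusion, RAS into other_mutation)
ANALYSIS_GROUPING = {
    "BRAF_mutation": "BRAF_mutation",
    "RAS_mutation": "other_mutation",
    "other_mutation": "other_mutation",
    "RET_fusion": "RET_fusion",
    "other_RTK_fusion": "other_RTK_fusion",
    "BRAF_fusion": "other_fusion",
    "other_fusion": "other_fusion",
}


@dataclass
class DriverGeneLists:
    """Known driver genes by mechanism, with free-text provenance."""

    mutation_genes: frozenset
    fusion_genes: frozenset
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mutation_genes = frozenset(g.upper() for g in self.mutation_genes)
        self.fusion_genes = frozenset(g.upper() for g in self.fusion_genes)
        if not self.mutation_genes and not self.fusion_genes:
            raise ValueError("driver gene lists are empty")

    @classmethod
    def default(cls) -> "DriverGeneLists":
        """Frozen list packaged with the repo (editable TSV)."""
        ref = importlib.resources.files("metseed.data").joinpath("driver_genes.tsv")
        with importlib.resources.as_file(ref) as path:
            return cls.from_tsv(path)

    @classmethod
    def from_tsv(cls, path) -> "DriverGeneLists":
        df = pd.read_csv(path, sep="\t")
        mut = df.loc[df["mechanism"] == "mutation", "gene"]
        fus = df.loc[df["mechanism"] == "fusion", "gene"]
        prov = {
            (r["gene"].upper(), r["mechanism"]): r.get("provenance", "")
            for _, r in df.iterrows()
        }
        return cls(frozenset(mut), frozenset(fus), prov)


@dataclass(frozen=True)
class CandidateDriver:
    gene: str
    mechanism: str  # "mutation" | "fusion"
    detail: str = ""
    evidence_sources: frozenset = frozenset()


@dataclass(frozen=True)
class FinalDriver:
    gene: str
    mechanism: str
    detail: str = ""
    category: str = ""
    ambiguous_tie: bool = False


def find_candidates(
    variants: pd.DataFrame | None,
    fusions: pd.DataFrame | None,
    lists: DriverGeneLists,
) -> list[CandidateDriver]:
    """Candidate drivers from annotated variant and fusion evidence.

    ``variants`` needs gene/consequence columns (plus optional
    protein_change); ``fusions`` needs gene_a/gene_b (plus optional
    source).  Consequence matching is restricted to protein-altering
    classes; fusions qualify when either partner is a listed fusion gene.
    Duplicate (gene, mechanism) evidence collapses to one candidate.
    """
    seen: dict[tuple[str, str], CandidateDriver] = {}
    if variants is not None and len(variants):
        if "gene" not in variants.columns or "consequence" not in variants.columns:
            raise ValueError("variant table must carry gene and consequence columns")
        for _, r in variants.iterrows():
            gene = str(r["gene"]).upper()
            cons = str(r["consequence"]).lower().replace("-", "_").replace(" ", "_")
            if cons in PROTEIN_ALTERING and gene in lists.mutation_genes:
                key = (gene, "mutation")
                if key not in seen:
                    seen[key] = CandidateDriver(
                        gene,
                        "mutation",
                        detail=str(r.get("protein_change", "") or ""),
                        evidence_sources=frozenset({str(r.get("source", "wgs") or "wgs")}),
                    )
    if fusions is not None and len(fusions):
        if "gene_a" not in fusions.columns or "gene_b" not in fusions.columns:
            raise ValueError("fusion table must carry gene_a and gene_b columns")
        for _, r in fusions.iterrows():
            a, b = str(r["gene_a"]).upper(), str(r["gene_b"]).upper()
            listed = [g for g in (a, b) if g in lists.fusion_genes]
            for gene in listed:
                key = (gene, "fusion")
                if key not in seen:
                    partner = b if gene == a else a
                    seen[key] = CandidateDriver(
                        gene,
                        "fusion",
                        detail=f"{a}-{b}" if partner else "",
                        evidence_sources=frozenset({str(r.get("source", "wgs") or "wgs")}),
                    )
    return sorted(seen.values(), key=lambda c: (c.gene, c.mechanism))


def designate_final(
    candidates: list[CandidateDriver],
    cohort_recurrence: dict[str, int],
    category_map: dict | None = None,
) -> FinalDriver | None:
    """Pick one final driver per sample.

    No candidate -> None; a sole candidate is designated directly; with
    several, the gene most recurrently altered across the full cohort
    wins, exact recurrence ties going to the lexicographically first gene
    with ``ambiguous_tie=True``.  Deterministic and independent of
    candidate input order.
    """
    if not candidates:
        return None
    if len(candidates) == 1:
        chosen, tie = candidates[0], False
    else:
        ranked = sorted(
            candidates,
            key=lambda c: (-cohort_recurrence.get(c.gene, 0), c.gene, c.mechanism),
        )
        chosen = ranked[0]
        top = cohort_recurrence.get(chosen.gene, 0)
        tie = (
            sum(1 for c in candidates if cohort_recurrence.get(c.gene, 0) == top) > 1
        )
    return FinalDriver(
        gene=chosen.gene,
        mechanism=chosen.mechanism,
        detail=chosen.detail,
        category=categorize(chosen.gene, chosen.mechanism, category_map),
        ambiguous_tie=tie,
    )


def categorize(
    gene: str, mechanism: str, category_map: dict | None = None
) -> str:
    """Map a (gene, mechanism) to its reporting category.

    Unmapped genes fall back to other_mutation / other_fusion by
    mechanism.
    """
    cmap = DEFAULT_CATEGORY_MAP if category_map is None else category_map
    key = (gene.upper(), mechanism)
    if key in cmap:
        return cmap[key]
    return "other_mutation" if mechanism == "mutation" else "other_fusion"


def paired_concordance(
    pairs: list[tuple[FinalDriver | None, FinalDriver | None]],
) -> tuple[float, list[int]]:
    """Fraction of pairs whose met and PT designations agree on (gene, mechanism).

    Pairs with a missing designation on either side are excluded from the
    denominator; returns ``(fraction, discordant_indices)``.
    """
    if not pairs:
        raise ValueError("no pairs provided")
    usable, discordant = 0, []
    for i, (met, pt) in enumerate(pairs):
        if met is None or pt is None:
            continue
        usable += 1
        if (met.gene, met.mechanism) != (pt.gene, pt.mechanism):
            discordant.append(i)
    if usable == 0:
        raise ValueError("no pairs with both members designated")
    return 1.0 - len(discordant) / usable, discordant
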