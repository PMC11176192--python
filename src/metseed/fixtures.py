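"""Reference tables transcribed from the calibration cohort.

The package's defaults are calibrated to a published series of 440
adolescent and young-adult papillary thyroid carcinomas (PTC) from
Ukraine, 428 of which carry a single designated driver.  Two small
tables bundled with the package transcribe the printed driver-by-cLNM
contingency counts and the fusion-partner breakdown; a builder expands
them (and the printed TNM staging margins) into per-subject rows so
the crosstab and cohort-summary code paths can be exercised against
the published percentages without any external data.
"""
from __future__ import annotations

import importlib.resources

import pandas as pd

__all__ = [
    "driver_clnm_counts",
    "fusion_partner_counts",
    "reference_driver_cohort",
    "reference_staging_cohort",
]


def _read_packaged(name: str) -> pd.DataFrame:
    ref = importlib.resources.files("metseed.data").joinpath(name)
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def driver_clnm_counts() -> pd.DataFrame:
    """Driver-category x cLNM counts for the 428 driver-designated PTC."""
    return _read_packaged("driver_clnm_counts.tsv")


def fusion_partner_counts() -> pd.DataFrame:
    """Fusion-partner x cLNM counts nested within the fusion categories."""
    return _read_packaged("fusion_partner_counts.tsv")


def expand_counts(
    counts: pd.DataFrame, n_event: str = "n_clnm", n_total: str = "n_total"
) -> pd.DataFrame:
    """Expand an aggregated count table into one row per subject.

    Every column other than ``n_event``/``n_total`` is carried over; a
    boolean ``clnm`` column encodes event status.
    """
    keep = [c for c in counts.columns if c not in (n_event, n_total)]
    rows = []
    for _, r in counts.iterrows():
        n_ev, n_tot = int(r[n_event]), int(r[n_total])
        if not 0 <= n_ev <= n_tot:
            raise ValueError(f"event count {n_ev} outside [0, {n_tot}]")
        base = {c: r[c] for c in keep}
        rows.extend([{**base, "clnm": True}] * n_ev)
        rows.extend([{**base, "clnm": False}] * (n_tot - n_ev))
    return pd.DataFrame(rows)


def reference_driver_cohort() -> pd.DataFrame:
    """One row per driver-designated tumor (N = 428), with partner detail.

    Fusion-partner labels are nested consistently inside the driver
    categories, so partner-level and category-level crosstabs computed
    from this table agree with the bundled aggregated counts.
    """
    partners = expand_counts(fusion_partner_counts())
    partners = partners.rename(columns={"parent_category": "driver_category"})
    partners["mechanism"] = "fusion"
    cats = expand_counts(driver_clnm_counts()).rename(
        columns={"category": "driver_category"}
    )
    # Non-RET / non-RTK categories have no partner breakdown.
    rest = cats[~cats["driver_category"].isin(["RET_fusion", "other_RTK_fusion"])]
    rest = rest.assign(partner_group=pd.NA)
    out = pd.concat([partners, rest], ignore_index=True)
    out.insert(0, "subject_id", [f"REF{i:04d}" for i in range(len(out))])
    return out


def reference_staging_cohort() -> pd.DataFrame:
    """One row per subject (N = 440) with the printed TNM nodal/metastasis margins.

    Margins: 87 N1a, 91 N1b (14 of the nodal-positive also M1), one
    N0M1 subject, and 261 N0M0.  Only staging-derived fields are
    populated; driver and exposure fields are not part of this table.
    """
    rows = []
    for n_stage, m_stage, n in [
        ("N1a", "M0", 87),
        ("N1b", "M1", 14),
        ("N1b", "M0", 77),
        ("N0", "M1", 1),
        ("N0", "M0", 261),
    ]:
        rows.extend([{"n_stage": n_stage, "m_stage": m_stage}] * n)
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", [f"STG{i:04d}" for i in range(len(df))])
    df["clnm"] = df["n_stage"].isin(["N1a", "N1b"])
    df["any_metastasis"] = df["clnm"] | (df["m_stage"] == "M1")
    return df
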