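"""Stage orchestration: simulate -> filter -> clonality -> drivers -> associate -> de.

A run is described by a YAML/dict config naming the stages to execute, a
root seed, and per-stage parameter blocks.  Each stage writes its outputs
under the run directory and records a manifest entry (parameters, output
files with SHA-256 checksums), so reruns with an unchanged config skip
completed stages and corrupted intermediates are detected by checksum.
:func:`cohort_report` assembles the cohort-level summary tables from
whatever stage outputs are present.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import clonality, cohortgen, drivers, epi, expression, somatic

logger = logging.getLogger("metseed")

STAGE_ORDER = ["simulate", "filter", "clonality", "drivers", "associate", "de"]

DEFAULT_CONFIG = {
    "seed": 0,
    "stages": STAGE_ORDER,
    "simulate": {"n_subjects": 440, "n_pairs": 8},
    "filter": {},
    "clonality": {"shared_clonality": "both", "rescue_min_alt": 0},
    "drivers": {},
    "associate": {"dose_terms": "linear"},
    "de": {
        "n_genes": 400,
        "n_met": 45,
        "n_pt": 130,
        "spikes": [["G0000", 3.4], ["G0001", -3.6]],
    },
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = [s for s in cfg["stages"] if s not in STAGE_ORDER]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    cfg["stages"] = [s for s in STAGE_ORDER if s in cfg["stages"]]
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _params_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True).encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


def run_pipeline(config, out_dir) -> dict:
    """Execute the configured stages; return (and write) the run manifest.

    Idempotent: a stage is skipped when the manifest already records it
    with the same parameter hash and every output file still matches its
    checksum; a mismatch raises naming the corrupted file.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )

    runners = {
        "simulate": _stage_simulate,
        "filter": _stage_filter,
        "clonality": _stage_clonality,
        "drivers": _stage_drivers,
        "associate": _stage_associate,
        "de": _stage_de,
    }
    for stage in cfg["stages"]:
        params = {"seed": cfg["seed"], **cfg.get(stage, {})}
        phash = _params_hash(params)
        entry = manifest["stages"].get(stage)
        if entry and entry["params_hash"] == phash:
            for f, digest in entry["outputs"].items():
                fp = out / f
                if not fp.exists():
                    raise PipelineError(f"manifest lists missing file {f}")
                if _sha256(fp) != digest:
                    raise PipelineError(f"checksum mismatch for {f}; remove it to rerun")
            logger.info("stage %s: up to date, skipping", stage)
            continue
        logger.info("stage %s: running", stage)
        try:
            files = runners[stage](params, out)
        except Exception as exc:  # annotate failing stage
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "params": params,
            "params_hash": phash,
            "outputs": {f: _sha256(out / f) for f in files},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# --- stages ----------------------------------------------------------------


def _stage_simulate(params: dict, out: Path) -> list[str]:
    seed = params["seed"]
    subjects, _ = cohortgen.generate_cohort(
        cohortgen.CohortConfig(n_subjects=params.get("n_subjects", 440), seed=seed)
    )
    subjects.to_csv(out / "cohort.tsv", sep="\t", index=False)
    files = ["cohort.tsv"]
    for i in range(params.get("n_pairs", 8)):
        met, pt, truth = cohortgen.generate_paired_variants(
            cohortgen.PairedConfig(seed=seed * 1000 + i)
        )
        met.to_csv(out / f"pair{i}_met.tsv", sep="\t", index=False)
        pt.to_csv(out / f"pair{i}_pt.tsv", sep="\t", index=False)
        truth.variants.to_csv(out / f"pair{i}_truth.tsv", sep="\t", index=False)
        files += [f"pair{i}_met.tsv", f"pair{i}_pt.tsv", f"pair{i}_truth.tsv"]
    return files


def _iter_pairs(out: Path):
    i = 0
    while (out / f"pair{i}_met.tsv").exists():
        yield i
        i += 1


def _stage_filter(params: dict, out: Path) -> list[str]:
    files = []
    for i in _iter_pairs(out):
        for member in ("met", "pt"):
            calls = pd.read_csv(out / f"pair{i}_{member}.tsv", sep="\t")
            kept, rejected = somatic.consensus_filter_ssv(calls)
            kept.to_csv(out / f"pair{i}_{member}_kept.tsv", sep="\t", index=False)
            rejected.to_csv(out / f"pair{i}_{member}_rejected.tsv", sep="\t", index=False)
            files += [f"pair{i}_{member}_kept.tsv", f"pair{i}_{member}_rejected.tsv"]
    if not files:
        raise PipelineError("no simulated pairs found; run the simulate stage first")
    return files


def _stage_clonality(params: dict, out: Path) -> list[str]:
    rows = []
    for i in _iter_pairs(out):
        tables = {}
        for member in ("met", "pt"):
            kept = pd.read_csv(out / f"pair{i}_{member}_kept.tsv", sep="\t")
            est = clonality.estimate_purity(kept["vaf"])
            tables[member] = clonality.ccf_table(kept, est.purity)
        pc = clonality.classify_paired(
            tables["met"],
            tables["pt"],
            shared_clonality=params.get("shared_clonality", "both"),
            rescue_min_alt=params.get("rescue_min_alt", 0),
        )
        call = clonality.infer_seeding(pc)
        rows.append(
            {
                "pair": i,
                "verdict": call.verdict,
                "n_shared_subclonal": call.n_shared_subclonal,
                "n_private_clonal_met": call.n_private_clonal_met,
                "n_private_clonal_pt": call.n_private_clonal_pt,
            }
        )
    if not rows:
        raise PipelineError("no filtered pairs found; run the filter stage first")
    pd.DataFrame(rows).to_csv(out / "seeding.tsv", sep="\t", index=False)
    return ["seeding.tsv"]


def _stage_drivers(params: dict, out: Path) -> list[str]:
    subjects = pd.read_csv(out / "cohort.tsv", sep="\t")
    lists = drivers.DriverGeneLists.default()
    evidence = cohortgen.driver_evidence_tables(subjects, seed=params["seed"])
    recurrence = subjects["driver_gene"].value_counts().to_dict()
    pairs, rows = [], []
    for sid, tabs in evidence.items():
        met = drivers.designate_final(
            drivers.find_candidates(tabs["met_variants"], tabs["met_fusions"], lists),
            recurrence,
        )
        pt = drivers.designate_final(
            drivers.find_candidates(tabs["pt_variants"], tabs["pt_fusions"], lists),
            recurrence,
        )
        pairs.append((met, pt))
        rows.append(
            {
                "subject_id": sid,
                "met_driver": met.gene if met else "",
                "pt_driver": pt.gene if pt else "",
                "category": met.category if met else "",
            }
        )
    frac, discordant = drivers.paired_concordance(pairs)
    pd.DataFrame(rows).to_csv(out / "drivers.tsv", sep="\t", index=False)
    (out / "concordance.json").write_text(
        json.dumps({"concordance": frac, "n_pairs": len(pairs), "discordant": discordant})
    )
    return ["drivers.tsv", "concordance.json"]


def _stage_associate(params: dict, out: Path) -> list[str]:
    subjects, _ = epi.ingest_cohort(pd.read_csv(out / "cohort.tsv", sep="\t"))
    ct = epi.crosstab(subjects)
    ct.to_csv(out / "crosstab.tsv", sep="\t")
    design = pd.DataFrame(
        {
            "male": (subjects["sex"] == "M").astype(float),
            "age_at_ptc": subjects["age_at_ptc"].astype(float),
        },
        index=subjects.index,
    )
    res = epi.fit_eor(
        subjects["clnm"].astype(float),
        subjects["dose_Gy_trunc"],
        design,
        dose_terms=params.get("dose_terms", "linear"),
    )
    # quasi-separated categories (no events or all events at small n) make
    # the heterogeneity LRT unidentifiable; drop them before testing
    ev = subjects.groupby("driver_category")["clnm"].agg(["sum", "count"])
    informative = ev[(ev["sum"] > 0) & (ev["sum"] < ev["count"])].index
    het_p = None
    if len(informative) >= 2:
        try:
            het_p = epi.heterogeneity_test(
                subjects[subjects["driver_category"].isin(informative)]
            ).p
        except (ValueError, RuntimeError) as exc:
            logger.warning("heterogeneity test skipped: %s", exc)
    fit = {
        "params": {k: float(v) for k, v in res.params.items()},
        "loglik": res.loglik,
        "theta1_ci": list(res.theta1_ci),
        "dose_trend_p": res.dose_trend_lrt().p,
        "heterogeneity_p": het_p,
    }
    (out / "association.json").write_text(json.dumps(fit, indent=2))
    return ["crosstab.tsv", "association.json"]


def _stage_de(params: dict, out: Path) -> list[str]:
    spikes = tuple((g, float(f)) for g, f in params.get("spikes", []))
    counts, meta, _ = cohortgen.generate_counts(
        cohortgen.CountsConfig(
            n_genes=params.get("n_genes", 400),
            n_met=params.get("n_met", 45),
            n_pt=params.get("n_pt", 130),
            spike_table=spikes,
            seed=params["seed"],
        )
    )
    s = expression.uq_size_factors(counts)
    Y = expression.log_normalize(counts, s)
    res = expression.de_linear_model(Y, meta)
    res.table.to_csv(out / "de.tsv", sep="\t")
    return ["de.tsv"]


# --- report ----------------------------------------------------------------


def cohort_report(out_dir) -> str:
    """Assemble a markdown summary from available stage outputs.

    Sections (driver crosstab, seeding verdicts, driver concordance,
    top differentially expressed genes) are included when their stage
    output exists and marked absent otherwise.
    """
    out = Path(out_dir)
    lines = ["# Cohort report", ""]

    def section(title, fname, render):
        lines.append(f"## {title}")
        path = out / fname
        if path.exists():
            lines.append(render(path))
        else:
            lines.append(f"_absent: {fname} not produced by any completed stage_")
        lines.append("")

    section(
        "Driver x cLNM crosstab",
        "crosstab.tsv",
        lambda p: pd.read_csv(p, sep="\t").to_string(index=False),
    )
    section(
        "Metastasis seeding verdicts",
        "seeding.tsv",
        lambda p: pd.read_csv(p, sep="\t").to_string(index=False),
    )
    section(
        "Paired driver concordance",
        "concordance.json",
        lambda p: json.dumps(json.loads(p.read_text())),
    )
    section(
        "Top differentially expressed genes",
        "de.tsv",
        lambda p: pd.read_csv(p, sep="\t")
        .sort_values("p_adj")
        .head(10)
        .to_string(index=False),
    )
    report = "\n".join(lines)
    (out / "report.md").write_text(report)
    return report
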