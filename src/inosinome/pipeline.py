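"""End-to-end orchestration: cohort directory in, analysis directory out.

The stages run in the order the method is defined: read the per-sample count
tables and annotations, annotate site classes, build and filter the editing
matrix, compute per-sample indexes, call differential recoding sites, stratify
tumors into INO groups (discovering the subtype-differential DEI site list on
the way), ordinate the cohort, and test survival associations.  Every run
echoes its effective configuration and writes a manifest of stages, record
counts and the seed, so two runs from the same inputs are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .model import (
    ALU,
    EditingMatrix,
    RegionSet,
    SiteCatalog,
    SNPMask,
    annotate_site_class,
    build_editing_matrix,
    read_clinical_table,
    read_reditools_table,
)
from .indexes import compute_dei, index_profiles
from .differential import (
    differential_editing_table,
    direction_summary,
    filter_informative_sites,
    top_sites,
)
from .stratify import (
    discover_subtype_differential_sites,
    merge_tree_to_newick,
    nmds_ordination,
    stratify_inosinome,
)
from .survival import cox_ph_fit, gender_stratified_survival, logrank_test

log = logging.getLogger("inosinome")

STAGES = ["read", "annotate", "matrix", "indexes", "differential",
          "stratify", "ordinate", "survival"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class PipelineConfig:
    """Inputs, thresholds and provenance knobs for one full run."""

    tables_dir: str
    catalog: str
    alu_bed: str
    outdir: str
    rep_bed: str | None = None
    snp_mask: str | None = None
    clinical: str | None = None
    # thresholds (defaults are the standard site-calling rules)
    min_coverage: int = 10
    min_frequency: float = 0.01
    min_per_group: int = 2
    alpha: float = 0.05
    delta_median_top: float = 0.15
    min_detected_fraction: float = 140 / 145
    site_survival_cutoff: float = 0.40
    seed: int = 0
    skip_survival: bool = False
    skip_ordination: bool = False
    nmds_restarts: int = 8

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 <= self.min_frequency <= 1:
            raise ValueError("min_frequency must lie in [0, 1]")
        if self.min_coverage < 0 or self.min_per_group < 0:
            raise ValueError("thresholds must be non-negative")


def validate_inputs(config: PipelineConfig) -> list[dict[str, str]]:
    """Pre-flight consistency checks; returns issues, never raises."""
    issues: list[dict[str, str]] = []

    def issue(kind: str, detail: str) -> None:
        issues.append({"issue": kind, "detail": detail})

    tables_dir = Path(config.tables_dir)
    if not tables_dir.is_dir():
        issue("missing input", f"tables directory {tables_dir} not found")
        table_samples: set[str] = set()
    else:
        tables = sorted(tables_dir.glob("*.tsv"))
        table_samples = {p.stem for p in tables}
        if not tables:
            issue("no samples", f"no .tsv tables in {tables_dir}")
        for p in tables[:3]:  # header conformity spot check
            with open(p) as fh:
                line = fh.readline()
                while line.startswith("#"):
                    line = fh.readline()
            if "Position" not in line or "BaseCount" not in line:
                issue("bad header", f"{p.name} lacks caller-table columns")
    for name in ("catalog", "alu_bed", "rep_bed", "snp_mask", "clinical"):
        path = getattr(config, name)
        if path is not None and not Path(path).is_file():
            issue("missing input", f"{name} file {path} not found")
    if config.clinical and Path(config.clinical).is_file() and table_samples:
        try:
            clin = read_clinical_table(config.clinical)
        except Exception as exc:  # malformed clinical is an issue, not a crash
            issue("bad clinical table", str(exc))
        else:
            for s in sorted(table_samples - set(clin["sample_id"])):
                issue("unmatched sample", f"{s} has counts but no clinical row")
            for s in sorted(set(clin["sample_id"]) - table_samples):
                issue("unmatched sample", f"{s} has clinical row but no counts")
    return issues


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format="%.10g")


def run_full_analysis(config: PipelineConfig) -> Path:
    """Execute all stages; returns the output directory.

    Any stage failure raises :class:`PipelineError` (stage name + cause),
    leaves partial outputs in place and drops a ``FAILED`` marker file.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest: dict[str, object] = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    (outdir / "config.json").write_text(
        json.dumps(dataclasses.asdict(config), indent=1, sort_keys=True))

    state: dict[str, object] = {}
    stage_fns = {
        "read": _stage_read,
        "annotate": _stage_annotate,
        "matrix": _stage_matrix,
        "indexes": _stage_indexes,
        "differential": _stage_differential,
        "stratify": _stage_stratify,
        "ordinate": _stage_ordinate,
        "survival": _stage_survival,
    }
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            info = stage_fns[stage](config, state, outdir)
            info["seconds"] = round(time.perf_counter() - t0, 3)
            manifest["stages"][stage] = info  # type: ignore[index]
            log.info("stage %s done in %.2fs: %s", stage, info["seconds"], info)
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{stage}: {exc}\n")
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=str))
        log.error("stage %s failed: %s", stage, exc)
        log.removeHandler(handler)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str))
    log.removeHandler(handler)
    handler.close()
    return outdir


# -- individual stages -------------------------------------------------------


def _stage_read(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    tables = {}
    skipped = 0
    for path in sorted(Path(config.tables_dir).glob("*.tsv")):
        res = read_reditools_table(path)
        tables[path.stem] = res.measurements
        skipped += res.n_skipped_non_a
    if not tables:
        raise ValueError(f"no count tables found in {config.tables_dir}")
    state["tables"] = tables
    state["catalog"] = SiteCatalog.from_tsv(config.catalog)
    state["regions"] = RegionSet.from_beds(config.alu_bed, config.rep_bed)
    state["snps"] = (SNPMask.from_tsv(config.snp_mask)
                     if config.snp_mask else None)
    state["clinical"] = (read_clinical_table(config.clinical)
                         if config.clinical and not config.skip_survival
                         else None)
    return {"n_samples": len(tables), "n_catalog_sites": len(state["catalog"]),
            "n_skipped_non_a": skipped}


def _stage_annotate(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    catalog = annotate_site_class(state["catalog"], state["regions"])
    state["catalog"] = catalog
    catalog.to_tsv(outdir / "catalog_annotated.tsv")
    return {"class_counts": catalog.class_counts()}


def _stage_matrix(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    matrix = build_editing_matrix(state["tables"], state["catalog"])
    state["matrix"] = matrix
    state["groups"] = _condition_groups(state, matrix)
    informative = filter_informative_sites(
        matrix, state["groups"], config.min_coverage, config.min_frequency,
        config.min_per_group) if state["groups"] else []
    state["informative"] = informative
    matrix.write(outdir / "editing_freq.tsv", outdir / "editing_cov.tsv")
    return {"n_samples": len(matrix.samples), "n_sites": len(matrix.sites),
            "n_informative": len(informative),
            "n_off_catalog": getattr(matrix, "n_dropped_off_catalog", 0)}


def _condition_groups(state: dict, matrix: EditingMatrix) -> dict | None:
    clinical = state.get("clinical")
    if clinical is not None:
        tumors = [s for s in matrix.samples
                  if s in clinical.index and clinical.loc[s, "condition"] == "tumor"]
        normals = [s for s in matrix.samples
                   if s in clinical.index and clinical.loc[s, "condition"] == "normal"]
    else:  # fall back on the simulator's naming convention
        tumors = [s for s in matrix.samples if s.startswith("T")]
        normals = [s for s in matrix.samples if s.startswith("N")]
    if not tumors or not normals:
        return None
    return {"tumor": tumors, "normal": normals}


def _stage_indexes(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    profiles = index_profiles(state["tables"], state["catalog"],
                              state["regions"], state["snps"],
                              min_coverage=config.min_coverage)
    state["profiles"] = profiles
    _write(profiles, outdir / "index_profiles.tsv")
    return {"n_samples": len(profiles),
            "median_aei": float(np.nanmedian(profiles["aei"]))}


def _stage_differential(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    if state["groups"] is None:
        return {"skipped": "no tumor/normal partition available"}
    table = differential_editing_table(
        state["matrix"], state["groups"], alpha=config.alpha,
        min_coverage=config.min_coverage, min_frequency=config.min_frequency,
        min_per_group=config.min_per_group, sites=state["informative"])
    state["differential"] = table
    _write(table, outdir / "differential_sites.tsv")
    _write(direction_summary(table), outdir / "differential_summary.tsv")
    _write(top_sites(table, config.delta_median_top, config.alpha),
           outdir / "differential_top_sites.tsv")
    n_sig = int((table["q_value"] <= config.alpha).sum()) if len(table) else 0
    return {"n_tested": len(table), "n_significant": n_sig}


def _stage_stratify(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    matrix: EditingMatrix = state["matrix"]
    groups = state["groups"]
    tumors = groups["tumor"] if groups else matrix.samples
    tumor_matrix = EditingMatrix(matrix.freq.loc[tumors].copy(),
                                 matrix.cov.loc[tumors].copy(),
                                 list(matrix.sites))
    result = stratify_inosinome(tumor_matrix,
                                min_detected=config.min_detected_fraction)
    state["ino"] = result
    result.labels.rename_axis("sample_id").reset_index().to_csv(
        outdir / "ino_labels.tsv", sep="\t", index=False)
    (outdir / "ino_dendrogram.nwk").write_text(
        merge_tree_to_newick(result.merge_tree, tumors) + "\n")
    info: dict[str, object] = {
        "n_signature_sites": len(result.sites_used),
        "n_imputed": result.n_imputed,
        "cluster_sizes": result.labels.value_counts().to_dict(),
    }
    clinical = state.get("clinical")
    if clinical is not None and "subtype" in clinical.columns:
        subtypes = clinical.loc[[s for s in tumors if s in clinical.index],
                                "subtype"].replace("NA", np.nan).dropna()
        if subtypes.nunique() >= 2:
            dei_sites = discover_subtype_differential_sites(
                tumor_matrix, subtypes, alpha=config.alpha,
                min_coverage=config.min_coverage,
                min_frequency=config.min_frequency)
            state["dei_sites"] = dei_sites
            SiteCatalog(dei_sites).to_tsv(outdir / "dei_sites.tsv")
            profiles = state["profiles"]
            dei = {s: compute_dei(state["tables"][s], dei_sites,
                                  config.min_coverage).value
                   for s in profiles.index}
            profiles["dei"] = pd.Series(dei)
            _write(profiles, outdir / "index_profiles.tsv")
            info["n_dei_sites"] = len(dei_sites)
    return info


def _stage_ordinate(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    if config.skip_ordination:
        return {"skipped": "ordination disabled"}
    matrix: EditingMatrix = state["matrix"]
    # restrict to sites seen in most samples so rank correlations are stable
    detected = matrix.freq.notna().mean(axis=0) >= 0.8
    sub = [s for s in matrix.sites if detected[s.label]]
    if len(sub) < 10:
        return {"skipped": "too few broadly detected sites"}
    result = nmds_ordination(matrix.restrict(sub), n_dims=2, seed=config.seed,
                             n_restarts=config.nmds_restarts)
    state["ordination"] = result
    _write(result.coords.rename_axis("sample_id").reset_index(),
           outdir / "nmds_coords.tsv")
    return {"stress": round(result.stress, 6), "n_sites": len(sub),
            "n_iterations": len(result.stress_trace)}


def _stage_survival(config: PipelineConfig, state: dict, outdir: Path) -> dict:
    clinical = state.get("clinical")
    if config.skip_survival or clinical is None:
        return {"skipped": "no clinical metadata"}
    profiles = state["profiles"]
    tumors = clinical[(clinical["condition"] == "tumor")
                      & clinical["os_time"].notna()]
    if len(tumors) < 8:
        return {"skipped": f"only {len(tumors)} tumors with outcome"}
    aei = profiles["aei"].reindex(tumors.index)
    fits = gender_stratified_survival(tumors, aei, split="per_sex_median")
    rows = []
    for sex, fit in fits.items():
        hr_row = fit.cox_terms.iloc[0]
        rows.append({"sex": sex, "metric": "aei", "n": fit.n,
                     "n_events": fit.n_events, "threshold": fit.threshold,
                     "logrank_chi2": fit.logrank_chi2,
                     "logrank_p": fit.logrank_p,
                     "hr_high_vs_low": hr_row["hr"],
                     "hr_ci_lower": hr_row["ci_lower"],
                     "hr_ci_upper": hr_row["ci_upper"]})
        for grp, curve in fit.km_curves.items():
            _write(curve, outdir / f"km_{sex}_{grp}.tsv")
    out: dict[str, object] = {}
    if rows:
        _write(pd.DataFrame(rows), outdir / "survival_sex_stratified.tsv")
        out["sex_strata"] = [r["sex"] for r in rows]
    # multivariate Cox with molecular covariates + AEI, per the risk model
    covs = [c for c in ("tp53_mutant", "idh_mutant", "mgmt_methylated",
                        "chr7gain_chr10loss") if c in tumors.columns]
    design = tumors[covs].astype(float).copy()
    design["aei"] = aei
    usable = [c for c in design.columns if design[c].dropna().nunique() > 1]
    cox = cox_ph_fit(tumors["os_time"], tumors["os_event"], design[usable],
                     mode="multivariate")
    cox_uni = cox_ph_fit(tumors["os_time"], tumors["os_event"], design[usable],
                         mode="univariate_each")
    _write(pd.concat([cox, cox_uni]), outdir / "cox_terms.tsv")
    # INO-group survival in females (the stratification's clinical readout)
    ino = state.get("ino")
    if ino is not None:
        females = [s for s in ino.labels.index
                   if s in tumors.index and tumors.loc[s, "sex"] == "female"]
        labels = ino.labels.loc[females]
        if labels.nunique() == 2 and len(females) >= 8:
            chi2, p = logrank_test(tumors.loc[females, "os_time"],
                                   tumors.loc[females, "os_event"], labels)
            out["ino_female_logrank_p"] = round(float(p), 6)
            (outdir / "ino_female_survival.json").write_text(json.dumps(
                {"chi2": chi2, "p": p, "n": len(females)}, indent=1))
    out["n_cox_terms"] = int(len(cox))
    return out


def main_logging_setup(verbose: bool = True) -> None:
    logging.basicConfig(stream=sys.stderr,
                        level=logging.INFO if verbose else logging.WARNING,
                        format="%(levelname)s %(name)s: %(message)s")
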