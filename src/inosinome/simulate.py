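"""Synthetic editing cohorts with known ground truth.

Real inosinome cohorts live behind controlled-access repositories, so the
package ships a generator that reproduces the *statistical shape* those
analyses assume, at desk scale:

* a site catalog on synthetic chromosomes with ALU / REP / NONREP classes,
  recoding flags, genic features, emitted Alu/repeat BED intervals and a
  decoy SNP mask (heterozygous DNA variants inside Alu elements that mimic
  editing until masked);
* per-sample base-count tables in the caller dialect the readers accept:
  coverage is negative-binomial, the biological editing rate of sample s at
  site j is ``expit(site baseline + tumor shift + cluster shift + sample
  offset + jitter)`` — a logit-normal/binomial hierarchy, i.e. beta-binomial-
  like overdispersion with analytically tractable means — and edited reads
  are binomial in the A+G read portion;
* tumors carry a broad under-editing shift on most sites, a couple of
  planted over-edited recoding sites, and a two-cluster substructure
  (cluster A more edited at a block of signature sites) for stratification
  recovery;
* clinical metadata with exponential overall survival whose log-hazard is
  ``beta_sex * z(AEI)`` — opposite signs by sex by default — plus uniform
  censoring and independent binary molecular covariates.

Every random draw flows from the single seed in the config; files written by
:func:`simulate_cohort` record that seed in a header comment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .model import (
    ALU,
    NONREP,
    REP,
    GenomicSite,
    RegionSet,
    SiteCatalog,
    SiteMeasurement,
    SNPMask,
    write_clinical_table,
    write_reditools_table,
)

_AA_CHANGES = ("I/V", "Q/R", "K/R", "E/G", "R/G", "Y/C", "I/M", "S/G")


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    seed: int = 0
    # cohort size (desk-scale defaults; tumor-heavy like real GBM cohorts)
    n_tumor: int = 60
    n_normal: int = 40
    n_astrocyte: int = 0
    # catalog composition
    n_alu_sites: int = 250
    n_rep_sites: int = 50
    n_nonrep_sites: int = 200
    recoding_frac_alu: float = 0.10
    recoding_frac_rep: float = 0.05
    recoding_frac_nonrep: float = 0.40
    snp_decoy_fraction: float = 0.02  # decoy SNP positions per Alu site
    # coverage model: negative binomial (mean, dispersion r)
    coverage_mean: float = 50.0
    coverage_dispersion: float = 5.0
    # class baselines: logit-normal site-to-site heterogeneity
    baseline_mean_alu: float = 0.015
    baseline_mean_rep: float = 0.03
    baseline_mean_nonrep: float = 0.12
    baseline_logit_sd: float = 0.5
    astrocyte_shift: float = 0.2  # logit shift of astrocytes vs normal brain
    # tumor under-editing: broad negative logit shift on a site fraction
    tumor_effect_shift: float = -1.0
    tumor_effect_fraction: float = 0.80
    # planted over-edited recoding sites (positive logit shift in tumors)
    n_overedited_sites: int = 2
    overedited_shift: float = 1.2
    # two-cluster tumor substructure at signature sites (frequency-scale gap)
    ino_fraction_a: float = 0.5
    ino_n_sites: int = 50
    ino_delta: float = 0.15
    # noise
    sample_offset_sd: float = 0.15  # per-sample global logit offset
    site_jitter_sd: float = 0.30  # per-sample x site logit jitter
    non_ag_noise: float = 0.002  # per-read probability of a C or T call
    # survival: h(s) = baseline_hazard * exp(beta_sex * z(AEI_s))
    baseline_hazard: float = 1.0 / 400.0  # per day; median OS ~ 9 months
    beta_aei_male: float = -0.8
    beta_aei_female: float = 0.8
    censoring_rate: float = 0.30
    sex_ratio_male: float = 0.60

    def __post_init__(self) -> None:
        for name in ("baseline_mean_alu", "baseline_mean_rep",
                     "baseline_mean_nonrep", "recoding_frac_alu",
                     "recoding_frac_rep", "recoding_frac_nonrep",
                     "tumor_effect_fraction", "ino_fraction_a",
                     "sex_ratio_male"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if min(self.n_alu_sites, self.n_rep_sites, self.n_nonrep_sites) < 1:
            raise ValueError("each site class needs at least one site")


@dataclass
class GroundTruth:
    """Everything recovery tests need, recorded at generation time."""

    seed: int
    site_rates: pd.DataFrame  # per site: normal/tumor/tumor-cluster-A rates
    planted_under: list[str]
    planted_over: list[str]
    ino_sites: list[str]
    ino_labels: dict[str, str]  # tumor sample -> A / B
    aei_truth: pd.Series  # per-sample analytic mean Alu editing rate
    beta_aei_male: float = 0.0
    beta_aei_female: float = 0.0

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "site_rates": self.site_rates.round(10).to_dict(orient="index"),
            "planted_under": self.planted_under,
            "planted_over": self.planted_over,
            "ino_sites": self.ino_sites,
            "ino_labels": self.ino_labels,
            "aei_truth": {k: round(v, 10) for k, v in self.aei_truth.items()},
            "beta_aei_male": self.beta_aei_male,
            "beta_aei_female": self.beta_aei_female,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            seed=payload["seed"],
            site_rates=pd.DataFrame.from_dict(payload["site_rates"],
                                              orient="index"),
            planted_under=payload["planted_under"],
            planted_over=payload["planted_over"],
            ino_sites=payload["ino_sites"],
            ino_labels=payload["ino_labels"],
            aei_truth=pd.Series(payload["aei_truth"]),
            beta_aei_male=payload["beta_aei_male"],
            beta_aei_female=payload["beta_aei_female"],
        )


# ---------------------------------------------------------------------------
# Catalog / region / SNP-mask generation
# ---------------------------------------------------------------------------


def simulate_catalog(config: SimulationConfig
                     ) -> tuple[SiteCatalog, RegionSet, SNPMask]:
    """Place catalog sites on a synthetic chromosome with emitted intervals.

    Alu sites sit inside 300-bp Alu intervals (about five sites each), repeat
    sites inside longer non-Alu repeat intervals, non-repetitive sites in the
    gaps between them.  A small set of decoy SNP positions is planted inside
    Alu intervals, disjoint from catalog sites.
    """
    rng = np.random.default_rng(config.seed)
    regions = RegionSet()
    chrom = "chrS1"
    sites: list[GenomicSite] = []
    used: set[int] = set()
    cursor = 1000

    def place_in_interval(n_sites_here: int, length: int, label: str) -> list[int]:
        nonlocal cursor
        start = cursor
        end = start + length
        regions.add(label, chrom, start, end)  # 0-based half-open
        positions = []
        attempts = 0
        while len(positions) < n_sites_here:
            pos = int(rng.integers(start + 1, end + 1))  # 1-based inside
            attempts += 1
            if attempts > 1000 * n_sites_here:
                raise RuntimeError("interval placement exhausted; shrink n_sites")
            if pos not in used:
                used.add(pos)
                positions.append(pos)
        cursor = end + int(rng.integers(500, 1500))
        return positions

    def feature_of() -> str:
        return str(rng.choice(["exon", "intron", "UTR", "intergenic"],
                              p=[0.15, 0.45, 0.25, 0.15]))

    def make_sites(positions: list[int], region_class: str,
                   recoding_frac: float) -> None:
        for pos in positions:
            recoding = bool(rng.random() < recoding_frac)
            sites.append(GenomicSite(
                chrom=chrom, pos=pos,
                strand="+" if rng.random() < 0.5 else "-",
                region_class=region_class, recoding=recoding,
                aa_change=str(rng.choice(_AA_CHANGES)) if recoding else None,
                gene=f"GENE{len(sites):04d}",
                feature=feature_of(),
            ))

    # Alu intervals, ~5 catalog sites each
    remaining = config.n_alu_sites
    while remaining > 0:
        k = min(5, remaining)
        make_sites(place_in_interval(k, 300, ALU), ALU, config.recoding_frac_alu)
        remaining -= k
    # non-Alu repeats (LINE-like, longer intervals)
    remaining = config.n_rep_sites
    while remaining > 0:
        k = min(3, remaining)
        make_sites(place_in_interval(k, 1000, REP), REP, config.recoding_frac_rep)
        remaining -= k
    # non-repetitive sites in the clear gaps beyond all intervals
    for _ in range(config.n_nonrep_sites):
        attempts = 0
        while True:
            pos = cursor + 1 + int(rng.integers(0, 200))
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError("site placement exhausted; shrink n_sites")
            if pos not in used and regions.classify(chrom, pos) == NONREP:
                used.add(pos)
                break
        cursor = pos + int(rng.integers(50, 400))
        make_sites([pos], NONREP, config.recoding_frac_nonrep)

    # decoy SNP positions inside Alu intervals, off-catalog
    n_decoys = int(round(config.snp_decoy_fraction * config.n_alu_sites))
    decoys: list[tuple[str, int]] = []
    alu_tree = regions._trees[ALU][chrom]
    intervals = sorted(alu_tree)
    while len(decoys) < n_decoys:
        iv = intervals[int(rng.integers(0, len(intervals)))]
        pos = int(rng.integers(iv.begin + 1, iv.end + 1))
        if pos not in used:
            used.add(pos)
            decoys.append((chrom, pos))

    catalog = SiteCatalog(sites, provenance=[f"synthetic(seed={config.seed})"])
    return catalog, regions, SNPMask(decoys)


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


def _sample_names(config: SimulationConfig) -> tuple[list[str], list[str], list[str]]:
    tumors = [f"T{i:03d}" for i in range(config.n_tumor)]
    normals = [f"N{i:03d}" for i in range(config.n_normal)]
    astro = [f"A{i:03d}" for i in range(config.n_astrocyte)]
    return tumors, normals, astro


def simulate_cohort_counts(config: SimulationConfig, catalog: SiteCatalog,
                           snps: SNPMask | None = None,
                           ) -> tuple[dict[str, list[SiteMeasurement]], GroundTruth]:
    """Draw per-sample base-count tables and the matching ground truth."""
    rng = np.random.default_rng(config.seed + 1)
    tumors, normals, astro = _sample_names(config)
    samples = tumors + normals + astro
    sites = list(catalog.sites)
    n_sites = len(sites)

    base_mean = {ALU: config.baseline_mean_alu, REP: config.baseline_mean_rep,
                 NONREP: config.baseline_mean_nonrep}
    site_logit = np.array([
        rng.normal(logit(base_mean[s.region_class]), config.baseline_logit_sd)
        for s in sites])

    # broad tumor under-editing on a random site fraction
    n_under = int(round(config.tumor_effect_fraction * n_sites))
    under_idx = rng.choice(n_sites, size=n_under, replace=False)
    tumor_shift = np.zeros(n_sites)
    tumor_shift[under_idx] = config.tumor_effect_shift
    # a few recoding sites over-edited in tumor instead
    recoding_idx = [i for i, s in enumerate(sites) if s.recoding]
    n_over = min(config.n_overedited_sites, len(recoding_idx))
    over_idx = rng.choice(recoding_idx, size=n_over, replace=False) \
        if n_over else np.array([], dtype=int)
    tumor_shift[over_idx] = config.overedited_shift

    # signature sites carrying the two-cluster tumor substructure
    genic_idx = [i for i, s in enumerate(sites)
                 if s.feature in ("exon", "intron", "UTR")]
    n_ino = min(config.ino_n_sites, len(genic_idx))
    ino_idx = rng.choice(genic_idx, size=n_ino, replace=False) if n_ino \
        else np.array([], dtype=int)
    ino_mask = np.zeros(n_sites, dtype=bool)
    ino_mask[ino_idx] = True
    n_cluster_a = int(round(config.ino_fraction_a * config.n_tumor))
    a_members = set(rng.choice(config.n_tumor, size=n_cluster_a, replace=False))
    ino_labels = {t: ("A" if i in a_members else "B")
                  for i, t in enumerate(tumors)}

    rate_normal = expit(site_logit)
    rate_tumor = expit(site_logit + tumor_shift)
    rate_tumor_a = np.clip(rate_tumor + config.ino_delta * ino_mask, 0.0, 0.99)
    rate_astro = expit(site_logit + config.astrocyte_shift)

    site_rates = pd.DataFrame({
        "normal": rate_normal, "tumor": rate_tumor, "tumor_cluster_a": rate_tumor_a,
    }, index=[s.label for s in sites])

    alu_mask = np.array([s.region_class == ALU for s in sites])
    nb_p = config.coverage_dispersion / (config.coverage_dispersion
                                         + config.coverage_mean)
    snp_positions = sorted(snps._positions) if snps is not None else []

    tables: dict[str, list[SiteMeasurement]] = {}
    aei_truth = {}
    for s_ix, sample in enumerate(samples):
        offset = rng.normal(0.0, config.sample_offset_sd)
        if sample in tumors:
            base = rate_tumor_a if ino_labels[sample] == "A" else rate_tumor
        elif sample in normals:
            base = rate_normal
        else:
            base = rate_astro
        jitter = rng.normal(0.0, config.site_jitter_sd, size=n_sites)
        rates = expit(logit(np.clip(base, 1e-6, 1 - 1e-6)) + offset + jitter)
        coverage = rng.negative_binomial(config.coverage_dispersion, nb_p,
                                         size=n_sites)
        n_other = rng.binomial(coverage, 2 * config.non_ag_noise)
        ag = coverage - n_other
        g = rng.binomial(ag, rates)
        a = ag - g
        c = rng.binomial(n_other, 0.5)
        t = n_other - c
        rows = []
        for j, site in enumerate(sites):
            if coverage[j] == 0:
                continue  # unmeasured cell
            rows.append(SiteMeasurement(
                site=site, counts=(int(a[j]), int(c[j]), int(g[j]), int(t[j]))))
        # decoy het SNPs inside Alu intervals: apparent 50% "editing"
        for chrom, pos in snp_positions:
            cov = int(rng.negative_binomial(config.coverage_dispersion, nb_p))
            if cov == 0:
                continue
            g_snp = int(rng.binomial(cov, 0.5))
            rows.append(SiteMeasurement(
                site=GenomicSite(chrom=chrom, pos=pos, strand="+"),
                counts=(cov - g_snp, 0, g_snp, 0)))
        tables[sample] = rows
        aei_truth[sample] = float(np.mean(rates[alu_mask]))

    truth = GroundTruth(
        seed=config.seed,
        site_rates=site_rates,
        planted_under=[sites[i].label for i in sorted(set(under_idx) - set(over_idx))],
        planted_over=[sites[i].label for i in sorted(over_idx)],
        ino_sites=[sites[i].label for i in sorted(ino_idx)],
        ino_labels=ino_labels,
        aei_truth=pd.Series(aei_truth),
        beta_aei_male=config.beta_aei_male,
        beta_aei_female=config.beta_aei_female,
    )
    return tables, truth


# ---------------------------------------------------------------------------
# Clinical metadata
# ---------------------------------------------------------------------------

_COVARIATE_PREVALENCE = {
    "tp53_mutant": 0.30,
    "idh_mutant": 0.10,
    "mgmt_methylated": 0.45,
    "chr7gain_chr10loss": 0.60,
}


def simulate_clinical(config: SimulationConfig,
                      aei_truth: pd.Series) -> pd.DataFrame:
    """Clinical table with sex-dependent AEI survival effects.

    Tumor overall survival is exponential with log-hazard
    ``beta_sex * z(AEI)`` around the baseline hazard; censored samples are
    observed at a uniform fraction of their event time, hitting the stated
    censoring rate in expectation.  Normals and astrocytes carry no outcome.
    """
    rng = np.random.default_rng(config.seed + 2)
    tumors, normals, astro = _sample_names(config)
    aei_t = aei_truth.loc[tumors]
    z = (aei_t - aei_t.mean()) / (aei_t.std(ddof=0) or 1.0)
    rows = []
    for sample in tumors + normals + astro:
        condition = ("tumor" if sample in set(tumors)
                     else "normal" if sample in set(normals) else "astrocyte")
        sex = "male" if rng.random() < config.sex_ratio_male else "female"
        age = float(np.round(rng.normal(60 if condition == "tumor" else 55, 10), 1))
        row: dict[str, object] = {
            "sample_id": sample, "condition": condition, "sex": sex,
            "age": age, "os_time": np.nan, "os_event": np.nan, "subtype": "NA",
            "kps": np.nan,
        }
        if condition == "tumor":
            beta = (config.beta_aei_male if sex == "male"
                    else config.beta_aei_female)
            hazard = config.baseline_hazard * float(np.exp(beta * z[sample]))
            t_event = rng.exponential(1.0 / hazard)
            if rng.random() < config.censoring_rate:
                row["os_time"] = float(np.round(t_event * rng.random(), 1))
                row["os_event"] = 0
            else:
                row["os_time"] = float(np.round(t_event, 1))
                row["os_event"] = 1
            row["subtype"] = str(rng.choice(["CL", "M", "N", "PN"]))
            row["kps"] = float(rng.choice([60, 70, 80, 90, 100]))
            for cov, prev in _COVARIATE_PREVALENCE.items():
                row[cov] = int(rng.random() < prev)
        else:
            for cov in _COVARIATE_PREVALENCE:
                row[cov] = np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# One-call cohort generation (optionally persisted)
# ---------------------------------------------------------------------------


@dataclass
class CohortData:
    config: SimulationConfig
    catalog: SiteCatalog
    regions: RegionSet
    snps: SNPMask
    tables: dict[str, list[SiteMeasurement]]
    clinical: pd.DataFrame
    truth: GroundTruth


def simulate_cohort(config: SimulationConfig,
                    outdir: str | Path | None = None) -> CohortData:
    """Generate a full cohort; when ``outdir`` is given, write it out as a
    self-contained directory (tables/, catalog.tsv, alu.bed, rep.bed,
    snps.tsv, clinical.tsv, truth.json, config.json)."""
    catalog, regions, snps = simulate_catalog(config)
    tables, truth = simulate_cohort_counts(config, catalog, snps=snps)
    clinical = simulate_clinical(config, truth.aei_truth)
    cohort = CohortData(config=config, catalog=catalog, regions=regions,
                        snps=snps, tables=tables, clinical=clinical,
                        truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "tables").mkdir(parents=True, exist_ok=True)
        tag = f"synthetic cohort, seed={config.seed}"
        for sample in sorted(tables):
            write_reditools_table(tables[sample],
                                  outdir / "tables" / f"{sample}.tsv",
                                  header_comment=tag)
        catalog.to_tsv(outdir / "catalog.tsv")
        regions.to_bed(outdir / "alu.bed", ALU)
        regions.to_bed(outdir / "rep.bed", REP)
        snps.to_tsv(outdir / "snps.tsv")
        write_clinical_table(clinical, outdir / "clinical.tsv",
                             header_comment=tag)
        truth.to_json(outdir / "truth.json")
        (outdir / "config.json").write_text(
            json.dumps(asdict(config), indent=1, sort_keys=True))
    return cohort
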