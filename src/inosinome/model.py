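"""Domain types and file readers/writers for site-level A-to-I editing data.

A-to-I editing is observed in RNA-seq as A→G mismatches on the sense strand.
Everything downstream works from per-site base counts: for each genomic
adenosine we keep the four base tallies ``(A, C, G, T)`` of the reads covering
it, oriented to the annotated strand by the variant caller that produced the
table.  The editing frequency of a site is ``G / (A + G)`` — the fraction of
transcripts carrying the edit — while the total coverage ``A+C+G+T`` is kept
separately for the pooled Alu editing index.

Coordinate conventions: site positions are 1-based (the caller-table dialect);
interval files are 0-based half-open (BED).  Conversions happen at the file
boundary, never downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

ALU = "ALU"
REP = "REP"
NONREP = "NONREP"
REGION_CLASSES = (ALU, REP, NONREP)

#: genic feature labels used for stratification-site selection
FEATURES = ("exon", "intron", "UTR", "intergenic")

REDITOOLS_COLUMNS = [
    "Region",
    "Position",
    "Reference",
    "Strand",
    "Coverage",
    "MeanQ",
    "BaseCount[A,C,G,T]",
    "AllSubs",
    "Frequency",
]


class TableFormatError(ValueError):
    """A file does not conform to its declared tabular dialect."""


# ---------------------------------------------------------------------------
# Sites and catalogs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicSite:
    """A known editing position.

    Identity (equality/hash) is the genomic key ``(chrom, pos, strand)``;
    annotation fields do not participate so that differently annotated records
    of the same position collide in set operations and can be reconciled.
    """

    chrom: str
    pos: int  # 1-based
    strand: str = "+"
    region_class: str = field(default=NONREP, compare=False)
    recoding: bool = field(default=False, compare=False)
    aa_change: str | None = field(default=None, compare=False)
    gene: str | None = field(default=None, compare=False)
    feature: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"site position must be >= 1, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)

    @property
    def label(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.strand}"


def _site_sort_key(s: GenomicSite) -> tuple[str, int, str]:
    return (s.chrom, s.pos, s.strand)


@dataclass
class SiteCatalog:
    """An ordered, duplicate-free collection of editing sites."""

    sites: list[GenomicSite]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sites = sorted(self.sites, key=_site_sort_key)
        keys = [s.key for s in self.sites]
        if len(set(keys)) != len(keys):
            seen: set = set()
            dup = next(k for k in keys if k in seen or seen.add(k))
            raise ValueError(f"duplicate site in catalog: {dup}")

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def lookup(self) -> dict[tuple[str, int, str], GenomicSite]:
        return {s.key: s for s in self.sites}

    def subset(self, predicate) -> list[GenomicSite]:
        return [s for s in self.sites if predicate(s)]

    @property
    def recoding_sites(self) -> list[GenomicSite]:
        return self.subset(lambda s: s.recoding)

    @property
    def nonrep_sites(self) -> list[GenomicSite]:
        return self.subset(lambda s: s.region_class == NONREP)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in REGION_CLASSES}
        for s in self.sites:
            counts[s.region_class] += 1
        return counts

    # -- persistence --------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {
                "chrom": s.chrom,
                "pos": s.pos,
                "strand": s.strand,
                "region_class": s.region_class,
                "recoding": int(s.recoding),
                "aa_change": s.aa_change if s.aa_change is not None else "NA",
                "gene": s.gene if s.gene is not None else "NA",
                "feature": s.feature if s.feature is not None else "NA",
            }
            for s in self.sites
        ]
        pd.DataFrame(rows, columns=["chrom", "pos", "strand", "region_class",
                                    "recoding", "aa_change", "gene", "feature"]
                     ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, provenance: str | None = None) -> "SiteCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
        required = {"chrom", "pos", "strand"}
        if not required.issubset(df.columns):
            raise TableFormatError(f"catalog {path} missing columns {required - set(df.columns)}")
        sites = []
        for row in df.itertuples(index=False):
            sites.append(GenomicSite(
                chrom=row.chrom,
                pos=int(row.pos),
                strand=row.strand,
                region_class=getattr(row, "region_class", NONREP) or NONREP,
                recoding=bool(int(getattr(row, "recoding", 0) or 0)),
                aa_change=None if getattr(row, "aa_change", "NA") in ("NA", "") else row.aa_change,
                gene=None if getattr(row, "gene", "NA") in ("NA", "") else row.gene,
                feature=None if getattr(row, "feature", "NA") in ("NA", "") else row.feature,
            ))
        return cls(sites, provenance=[provenance or str(path)])


def merge_catalogs(catalogs: Sequence[SiteCatalog]) -> SiteCatalog:
    """Union of site catalogs on the genomic key.

    The recoding flag of a merged site is the OR over sources; for the other
    annotations the first source listing the site wins and later conflicts are
    counted (a reconciliation policy, since upstream databases disagree).
    """
    merged: dict[tuple[str, int, str], GenomicSite] = {}
    conflicts = 0
    for cat in catalogs:
        for s in cat.sites:
            if s.key not in merged:
                merged[s.key] = s
            else:
                prev = merged[s.key]
                if s.aa_change is not None and prev.aa_change is not None \
                        and s.aa_change != prev.aa_change:
                    conflicts += 1
                merged[s.key] = replace(
                    prev,
                    recoding=prev.recoding or s.recoding,
                    aa_change=prev.aa_change if prev.aa_change is not None else s.aa_change,
                    gene=prev.gene if prev.gene is not None else s.gene,
                    feature=prev.feature if prev.feature is not None else s.feature,
                )
    provenance = [p for cat in catalogs for p in cat.provenance]
    result = SiteCatalog(list(merged.values()), provenance=provenance)
    result.annotation_conflicts = conflicts  # type: ignore[attr-defined]
    return result


# ---------------------------------------------------------------------------
# Genomic intervals and SNP masking
# ---------------------------------------------------------------------------


class RegionSet:
    """Repeat-region intervals (Alu and other repeats), 0-based half-open.

    Classification precedence is ALU > REP: a position inside both an Alu and
    another repeat annotation counts as Alu.  Queries are strand-agnostic.
    """

    def __init__(self) -> None:
        self._trees: dict[str, dict[str, IntervalTree]] = {ALU: {}, REP: {}}

    def add(self, label: str, chrom: str, start: int, end: int) -> None:
        if label not in (ALU, REP):
            raise ValueError(f"region class must be ALU or REP, got {label!r}")
        if not start < end:
            raise ValueError(f"invalid interval [{start},{end})")
        self._trees[label].setdefault(chrom, IntervalTree()).addi(start, end)

    def load_bed(self, path: str | Path, label: str) -> int:
        n = 0
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise TableFormatError(f"BED line with <3 fields in {path}: {line!r}")
                self.add(label, parts[0], int(parts[1]), int(parts[2]))
                n += 1
        return n

    @classmethod
    def from_beds(cls, alu_bed: str | Path | None = None,
                  rep_bed: str | Path | None = None) -> "RegionSet":
        rs = cls()
        if alu_bed is not None:
            rs.load_bed(alu_bed, ALU)
        if rep_bed is not None:
            rs.load_bed(rep_bed, REP)
        return rs

    def contains(self, label: str, chrom: str, pos: int) -> bool:
        """Membership of a 1-based position in the intervals of one class."""
        tree = self._trees[label].get(chrom)
        return bool(tree is not None and tree.overlaps_point(pos - 1))

    def classify(self, chrom: str, pos: int) -> str:
        if self.contains(ALU, chrom, pos):
            return ALU
        if self.contains(REP, chrom, pos):
            return REP
        return NONREP

    def chroms(self) -> set[str]:
        return {c for trees in self._trees.values() for c in trees}

    def to_bed(self, path: str | Path, label: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self._trees[label]):
                for iv in sorted(self._trees[label][chrom]):
                    fh.write(f"{chrom}\t{iv.begin}\t{iv.end}\t{label}\n")


class SNPMask:
    """Set of genomic positions (1-based) excluded as known DNA polymorphisms."""

    def __init__(self, positions: Iterable[tuple[str, int]] = ()) -> None:
        self._positions: set[tuple[str, int]] = set(positions)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._positions

    def __len__(self) -> int:
        return len(self._positions)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SNPMask":
        positions = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise TableFormatError(f"SNP mask line with <2 fields: {line!r}")
                positions.append((parts[0], int(parts[1])))
        return cls(positions)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\n")
            for chrom, pos in sorted(self._positions):
                fh.write(f"{chrom}\t{pos}\n")


# ---------------------------------------------------------------------------
# Per-sample site measurements
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteMeasurement:
    """Base counts of one sample at one genomic adenosine (sense-oriented)."""

    site: GenomicSite
    counts: tuple[int, int, int, int]  # A, C, G, T

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts):
            raise ValueError(f"negative base count at {self.site.label}")

    @property
    def coverage(self) -> int:
        return sum(self.counts)

    @property
    def a_count(self) -> int:
        return self.counts[0]

    @property
    def edited_reads(self) -> int:
        return self.counts[2]

    @property
    def ag_depth(self) -> int:
        return self.counts[0] + self.counts[2]

    @property
    def editing_frequency(self) -> float:
        """G/(A+G); NaN when no A or G read covers the site (undefined, not 0)."""
        d = self.ag_depth
        return self.edited_reads / d if d > 0 else math.nan


@dataclass
class ReditoolsRead:
    """Result of parsing one per-sample editing table."""

    measurements: list[SiteMeasurement]
    n_rows: int = 0
    n_skipped_non_a: int = 0
    n_skipped_quality: int = 0
    unenforced_filters: list[str] = field(default_factory=list)


def _parse_basecount(text: str) -> tuple[int, int, int, int]:
    text = text.strip()
    if not (text.startswith("[") and text.endswith("]")):
        raise ValueError(f"malformed BaseCount field {text!r}")
    parts = [p.strip() for p in text[1:-1].split(",")]
    if len(parts) != 4:
        raise ValueError(f"BaseCount must have 4 entries, got {text!r}")
    return tuple(int(p) for p in parts)  # type: ignore[return-value]


def read_reditools_table(path: str | Path, min_mapq: int = 60,
                         min_baseq: int = 30) -> ReditoolsRead:
    """Parse a REDItools-dialect per-position TSV into site measurements.

    The table is taken as sense-oriented: the producing tool already resolves
    reverse-strand positions, so no re-complementation is performed here.
    Rows whose reference base is not A are skipped and counted.  ``min_baseq``
    gates rows on the MeanQ column; per-read mapping quality is not present in
    the table, so ``min_mapq`` is recorded as unenforceable rather than
    silently applied.
    """
    path = Path(path)
    result = ReditoolsRead(measurements=[], unenforced_filters=["min_mapq"])
    with open(path) as fh:
        header_line = fh.readline()
        while header_line.startswith("#"):  # provenance comments precede the header
            header_line = fh.readline()
        if not header_line:
            raise TableFormatError(f"{path}: empty file")
        header = header_line.rstrip("\n").split("\t")
        col = {name: i for i, name in enumerate(header)}
        basecount_col = next((c for c in header if c.startswith("BaseCount")), None)
        mandatory = ["Region", "Position", "Reference", "Strand", "Coverage",
                     "Frequency"]
        missing = [c for c in mandatory if c not in col]
        if missing or basecount_col is None:
            raise TableFormatError(
                f"{path}: missing mandatory column(s) "
                f"{missing + ([] if basecount_col else ['BaseCount'])}")
        has_meanq = "MeanQ" in col
        if not has_meanq:
            result.unenforced_filters.append("min_baseq")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            result.n_rows += 1
            ref = parts[col["Reference"]].upper()
            if ref != "A":
                result.n_skipped_non_a += 1
                continue
            if has_meanq:
                meanq = float(parts[col["MeanQ"]])
                if meanq < min_baseq:
                    result.n_skipped_quality += 1
                    continue
            try:
                counts = _parse_basecount(parts[col[basecount_col]])
            except ValueError as exc:
                raise TableFormatError(f"{path}:{lineno}: {exc}") from exc
            site = GenomicSite(chrom=parts[col["Region"]],
                               pos=int(parts[col["Position"]]),
                               strand=parts[col["Strand"]])
            result.measurements.append(SiteMeasurement(site=site, counts=counts))
    return result


def write_reditools_table(measurements: Iterable[SiteMeasurement],
                          path: str | Path, mean_q: float = 38.0,
                          header_comment: str | None = None) -> None:
    """Write measurements back out in the same dialect the reader accepts."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n" if not header_comment.startswith("#")
                     else header_comment + "\n")
        fh.write("\t".join(REDITOOLS_COLUMNS) + "\n")
        for m in measurements:
            freq = m.editing_frequency
            freq_txt = f"{freq:.6f}" if not math.isnan(freq) else "-"
            subs = "AG" if m.edited_reads > 0 else "-"
            fh.write("\t".join([
                m.site.chrom, str(m.site.pos), "A", m.site.strand,
                str(m.coverage), f"{mean_q:.2f}",
                f"[{m.counts[0]}, {m.counts[1]}, {m.counts[2]}, {m.counts[3]}]",
                subs, freq_txt,
            ]) + "\n")


# ---------------------------------------------------------------------------
# Region-class annotation
# ---------------------------------------------------------------------------


def annotate_site_class(catalog: SiteCatalog, regions: RegionSet) -> SiteCatalog:
    """Partition catalog sites into ALU / REP / NONREP by interval containment.

    Precedence ALU > REP; anything outside both annotation sets — including
    sites on chromosomes absent from the interval files — is NONREP.
    """
    annotated = [replace(s, region_class=regions.classify(s.chrom, s.pos))
                 for s in catalog.sites]
    return SiteCatalog(annotated, provenance=list(catalog.provenance))


# ---------------------------------------------------------------------------
# Editing matrix (samples x sites)
# ---------------------------------------------------------------------------


@dataclass
class EditingMatrix:
    """Editing frequencies and coverages for samples x catalog sites.

    ``freq`` is defined (non-NaN) only where the site was measured with at
    least one A/G read; NaN is genuine missingness, never zero editing.
    """

    freq: pd.DataFrame  # index: sample ids, columns: site labels
    cov: pd.DataFrame
    sites: list[GenomicSite]

    def __post_init__(self) -> None:
        if self.freq.shape != self.cov.shape:
            raise ValueError("freq and cov matrices must share a shape")
        if list(self.freq.columns) != [s.label for s in self.sites]:
            raise ValueError("matrix columns must align with the site list")

    @property
    def samples(self) -> list[str]:
        return list(self.freq.index)

    @property
    def site_labels(self) -> list[str]:
        return list(self.freq.columns)

    def site_by_label(self) -> dict[str, GenomicSite]:
        return {s.label: s for s in self.sites}

    def restrict(self, sites: Sequence[GenomicSite]) -> "EditingMatrix":
        labels = [s.label for s in sites]
        return EditingMatrix(self.freq[labels].copy(), self.cov[labels].copy(),
                             list(sites))

    def write(self, freq_path: str | Path, cov_path: str | Path,
              catalog_path: str | Path | None = None) -> None:
        # samples in columns, sites in rows; NA marks missing cells
        self.freq.T.to_csv(freq_path, sep="\t", na_rep="NA",
                           index_label="site", float_format="%.10g")
        self.cov.T.to_csv(cov_path, sep="\t", na_rep="NA",
                          index_label="site", float_format="%.10g")
        if catalog_path is not None:
            SiteCatalog(self.sites).to_tsv(catalog_path)

    @classmethod
    def read(cls, freq_path: str | Path, cov_path: str | Path,
             catalog: SiteCatalog) -> "EditingMatrix":
        freq = pd.read_csv(freq_path, sep="\t", index_col="site").T
        cov = pd.read_csv(cov_path, sep="\t", index_col="site").T
        lookup = {s.label: s for s in catalog.sites}
        try:
            sites = [lookup[label] for label in freq.columns]
        except KeyError as exc:
            raise TableFormatError(f"matrix site {exc} absent from catalog") from exc
        freq.index.name = None
        cov.index.name = None
        return cls(freq, cov, sites)


def build_editing_matrix(measurements: Mapping[str, Sequence[SiteMeasurement]],
                         catalog: SiteCatalog) -> EditingMatrix:
    """Align per-sample measurements on the catalog order.

    Measurements at positions outside the catalog are dropped (counted on the
    returned matrix as ``n_dropped_off_catalog``); absent sample x site cells
    are NaN in both frequency and coverage.
    """
    site_labels = [s.label for s in catalog.sites]
    col_index = {label: j for j, label in enumerate(site_labels)}
    samples = list(measurements.keys())
    freq = np.full((len(samples), len(site_labels)), np.nan)
    cov = np.full((len(samples), len(site_labels)), np.nan)
    dropped = 0
    for i, sample in enumerate(samples):
        seen: set[str] = set()
        for m in measurements[sample]:
            label = m.site.label
            j = col_index.get(label)
            if j is None:
                dropped += 1
                continue
            if label in seen:
                raise ValueError(f"duplicate measurement for ({sample}, {label})")
            seen.add(label)
            cov[i, j] = m.coverage
            if m.ag_depth > 0:
                freq[i, j] = m.editing_frequency
    matrix = EditingMatrix(
        pd.DataFrame(freq, index=samples, columns=site_labels),
        pd.DataFrame(cov, index=samples, columns=site_labels),
        list(catalog.sites),
    )
    matrix.n_dropped_off_catalog = dropped  # type: ignore[attr-defined]
    return matrix


# ---------------------------------------------------------------------------
# Clinical metadata
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["sample_id", "condition", "sex", "age", "os_time",
                    "os_event", "subtype"]
COVARIATE_COLUMNS = ["tp53_mutant", "idh_mutant", "mgmt_methylated",
                     "chr7gain_chr10loss"]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the clinical TSV (one row per sample) and validate its contract."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"clinical table missing columns {missing}")
    if df["sample_id"].duplicated().any():
        raise TableFormatError("duplicate sample_id in clinical table")
    if (df["os_time"].dropna() < 0).any():
        raise TableFormatError("negative os_time in clinical table")
    bad_event = ~df["os_event"].dropna().isin([0, 1])
    if bad_event.any():
        raise TableFormatError("os_event must be 0 (censored) or 1 (death)")
    return df.set_index("sample_id", drop=False)


def write_clinical_table(df: pd.DataFrame, path: str | Path,
                         header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"#{header_comment}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", float_format="%.10g")
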