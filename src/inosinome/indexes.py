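"""Weighted (count-pooled) editing indexes: AEI, nREI, REI, DEI.

All four indexes are pooled ratios, not means of per-site frequencies: read
counts are summed over the selected sites first and divided once.  Highly
covered sites therefore weigh more, which is what makes the statistic robust
to the noisy tail of barely covered positions.

Two denominators coexist by design:

* the Alu editing index (AEI) divides the pooled G count by *all* bases
  aligned to genomic adenosines inside Alu repeats (``G / (A+C+G+T)``) — the
  classic transcriptome-wide mismatch ratio;
* nREI, REI and DEI divide by the pooled ``A+G`` depth, i.e. they pool the
  per-site editing level ``G/(A+G)`` over curated catalog sites.

An index whose denominator is empty is *undefined* (NaN), never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .model import (
    ALU,
    GenomicSite,
    RegionSet,
    SiteCatalog,
    SiteMeasurement,
    SNPMask,
)

AG_DENOMINATOR = "AG_denominator"
ALL_BASES_DENOMINATOR = "all_bases_denominator"


@dataclass(frozen=True)
class IndexValue:
    """A pooled editing index with its evidence tallies."""

    value: float  # fraction in [0, 1]; NaN when undefined
    n_sites: int  # sites contributing a non-zero denominator
    n_reads: int  # pooled denominator reads

    @property
    def defined(self) -> bool:
        return not math.isnan(self.value)


def weighted_editing_index(measurements: Iterable[SiteMeasurement],
                           mode: str = AG_DENOMINATOR) -> IndexValue:
    """Pool counts over sites and return the single summed ratio.

    ``AG_denominator`` computes sum(G)/sum(A+G); ``all_bases_denominator``
    computes sum(G)/sum(A+C+G+T).  An empty selection or an all-zero
    denominator yields an undefined (NaN) value with zero tallies.
    """
    if mode not in (AG_DENOMINATOR, ALL_BASES_DENOMINATOR):
        raise ValueError(f"unknown index mode {mode!r}")
    num = 0
    den = 0
    n_sites = 0
    for m in measurements:
        d = m.ag_depth if mode == AG_DENOMINATOR else m.coverage
        if d > 0:
            n_sites += 1
        num += m.edited_reads
        den += d
    if den == 0:
        return IndexValue(math.nan, 0, 0)
    return IndexValue(num / den, n_sites, den)


def compute_aei(measurements: Iterable[SiteMeasurement], regions: RegionSet,
                snps: SNPMask | None = None) -> IndexValue:
    """Alu editing index of one sample.

    Uses every measured adenosine falling inside an Alu interval — the table
    is not restricted to cataloged sites — minus known-SNP positions, pooled
    with the all-bases denominator.  No coverage floor is applied: AEI is a
    per-read ratio and low-coverage Alu positions legitimately contribute.
    """
    selected = [
        m for m in measurements
        if regions.contains(ALU, m.site.chrom, m.site.pos)
        and (snps is None or (m.site.chrom, m.site.pos) not in snps)
    ]
    return weighted_editing_index(selected, mode=ALL_BASES_DENOMINATOR)


def _catalog_index(measurements: Iterable[SiteMeasurement],
                   wanted: set[tuple[str, int, str]],
                   min_coverage: int) -> IndexValue:
    selected = [m for m in measurements
                if m.site.key in wanted and m.coverage >= min_coverage]
    return weighted_editing_index(selected, mode=AG_DENOMINATOR)


def compute_nrei(measurements: Iterable[SiteMeasurement], catalog: SiteCatalog,
                 min_coverage: int = 10) -> IndexValue:
    """Non-repetitive editing index: pooled G/(A+G) over NONREP catalog sites."""
    wanted = {s.key for s in catalog.nonrep_sites}
    return _catalog_index(measurements, wanted, min_coverage)


def compute_rei(measurements: Iterable[SiteMeasurement], catalog: SiteCatalog,
                min_coverage: int = 10) -> IndexValue:
    """Recoding editing index: pooled G/(A+G) over recoding sites of any class."""
    wanted = {s.key for s in catalog.recoding_sites}
    return _catalog_index(measurements, wanted, min_coverage)


def compute_dei(measurements: Iterable[SiteMeasurement],
                dei_sites: Sequence[GenomicSite],
                min_coverage: int = 10) -> IndexValue:
    """Differential editing index: the pooled ratio over a discovered site list.

    The site list typically comes from subtype-differential discovery; with
    the full recoding catalog it reduces to the REI.
    """
    if not dei_sites:
        return IndexValue(math.nan, 0, 0)
    wanted = {s.key for s in dei_sites}
    return _catalog_index(measurements, wanted, min_coverage)


def index_profiles(per_sample: Mapping[str, Sequence[SiteMeasurement]],
                   catalog: SiteCatalog, regions: RegionSet,
                   snps: SNPMask | None = None,
                   dei_sites: Sequence[GenomicSite] | None = None,
                   min_coverage: int = 10) -> pd.DataFrame:
    """All four indexes for every sample, with site and read tallies.

    Returns a DataFrame indexed by sample id with columns
    ``aei, nrei, rei, dei`` plus ``<index>_n_sites`` / ``<index>_n_reads``.
    The coverage floor applies to the catalog-based indexes only.
    """
    rows = []
    for sample, measurements in per_sample.items():
        measurements = list(measurements)
        values = {
            "aei": compute_aei(measurements, regions, snps),
            "nrei": compute_nrei(measurements, catalog, min_coverage),
            "rei": compute_rei(measurements, catalog, min_coverage),
            "dei": (compute_dei(measurements, dei_sites, min_coverage)
                    if dei_sites is not None else IndexValue(math.nan, 0, 0)),
        }
        row: dict[str, object] = {"sample_id": sample}
        for name, iv in values.items():
            row[name] = iv.value
            row[f"{name}_n_sites"] = iv.n_sites
            row[f"{name}_n_reads"] = iv.n_reads
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id", drop=False)
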