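"""Indel-type extraction and coding-vs-intron indel density testing.

An indel *type* is a distinct maximal run of consecutive gap columns with a
unique (start, end) boundary signature carried by at least one allele; runs
sharing a start but differing in end are distinct types, and sharing across
alleles does not multiply types. Types are assigned to the region class
(coding or intron) containing their start column. The density test asks
whether the number of types per nucleotide differs between coding and
intron sequence, with a Yates-corrected chi-square against expectations
proportional to region lengths.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

from scipy.stats import chi2 as chi2_dist

from .alleles_qc import GAP, PopAlignment, Region


@dataclass
class IndelType:
    start: int  # 1-based inclusive
    end: int
    region: str  # "coding", "intron" or "unassigned"
    carriers: list[str]

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class IndelCatalog:
    events: list[IndelType]
    n_coding: int
    n_intron: int
    len_coding: int
    len_intron: int


@dataclass
class IndelDensityResult:
    chi2: float
    p_value: float
    density_coding: float
    density_intron: float


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    runs = []
    start = None
    for i, c in enumerate(seq, start=1):
        if c == GAP:
            if start is None:
                start = i
        elif start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(seq)))
    return runs


def extract_indels(aln: PopAlignment, region_map: list[Region] | None = None) -> IndelCatalog:
    """Catalog unique gap-run types and classify them by region."""
    regions = region_map if region_map is not None else aln.region_map
    carriers: dict[tuple[int, int], list[str]] = {}
    for allele, seq in aln.alleles.items():
        for run in _gap_runs(seq):
            carriers.setdefault(run, []).append(allele)

    def classify(start: int) -> str:
        for r in regions:
            if r.cls in ("coding", "intron") and r.start <= start <= r.end:
                return r.cls
        return "unassigned"

    events = []
    for (start, end), names in sorted(carriers.items()):
        region = classify(start)
        if region == "unassigned":
            warnings.warn(
                f"gap run ({start}, {end}) not covered by the region map",
                stacklevel=2,
            )
        events.append(IndelType(start, end, region, sorted(names)))
    n_coding = sum(1 for e in events if e.region == "coding")
    n_intron = sum(1 for e in events if e.region == "intron")
    len_coding = sum(r.length for r in regions if r.cls == "coding")
    len_intron = sum(r.length for r in regions if r.cls == "intron")
    return IndelCatalog(events, n_coding, n_intron, len_coding, len_intron)


def indel_density_test(
    n_coding: int,
    len_coding: int,
    n_intron: int,
    len_intron: int,
) -> IndelDensityResult:
    """Yates-corrected chi-square of equal indel density per unit length.

    Expected counts are proportional to region lengths; each term uses
    (|O-E| - 0.5)^2 / E with the correction floored at zero; df = 1.
    """
    if len_coding <= 0 or len_intron <= 0:
        raise ValueError("region lengths must be positive")
    if n_coding < 0 or n_intron < 0:
        raise ValueError("counts must be non-negative")
    total = n_coding + n_intron
    if total < 1:
        raise ValueError("need at least one indel in total")
    total_len = len_coding + len_intron
    exp_coding = total * len_coding / total_len
    exp_intron = total * len_intron / total_len
    stat = 0.0
    for obs, exp in ((n_coding, exp_coding), (n_intron, exp_intron)):
        adj = max(abs(obs - exp) - 0.5, 0.0)
        stat += adj * adj / exp
    return IndelDensityResult(
        chi2=float(stat),
        p_value=float(chi2_dist.sf(stat, 1)),
        density_coding=n_coding / len_coding,
        density_intron=n_intron / len_intron,
    )


def density_test_from_catalog(catalog: IndelCatalog) -> IndelDensityResult:
    return indel_density_test(
        catalog.n_coding, catalog.len_coding, catalog.n_intron, catalog.len_intron
    )
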