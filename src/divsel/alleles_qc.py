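"""Allele assembly and alignment QC for clone-sequenced diploid loci.

Workflow implemented here: build per-allele consensus sequences from the
aligned clone reads of each individual, estimate the per-nucleotide
sequencing-error rate from clone-vs-consensus mismatches, recode putative
error singletons with the column consensus, summarize polymorphism, and split
the alignment at a recombination breakpoint.

Conventions
-----------
* All coordinates are 1-based inclusive alignment columns.
* ``-`` is the gap character; ``N`` is missing data (never a votable state,
  never a singleton, never a variable state).
* Consensus ties are broken by lexicographic base order (A < C < G < T),
  which keeps the operation deterministic; a warning is logged when a tie
  occurs since ties are rare at typical 6-10x clone depth.
"""
from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field, replace

logger = logging.getLogger("divsel")

BASES = "ACGT"
GAP = "-"
MISSING = "N"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Region:
    """A named span of alignment columns with a functional class."""

    name: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    cls: str    # "coding", "intron" or "core"

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"invalid region span ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CloneSet:
    """Aligned clone reads for one individual with allele assignments.

    ``allele_assignment`` maps each clone id to allele index 1 or 2.
    """

    individual_id: str
    clones: list[tuple[str, str]]
    allele_assignment: dict[str, int]

    def validate(self) -> None:
        if not self.clones:
            raise ValueError(f"empty clone set for {self.individual_id}")
        lengths = {len(s) for _, s in self.clones}
        if len(lengths) != 1:
            raise ValueError(
                f"clones of unequal length for {self.individual_id}: {sorted(lengths)}"
            )
        alleles = set(self.allele_assignment.values())
        if not alleles <= {1, 2}:
            raise ValueError(f"allele indices must be 1 or 2, got {sorted(alleles)}")
        for cid, _ in self.clones:
            if cid not in self.allele_assignment:
                raise ValueError(f"clone {cid} has no allele assignment")


@dataclass
class PopAlignment:
    """Gap-aware alignment of alleles with population metadata and region map."""

    alleles: dict[str, str]
    meta: dict[str, tuple[str, str]]  # allele_id -> (individual_id, population)
    region_map: list[Region] = field(default_factory=list)
    breakpoint: int | None = None

    @property
    def ids(self) -> list[str]:
        return list(self.alleles)

    @property
    def length(self) -> int:
        return len(next(iter(self.alleles.values())))

    def validate(self, focal_populations: tuple[str, str] | None = None) -> None:
        if not self.alleles:
            raise ValueError("alignment has no sequences")
        lengths = {len(s) for s in self.alleles.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal sequence lengths: {sorted(lengths)}")
        for a in self.alleles:
            if a not in self.meta:
                raise ValueError(f"allele {a} missing from sample sheet")
        for r in self.region_map:
            if r.end > self.length:
                raise ValueError(f"region {r.name} exceeds alignment length")
            if r.cls == "coding" and r.length % 3 != 0:
                raise ValueError(
                    f"coding region {r.name} has length {r.length} not divisible by 3"
                )
        if focal_populations is not None:
            pops = Counter(p for _, p in self.meta.values())
            for p in focal_populations:
                if pops[p] == 0:
                    raise ValueError(f"no alleles sampled from population {p}")

    def populations(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for a, (_, pop) in self.meta.items():
            if a in self.alleles:
                out.setdefault(pop, []).append(a)
        return out

    def column(self, col: int) -> list[str]:
        """States at a 1-based column, in allele order."""
        return [s[col - 1] for s in self.alleles.values()]


@dataclass
class PolymorphismSummary:
    n_sequences: int
    n_unique_alleles: int
    n_variable_sites: int
    n_aa_polymorphisms: int | None
    pairwise_pi: float
    singleton_count: int
    est_error_rate: float = math.nan


# ---------------------------------------------------------------------------
# Consensus building
# ---------------------------------------------------------------------------

def _column_consensus(states: list[str]) -> str:
    """Majority state of a column; ties broken by A<C<G<T<- order."""
    votable = [s for s in states if s != MISSING]
    if not votable:
        return MISSING
    counts = Counter(votable)
    top = max(counts.values())
    winners = sorted(s for s, c in counts.items() if c == top)
    if len(winners) > 1:
        logger.warning("consensus tie among %s; resolving to %s", winners, winners[0])
    return winners[0]


def build_consensus(clone_set: CloneSet) -> tuple[dict[str, str], float]:
    """Collapse a clone set into per-allele consensus sequences.

    Returns ``({allele_id: consensus}, est_error_rate)``. The error rate is
    the fraction of clone bases that disagree with their allele consensus,
    counted over columns where both clone and consensus carry an unambiguous
    base; alleles represented by a single clone contribute nothing to the
    estimate (their consensus equals the clone by construction). If no allele
    has >= 2 clones the rate is NaN.
    """
    clone_set.validate()
    by_allele: dict[int, list[str]] = {}
    for cid, seq in clone_set.clones:
        by_allele.setdefault(clone_set.allele_assignment[cid], []).append(seq.upper())

    consensus: dict[str, str] = {}
    mismatches = 0
    compared = 0
    for idx in sorted(by_allele):
        seqs = by_allele[idx]
        cols = list(zip(*seqs))
        cons = "".join(_column_consensus(list(col)) for col in cols)
        consensus[f"{clone_set.individual_id}_a{idx}"] = cons
        if len(seqs) >= 2:
            for seq in seqs:
                for c, k in zip(seq, cons):
                    if c in BASES and k in BASES:
                        compared += 1
                        if c != k:
                            mismatches += 1
    rate = mismatches / compared if compared else math.nan
    return consensus, rate


def pooled_error_rate(clone_sets: list[CloneSet]) -> float:
    """Error-rate estimate pooled over many individuals' clone sets."""
    mism = 0
    comp = 0
    for cs in clone_sets:
        cons, _ = build_consensus(cs)
        by_allele: dict[int, list[str]] = {}
        for cid, seq in cs.clones:
            by_allele.setdefault(cs.allele_assignment[cid], []).append(seq.upper())
        for idx, seqs in by_allele.items():
            if len(seqs) < 2:
                continue
            ref = cons[f"{cs.individual_id}_a{idx}"]
            for seq in seqs:
                for c, k in zip(seq, ref):
                    if c in BASES and k in BASES:
                        comp += 1
                        if c != k:
                            mism += 1
    return mism / comp if comp else math.nan


# ---------------------------------------------------------------------------
# Singleton recoding
# ---------------------------------------------------------------------------

def recode_singletons(
    aln: PopAlignment,
    region: tuple[int, int] | list[tuple[int, int]] | None = None,
) -> tuple[PopAlignment, int]:
    """Replace singleton substitution states with the column majority base.

    A singleton is a base carried by exactly one allele in a column and seen
    in no other allele there. Gaps and Ns are never singletons and are never
    created or destroyed. ``region`` is one span, a list of spans, or None
    for the whole alignment. Returns the recoded alignment (a new object)
    and the number of recoded cells. Idempotent.
    """
    if region is None:
        spans = [(1, aln.length)]
    elif isinstance(region, tuple):
        spans = [region]
    else:
        spans = list(region)
    columns: set[int] = set()
    for lo, hi in spans:
        if lo < 1 or hi > aln.length or lo > hi:
            raise ValueError(f"region ({lo}, {hi}) outside alignment bounds")
        columns.update(range(lo - 1, hi))
    ids = aln.ids
    rows = [list(aln.alleles[a]) for a in ids]
    n_recoded = 0
    for col in sorted(columns):
        states = [row[col] for row in rows]
        base_counts = Counter(s for s in states if s in BASES)
        if len(base_counts) < 2:
            continue
        top = max(base_counts.values())
        majority = sorted(s for s, c in base_counts.items() if c == top)[0]
        for i, s in enumerate(states):
            if s in BASES and base_counts[s] == 1 and s != majority:
                rows[i][col] = majority
                n_recoded += 1
    new_alleles = {a: "".join(row) for a, row in zip(ids, rows)}
    return replace(aln, alleles=new_alleles), n_recoded


# ---------------------------------------------------------------------------
# Polymorphism summary
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] | None = None


def _codon_table() -> dict[str, str]:
    global _CODON_TABLE
    if _CODON_TABLE is None:
        from Bio.Data.CodonTable import standard_dna_table

        table = dict(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            table[stop] = "*"
        _CODON_TABLE = table
    return _CODON_TABLE


def summarize_polymorphism(
    aln: PopAlignment,
    span: tuple[int, int] | None = None,
    amino_acids: bool | None = None,
    est_error_rate: float = math.nan,
) -> PolymorphismSummary:
    """Summary statistics for a span of the alignment.

    ``amino_acids=None`` counts amino-acid polymorphisms only when the span
    width is divisible by 3; requesting them explicitly on a non-codon span
    raises. Pairwise pi is the mean over sequence pairs of the per-site
    difference proportion at pairwise-complete (both-base) sites.
    """
    lo, hi = span if span is not None else (1, aln.length)
    if lo < 1 or hi > aln.length or lo > hi:
        raise ValueError(f"span ({lo}, {hi}) outside alignment bounds")
    width = hi - lo + 1
    if amino_acids is True and width % 3 != 0:
        raise ValueError(f"span width {width} not divisible by 3")
    do_aa = amino_acids if amino_acids is not None else (width % 3 == 0)

    seqs = [s[lo - 1 : hi] for s in aln.alleles.values()]
    n = len(seqs)
    n_unique = len(set(seqs))

    n_variable = 0
    singletons = 0
    for col in zip(*seqs):
        counts = Counter(s for s in col if s in BASES)
        if len(counts) >= 2:
            n_variable += 1
            singletons += sum(1 for c in counts.values() if c == 1)

    n_aa: int | None = None
    if do_aa:
        table = _codon_table()
        n_aa = 0
        for cstart in range(0, width, 3):
            aas = set()
            for s in seqs:
                codon = s[cstart : cstart + 3]
                if GAP in codon or MISSING in codon:
                    continue
                aas.add(table[codon])
            if len(aas) >= 2:
                n_aa += 1

    pi_vals = []
    for i in range(n):
        for j in range(i + 1, n):
            diffs = comp = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in BASES and b in BASES:
                    comp += 1
                    if a != b:
                        diffs += 1
            if comp:
                pi_vals.append(diffs / comp)
    pi = sum(pi_vals) / len(pi_vals) if pi_vals else 0.0

    return PolymorphismSummary(
        n_sequences=n,
        n_unique_alleles=n_unique,
        n_variable_sites=n_variable,
        n_aa_polymorphisms=n_aa,
        pairwise_pi=pi,
        singleton_count=singletons,
        est_error_rate=est_error_rate,
    )


# ---------------------------------------------------------------------------
# Breakpoint partition
# ---------------------------------------------------------------------------

def _clip_region(r: Region, lo: int, hi: int, offset: int) -> Region | None:
    start = max(r.start, lo)
    end = min(r.end, hi)
    if start > end:
        return None
    return Region(r.name, start - offset, end - offset, r.cls)


def partition_at_breakpoint(aln: PopAlignment) -> tuple[PopAlignment, PopAlignment]:
    """Split the alignment into columns [1, breakpoint] and the remainder.

    Region-map spans are clipped to each partition and re-expressed in
    partition-local coordinates.
    """
    bp = aln.breakpoint
    if bp is None:
        raise ValueError("alignment has no breakpoint configured")
    length = aln.length
    if not (1 < bp < length):
        raise ValueError(f"breakpoint {bp} outside (1, {length})")
    left = {a: s[:bp] for a, s in aln.alleles.items()}
    right = {a: s[bp:] for a, s in aln.alleles.items()}
    regions_left = [
        c for r in aln.region_map if (c := _clip_region(r, 1, bp, 0)) is not None
    ]
    regions_right = [
        c for r in aln.region_map if (c := _clip_region(r, bp + 1, length, bp)) is not None
    ]
    p1 = PopAlignment(left, dict(aln.meta), regions_left, None)
    p2 = PopAlignment(right, dict(aln.meta), regions_right, None)
    return p1, p2
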