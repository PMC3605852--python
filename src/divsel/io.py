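"""File I/O for alignments, sample sheets, region maps and domain-span tables.

All coordinates in region and domain files are 1-based inclusive alignment
columns, matching the convention used throughout the package.
"""
from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PathLike = Union[str, Path]


def read_fasta_alignment(path: PathLike, format: str | None = None) -> dict[str, str]:
    """Read an aligned FASTA (or GenBank) file into an {id: sequence} mapping.

    The format is sniffed from the first line unless given ("fasta" or
    "genbank"; GenBank flat files are accepted for comparison loci pulled
    from the archives). Sequences are upper-cased and must share one length.
    """
    if format is None:
        with open(path) as fh:
            first = fh.readline()
        format = "genbank" if first.startswith("LOCUS") else "fasta"
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), format):
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"no sequences found in {path}")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError(f"sequences in {path} have unequal lengths: {sorted(lengths)}")
    return seqs


def write_fasta_alignment(seqs: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def fasta_string(seqs: dict[str, str]) -> str:
    """Serialize an alignment to a FASTA string (used for byte-identity checks)."""
    buf = _io.StringIO()
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, buf, "fasta")
    return buf.getvalue()


def read_sample_sheet(path: PathLike) -> dict[str, tuple[str, str]]:
    """Read a TSV with columns allele_id, individual_id, population."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"allele_id", "individual_id", "population"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return {r.allele_id: (r.individual_id, r.population) for r in df.itertuples()}


def write_sample_sheet(meta: dict[str, tuple[str, str]], path: PathLike) -> None:
    df = pd.DataFrame(
        [(a, ind, pop) for a, (ind, pop) in meta.items()],
        columns=["allele_id", "individual_id", "population"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_regions(path: PathLike):
    """Read a region-map TSV with columns name, start, end, class."""
    from .alleles_qc import Region

    df = pd.read_csv(path, sep="\t", dtype={"name": str, "class": str})
    required = {"name", "start", "end", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"region file missing columns: {sorted(missing)}")
    return [
        Region(str(row["name"]), int(row["start"]), int(row["end"]), str(row["class"]))
        for _, row in df.iterrows()
    ]


def write_regions(regions, path: PathLike) -> None:
    df = pd.DataFrame(
        [(r.name, r.start, r.end, r.cls) for r in regions],
        columns=["name", "start", "end", "class"],
    )
    df.to_csv(path, sep="\t", index=False)


def read_domain_spans(path: PathLike) -> list[tuple[str, int, int, int]]:
    """Read a repeat-domain span TSV with columns domain, copy_index, start, end."""
    df = pd.read_csv(path, sep="\t", dtype={"domain": str})
    required = {"domain", "copy_index", "start", "end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"domain file missing columns: {sorted(missing)}")
    return [
        (r.domain, int(r.copy_index), int(r.start), int(r.end)) for r in df.itertuples()
    ]


def write_domain_spans(spans, path: PathLike) -> None:
    df = pd.DataFrame(spans, columns=["domain", "copy_index", "start", "end"])
    df.to_csv(path, sep="\t", index=False)
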