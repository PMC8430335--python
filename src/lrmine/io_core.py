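"""Sequence I/O, assembly statistics and shared tabular formats.

All coordinates in gene/feature tables are 1-based, fully closed intervals
(GFF3 convention); strand is ``"+"`` / ``"-"``. FASTQ quality strings are
parsed and carried along but ignored by every statistic in the package
(Sequel II CCS data ships without per-base phred scores, so nothing
downstream may rely on them).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

logger = logging.getLogger("lrmine")

VALID_SOURCES = ("long_read", "short_read", "contig", "genome", "virome")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class FormatError(ValueError):
    """Raised for malformed input files; the message names the offending entry."""


@dataclass
class SequenceRecord:
    """A read, contig, genome or viral sequence.

    ``seq`` is an uppercase DNA string over {A,C,G,T,N}; ``qual`` is an
    optional list of per-base integer scores of the same length.
    """

    id: str
    seq: str
    qual: Sequence[int] | None = None
    source: str = "contig"

    def __post_init__(self) -> None:
        if len(self.seq) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        return SequenceRecord(
            id=self.id,
            seq=revcomp(self.seq),
            qual=None if self.qual is None else list(self.qual)[::-1],
            source=self.source,
        )


@dataclass
class GeneRecord:
    """A called gene on a parent sequence (read, contig or genome).

    ``taxon_path`` is a rank-ordered tuple of labels (domain ... genus);
    empty means no hit. ``family`` is an optional functional label such as
    ``"GT"``, ``"rhodopsin"`` or a marker tag.
    """

    gene_id: str
    parent_id: str
    start: int  # 1-based, closed
    end: int
    strand: str = "+"
    taxon_path: tuple[str, ...] = ()
    family: str | None = None
    evalue: float | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id!r}: start > end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")


@dataclass
class AssemblyStats:
    n_sequences: int
    total_bp: int
    max_len: int
    mean_len: float
    n50: int
    l50: int
    gc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _open_maybe_gzip(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, source: str = "contig") -> list[SequenceRecord]:
    """Read a FASTA file; sequences are uppercased and U is mapped to T.

    Raises :class:`FormatError` for entries with empty sequences or for
    files that do not start with a header line.
    """
    records: list[SequenceRecord] = []
    with _open_maybe_gzip(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty file")
        if first != ">":
            raise FormatError(f"{path}: line 1: expected FASTA header starting with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            seq = _normalize(str(rec.seq))
            if not seq:
                raise FormatError(f"{path}: entry {rec.id!r} has an empty sequence")
            records.append(SequenceRecord(id=rec.id, seq=seq, source=source))
    return records


def read_fastq(path: str | Path, source: str = "long_read") -> list[SequenceRecord]:
    records = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq"):
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=_normalize(str(rec.seq)),
                    qual=rec.letter_annotations.get("phred_quality"),
                    source=source,
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 80) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_maybe_gzip(path, "wt") as fh:
        for rec in records:
            qual = rec.qual if rec.qual is not None else [30] * len(rec.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


def gc_content(record: SequenceRecord | str) -> float:
    """GC fraction of a sequence; N bases are excluded from both numerator
    and denominator. Returns NaN (flagged missing) for an all-N sequence."""
    seq = record.seq if isinstance(record, SequenceRecord) else record
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    gc = np.count_nonzero((arr == ord("G")) | (arr == ord("C")))
    at = np.count_nonzero((arr == ord("A")) | (arr == ord("T")))
    if gc + at == 0:
        logger.warning("gc_content: all-N sequence, value undefined")
        return float("nan")
    return gc / (gc + at)


def assembly_stats(records: Sequence[SequenceRecord]) -> AssemblyStats:
    """N50/L50-style summary of a sequence set.

    N50 is the length of the sequence at which the cumulative length, in
    descending length order, first reaches >= half the total; L50 is the
    number of sequences needed to get there.
    """
    if not records:
        raise ValueError("assembly_stats: empty input")
    lengths = np.sort(np.array([len(r) for r in records]))[::-1]
    total = int(lengths.sum())
    cum = np.cumsum(lengths)
    l50 = int(np.searchsorted(cum, total / 2, side="left") + 1)
    n50 = int(lengths[l50 - 1])
    gc_counts = at_counts = 0
    for r in records:
        arr = np.frombuffer(r.seq.encode("ascii"), dtype=np.uint8)
        gc_counts += int(np.count_nonzero((arr == ord("G")) | (arr == ord("C"))))
        at_counts += int(np.count_nonzero((arr == ord("A")) | (arr == ord("T"))))
    gc = gc_counts / (gc_counts + at_counts) if gc_counts + at_counts else float("nan")
    return AssemblyStats(
        n_sequences=len(records),
        total_bp=total,
        max_len=int(lengths[0]),
        mean_len=float(total / len(records)),
        n50=n50,
        l50=l50,
        gc=gc,
    )


# ---------------------------------------------------------------------------
# gene tables


GENE_COLUMNS = ["gene_id", "parent_id", "start", "end", "strand", "taxon_path", "family", "evalue"]


def write_genes_tsv(genes: Iterable[GeneRecord], path: str | Path) -> None:
    rows = [
        {
            "gene_id": g.gene_id,
            "parent_id": g.parent_id,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "taxon_path": ";".join(g.taxon_path),
            "family": g.family if g.family is not None else "",
            "evalue": g.evalue if g.evalue is not None else "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=GENE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genes_tsv(path: str | Path) -> list[GeneRecord]:
    df = pd.read_csv(
        path, sep="\t", dtype={"taxon_path": str, "family": str},
        float_precision="round_trip",
    )
    genes = []
    for row in df.itertuples(index=False):
        taxon = tuple(str(row.taxon_path).split(";")) if isinstance(row.taxon_path, str) and row.taxon_path else ()
        family = row.family if isinstance(row.family, str) and row.family else None
        evalue = float(row.evalue) if pd.notna(row.evalue) and row.evalue != "" else None
        genes.append(
            GeneRecord(
                gene_id=str(row.gene_id),
                parent_id=str(row.parent_id),
                start=int(row.start),
                end=int(row.end),
                strand=str(row.strand),
                taxon_path=taxon,
                family=family,
                evalue=evalue,
            )
        )
    return genes


def write_gff3(genes: Iterable[GeneRecord], path: str | Path, source: str = "lrmine") -> None:
    """Minimal GFF3 writer for gene records (1-based closed coordinates)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.taxon_path:
                attrs.append("taxon_path=" + ";".join(g.taxon_path).replace(";", "%3B"))
            if g.family:
                attrs.append(f"family={g.family}")
            score = f"{g.evalue:.3g}" if g.evalue is not None else "."
            fh.write(
                f"{g.parent_id}\t{source}\tgene\t{g.start}\t{g.end}\t{score}\t{g.strand}\t0\t"
                + ",".join(attrs)
                + "\n"
            )


# ---------------------------------------------------------------------------
# configuration and logging


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg if cfg is not None else {}


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
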