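"""Read quality assessed through ORF length statistics.

CCS long reads carry no phred scores, but sequencing errors inject stop
codons (substitutions) and frameshifts (indels) into coding sequence, so
the average predicted protein length of a read set is a direct error
proxy: the higher the per-base error rate, the shorter the called ORFs and
the more (short) proteins per megabase. This module provides

* a deterministic six-frame stop-to-stop ORF caller (``call_orfs``),
* per-read-set QC summaries (``read_qc``), and
* a closed-form expectation for the mean called ORF length as a function
  of the per-base error rate (``expected_mean_orf``).

Absolute protein counts are caller-dependent (a coding-potential caller
such as Prodigal reports different numbers); the monotone response of the
statistics to the error rate is not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_core import SequenceRecord, revcomp

STOP_CODONS = ("TAA", "TAG", "TGA")  # translation table 11
START_CODONS = ("ATG", "GTG", "TTG")

_BASE_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_SENSE_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]


def _codon_code(codon: str) -> int:
    a, b, c = (_BASE_CODE[ord(x)] for x in codon)
    return int(a) * 16 + int(b) * 4 + int(c)


_STOP_CODES = frozenset(_codon_code(c) for c in STOP_CODONS)
_START_CODES = frozenset(_codon_code(c) for c in START_CODONS)
_STOP_LUT = np.zeros(65, dtype=bool)
for _c in _STOP_CODES:
    _STOP_LUT[_c] = True
_START_LUT = np.zeros(65, dtype=bool)
for _c in _START_CODES:
    _START_LUT[_c] = True


@dataclass
class OrfCall:
    """One called ORF. Coordinates are 1-based closed on the forward strand
    of the parent sequence; ``frame`` is +1/+2/+3 (forward) or -1/-2/-3
    (reverse complement). ``has_stop`` records whether a stop codon (not the
    sequence edge) terminated the ORF; the stop codon is included in the
    span but not in ``aa_len``."""

    read_id: str
    frame: int
    start: int
    end: int
    aa_len: int
    has_stop: bool = True


@dataclass
class ReadQcReport:
    n_reads: int
    n_proteins: int
    mean_protein_aa: float
    proteins_per_mb: float
    total_bp: int


def _frame_orfs(codes: np.ndarray, min_aa: int) -> list[tuple[int, int, bool]]:
    """ORFs in one frame: (start_codon_idx, end_codon_idx_exclusive_of_stop,
    terminated). An ORF is a maximal stop-free codon run, reported from its
    first start codon; runs abut stops or the sequence edges."""
    stop_mask = _STOP_LUT[codes]
    start_mask = _START_LUT[codes]
    n = len(codes)
    stops = np.flatnonzero(stop_mask)
    seg_starts = np.concatenate(([0], stops + 1))
    seg_ends = np.concatenate((stops, [n]))
    keep = (seg_ends - seg_starts) >= min_aa
    if not keep.any():
        return []
    start_idx = np.flatnonzero(start_mask)
    out = []
    for s, e in zip(seg_starts[keep], seg_ends[keep]):
        i = np.searchsorted(start_idx, s)
        if i == len(start_idx):
            continue
        pos = start_idx[i]
        if pos >= e or e - pos < min_aa:
            continue
        out.append((int(pos), int(e), bool(e < n)))
    return out


def call_orfs(record: SequenceRecord | str, min_aa: int = 30) -> list[OrfCall]:
    """Six-frame stop-to-stop ORF calling with starts ATG/GTG/TTG and stops
    TAA/TAG/TGA; ORFs shorter than ``min_aa`` amino acids are discarded.
    ORFs running into a sequence edge are reported without a terminating
    stop (``has_stop=False``)."""
    if isinstance(record, SequenceRecord):
        read_id, seq = record.id, record.seq
    else:
        read_id, seq = "", record
    n = len(seq)
    calls: list[OrfCall] = []
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        arr = _BASE_CODE[np.frombuffer(s.encode("ascii"), dtype=np.uint8)]
        for off in range(3):
            k = (n - off) // 3
            if k < min_aa:
                continue
            c = arr[off : off + 3 * k].reshape(-1, 3).astype(np.int16)
            codes = np.where(
                (c >= 4).any(axis=1), 64, c[:, 0] * 16 + c[:, 1] * 4 + c[:, 2]
            )
            for pos, e, terminated in _frame_orfs(codes, min_aa):
                aa_len = e - pos
                b0 = off + 3 * pos  # 0-based on this strand
                b1 = off + 3 * (e + (1 if terminated else 0)) - 1
                if strand == 1:
                    start, end = b0 + 1, b1 + 1
                else:
                    start, end = n - b1, n - b0
                calls.append(
                    OrfCall(
                        read_id=read_id,
                        frame=strand * (off + 1),
                        start=start,
                        end=end,
                        aa_len=aa_len,
                        has_stop=terminated,
                    )
                )
    calls.sort(key=lambda o: (o.start, o.end, o.frame))
    return calls


def read_qc(
    records: Iterable[SequenceRecord],
    min_read_bp: int = 1000,
    min_aa: int = 30,
) -> ReadQcReport:
    """QC summary over reads strictly longer than ``min_read_bp``.

    ``proteins_per_mb`` is normalised by the total bp of the surviving
    reads, matching how proteins-per-megabase-sequenced is tabulated.
    """
    n_reads = 0
    n_prot = 0
    aa_total = 0
    bp_total = 0
    for rec in records:
        if len(rec) <= min_read_bp:
            continue
        n_reads += 1
        bp_total += len(rec)
        for orf in call_orfs(rec, min_aa=min_aa):
            n_prot += 1
            aa_total += orf.aa_len
    if n_reads == 0:
        raise ValueError(f"read_qc: no reads longer than {min_read_bp} bp")
    mean_aa = aa_total / n_prot if n_prot else float("nan")
    return ReadQcReport(
        n_reads=n_reads,
        n_proteins=n_prot,
        mean_protein_aa=mean_aa,
        proteins_per_mb=n_prot / (bp_total / 1e6),
        total_bp=bp_total,
    )


def stop_gain_fraction() -> float:
    """Fraction of the 9 single-base substitutions of a sense codon that
    create a stop codon, averaged uniformly over the 61 sense codons
    (exact enumeration of the genetic code)."""
    hits = 0
    total = 0
    for codon in _SENSE_CODONS:
        for i in range(3):
            for b in "ACGT":
                if b == codon[i]:
                    continue
                total += 1
                if codon[:i] + b + codon[i + 1 :] in STOP_CODONS:
                    hits += 1
    return hits / total


def truncation_coefficient(sub_ins_del: Sequence[float] = (1.0, 1.0, 1.0)) -> float:
    """Probability that a single-base error truncates the reading frame:
    substitutions truncate when they create a stop (exact genetic-code
    enumeration); insertions and deletions always truncate (a frameshift
    ends the readable ORF)."""
    w = np.asarray(sub_ins_del, dtype=float)
    if w.sum() <= 0:
        raise ValueError("sub:ins:del weights must be positive")
    w = w / w.sum()
    return float(w[0] * stop_gain_fraction() + w[1] + w[2])


def expected_mean_orf(
    L0: float, eps: float, sub_ins_del: Sequence[float] = (1.0, 1.0, 1.0)
) -> float:
    """Expected mean called ORF length (aa) for true mean protein length
    ``L0`` under per-base error rate ``eps``:

        1 / (1/L0 + q),   q = 1 - (1 - c*eps)^3

    where q is the per-codon truncation probability and c the per-error
    truncation coefficient. Exact when gene lengths are memoryless, which
    is how the synthetic generator draws them."""
    if L0 <= 0:
        raise ValueError("L0 must be positive")
    c = truncation_coefficient(sub_ins_del)
    q = 1.0 - (1.0 - c * eps) ** 3
    return 1.0 / (1.0 / L0 + q)
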