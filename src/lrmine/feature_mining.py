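"""Flexible-genome feature detectors.

Replacement flexible genomic islands (glycosylation islands) are marked by
runs of glycosyltransferase (GT) genes: a fragment qualifies when at least
five GT genes with E-value < 1e-40 fall inside a window of at most 20
consecutive genes on a parent of at least 5 kb. Additive islands carry
CRISPR arrays, detected here by a minimal repeat-chain finder, with spacer
protospacer matching against a virome under the strict rule
identity > 97% over 100% of the spacer. Protein inventories (rhodopsins)
are de-replicated by greedy incremental clustering at decreasing identity
levels, cd-hit style.

Identity conventions: short DNA (spacers) uses exact Hamming identity over
the full spacer at every target offset on both strands — no heuristics;
proteins use global alignment with unit gap costs, identity = matches /
alignment columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import Align

from .io_core import GeneRecord, SequenceRecord, revcomp

logger = logging.getLogger("lrmine.features")


# --- GT islands ------------------------------------------------------------


@dataclass
class GtIsland:
    parent_id: str
    gene_window: list[str]  # ordered gene ids from first to last GT
    n_gt: int
    span_bp: int
    start: int
    end: int


def scan_gt_islands(
    genes: Sequence[GeneRecord],
    min_gt: int = 5,
    window_genes: int = 20,
    min_parent_bp: int = 5000,
    max_evalue: float = 1e-40,
    parent_len: int | None = None,
) -> list[GtIsland]:
    """GT-island scan over the ordered gene list of one parent.

    A window of <= ``window_genes`` consecutive genes containing >=
    ``min_gt`` GT genes (family "GT", E-value < ``max_evalue``) qualifies;
    overlapping qualifying windows are merged into one island, reported
    trimmed to its first and last GT gene.
    """
    if not genes:
        return []
    if parent_len is not None and parent_len < min_parent_bp:
        return []
    order = sorted(range(len(genes)), key=lambda i: (genes[i].start, genes[i].end))
    genes = [genes[i] for i in order]
    gt_idx = [
        i
        for i, g in enumerate(genes)
        if g.family == "GT" and g.evalue is not None and g.evalue < max_evalue
    ]
    if len(gt_idx) < min_gt:
        return []
    # Every qualifying window contains a "core": min_gt consecutive GT
    # genes spanning <= window_genes genes. The union of all qualifying
    # windows containing a given core is its core interval expanded by the
    # window size on both sides; merging these expansions therefore merges
    # exactly the overlapping qualifying windows. Islands are reported
    # trimmed to their first and last GT gene.
    n = len(genes)
    expanded = []
    for t in range(len(gt_idx) - min_gt + 1):
        i0, i1 = gt_idx[t], gt_idx[t + min_gt - 1]
        if i1 - i0 + 1 <= window_genes:
            expanded.append(
                (max(0, i1 - window_genes + 1), min(n - 1, i0 + window_genes - 1))
            )
    if not expanded:
        return []
    merged = [list(expanded[0])]
    for a, b in expanded[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    islands = []
    for lo, hi in merged:
        gts = [i for i in gt_idx if lo <= i <= hi]
        a, b = gts[0], gts[-1]
        islands.append(
            GtIsland(
                parent_id=genes[a].parent_id,
                gene_window=[g.gene_id for g in genes[a : b + 1]],
                n_gt=len(gts),
                span_bp=genes[b].end - genes[a].start + 1,
                start=genes[a].start,
                end=genes[b].end,
            )
        )
    return islands


# --- CRISPR arrays ---------------------------------------------------------


@dataclass
class CrisprArray:
    parent_id: str
    repeat_consensus: str
    n_repeats: int
    spacers: list[str]
    evidence: int  # = n_repeats (documented package score)
    start: int  # 1-based closed span of the array
    end: int
    repeat_starts: list[int] = field(default_factory=list)  # 1-based


_ANCHOR_K = 13


def _hamming_hits(seq_arr: np.ndarray, pattern: str, max_mismatch: int) -> np.ndarray:
    """Start positions (0-based) where the pattern matches within the
    mismatch budget; overlapping hits reduced to local minima."""
    m = len(pattern)
    if len(seq_arr) < m:
        return np.array([], dtype=int)
    win = np.lib.stride_tricks.sliding_window_view(seq_arr, m)
    pat = np.frombuffer(pattern.encode("ascii"), dtype=np.uint8)
    dist = (win != pat).sum(axis=1)
    cand = np.flatnonzero(dist <= max_mismatch)
    hits = []
    for p in cand:
        if hits and p - hits[-1] < m:
            if dist[p] < dist[hits[-1]]:
                hits[-1] = p
        else:
            hits.append(p)
    return np.array(hits, dtype=int)


def _column_support(seq: str, starts: Sequence[int], offset: int) -> tuple[str, int]:
    """Majority base and its count over the given copies at one column."""
    col = [seq[s + offset] for s in starts if 0 <= s + offset < len(seq)]
    if len(col) < len(starts):
        return "", 0
    vals, counts = np.unique(col, return_counts=True)
    i = int(np.argmax(counts))
    return str(vals[i]), int(counts[i])


def detect_crispr(
    record: SequenceRecord,
    repeat_len_range: tuple[int, int] = (21, 48),
    spacer_len_range: tuple[int, int] = (20, 72),
    min_repeats: int = 3,
    min_repeat_identity: float = 0.9,
    min_seq_bp: int = 5000,
) -> list[CrisprArray]:
    """Minimal CRISPR array detector.

    Finds chains of >= ``min_repeats`` near-identical repeats (each >=
    ``min_repeat_identity`` to the column-majority consensus) separated by
    spacer gaps within ``spacer_len_range``. Candidate repeats are seeded
    by exact 13-mers recurring at an array-compatible distance, extended
    to the maximal exact match, chained by Hamming search, and the repeat
    boundaries set to the maximum-scoring column interval of cross-copy
    agreement (each column scores its majority support minus a threshold
    near the copy number). The evidence score is the repeat count — a
    package-specific scale, not comparable to detector-specific scores
    such as CRISPRdetect's.
    """
    seq = record.seq
    n = len(seq)
    if n < min_seq_bp:
        raise ValueError(f"sequence shorter than {min_seq_bp} bp")
    rmin, rmax = repeat_len_range
    smin, smax = spacer_len_range
    gap_min, gap_max = rmin + smin, rmax + smax
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)

    # vectorised anchor scan: positions of recurring 13-mers at an
    # array-compatible distance
    base = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        base[ord(b)] = i
    enc = base[arr]
    m = n - _ANCHOR_K + 1
    codes = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(_ANCHOR_K):
        window = enc[j : j + m]
        codes = codes * 4 + np.where(window >= 0, window, 0)
        valid &= window >= 0
    order = np.argsort(codes[valid], kind="stable")
    pos_valid = np.flatnonzero(valid)[order]
    sorted_codes = codes[valid][order]
    same = sorted_codes[1:] == sorted_codes[:-1]
    gaps = pos_valid[1:] - pos_valid[:-1]
    pair_ok = same & (gaps >= gap_min) & (gaps <= gap_max) & (gaps > 0)
    candidates = [
        (int(pos_valid[i]), int(pos_valid[i + 1])) for i in np.flatnonzero(pair_ok)
    ]
    candidates.sort()
    if not candidates:
        return []

    arrays: list[CrisprArray] = []
    accepted_spans: list[tuple[int, int]] = []
    rejected_spans: list[tuple[int, int]] = []
    for p, q in candidates:
        if any(a <= p <= b for a, b in accepted_spans + rejected_spans):
            continue
        # maximal exact match around the anchor pair; with mutated repeats
        # this may recover only part of the repeat, so the length decision
        # is deferred to the column refinement below
        left = 0
        while p - left - 1 >= 0 and seq[p - left - 1] == seq[q - left - 1]:
            left += 1
        right = _ANCHOR_K
        while q + right < n and seq[p + right] == seq[q + right] and right < rmax + 8:
            right += 1
        rep = seq[p - left : p + right][: rmax + 4]
        budget = int((1 - min_repeat_identity) * len(rep)) + 1
        # local chain first: cheap window scan rejects periodic sequence
        # motifs (e.g. coding microsatellites) before any global work
        wlo = max(0, p - 2500)
        whi = min(n, q + 2500)
        hits = _hamming_hits(arr[wlo:whi], rep, max_mismatch=budget) + wlo
        if len(hits) < min_repeats:
            continue
        chains = [[int(hits[0])]]
        for h in hits[1:]:
            gap = int(h) - chains[-1][-1] - len(rep)
            if smin <= gap <= smax:
                chains[-1].append(int(h))
            else:
                chains.append([int(h)])
        # analyse the chain the candidate itself belongs to, falling back
        # to the longest one in the window
        containing = [
            c for c in chains if c[0] - len(rep) <= p <= c[-1] + len(rep)
        ]
        chain = max(containing or chains, key=len)
        # memo span for rejections: suppresses the many sibling candidates
        # a periodic coding motif spawns within the same chain
        chain_span = (chain[0], chain[-1] + len(rep))
        if len(chain) < min_repeats:
            rejected_spans.append(chain_span)
            continue
        # Refine boundaries outward from the anchor k-mer, which is known
        # to lie inside the repeat. Each column contributes its cross-copy
        # majority support minus a threshold near n; the boundary is the
        # cumulative argmax. Unanimous columns extend, chance spacer
        # agreement trims; with >= 5 copies a column carrying a repeat
        # mutation can be recovered by unanimous columns beyond it (below
        # 5 copies a mutated column is statistically indistinguishable
        # from chance, so the rule demands unanimity there). Boundary
        # columns whose support ties chance agreement are intrinsically
        # ambiguous, so mutated-array boundaries may be off by one.
        nch = len(chain)
        below = [c for c in chain if c <= p]
        c0 = below[-1] if below else chain[0]
        anchor_lo = min(max(p - c0, 0), max(len(rep) - _ANCHOR_K, 0))
        anchor_hi = anchor_lo + _ANCHOR_K  # exclusive
        threshold = nch - 0.75 if nch >= 5 else nch - 0.25
        # maximum-scoring contiguous column interval overlapping the anchor
        # (prefix-sum argmax); chance-matching columns, including any that
        # slipped inside the exact anchor match, score negative and fall
        # outside the optimum
        offs = list(range(anchor_lo - rmax, anchor_hi + rmax))
        scores = [
            _column_support(seq, chain, off)[1] - threshold for off in offs
        ]
        prefix = [0.0]
        for s in scores:
            prefix.append(prefix[-1] + s)
        a_lo = offs.index(anchor_lo)
        a_hi = offs.index(anchor_hi - 1)
        i_star = min(range(a_hi + 1), key=lambda i: prefix[i])
        j_star = max(range(a_lo, len(offs)), key=lambda j: prefix[j + 1])
        if i_star > j_star:
            rejected_spans.append(chain_span)
            continue
        lo_off = offs[i_star]
        hi_off = offs[j_star] + 1
        starts = [c + lo_off for c in chain]
        rlen = hi_off - lo_off
        if not (rmin <= rlen <= rmax):
            rejected_spans.append(chain_span)
            continue
        if starts[0] < 0 or starts[-1] + rlen > n:
            rejected_spans.append(chain_span)
            continue
        consensus = "".join(
            _column_support(seq, starts, off)[0] for off in range(rlen)
        )
        # extend the chain stepwise beyond the local window
        cbudget = int((1 - min_repeat_identity) * rlen) + 1
        while True:
            lo = starts[-1] + rlen + smin
            hi = min(n, starts[-1] + rlen + smax + rlen)
            if lo >= n:
                break
            nxt = _hamming_hits(arr[lo:hi], consensus, max_mismatch=cbudget)
            if len(nxt) == 0:
                break
            starts.append(int(nxt[0]) + lo)
        while True:
            hi = starts[0] - smin
            lo = max(0, starts[0] - smax - rlen)
            if hi - lo < rlen:
                break
            prv = _hamming_hits(arr[lo:hi], consensus, max_mismatch=cbudget)
            if len(prv) == 0:
                break
            starts.insert(0, int(prv[-1]) + lo)
        copies = [seq[s : s + rlen] for s in starts]
        if any(
            sum(a != b for a, b in zip(c, consensus)) / rlen > 1 - min_repeat_identity
            for c in copies
        ):
            continue
        spacers = [
            seq[starts[i] + rlen : starts[i + 1]] for i in range(len(starts) - 1)
        ]
        if any(not (smin <= len(s) <= smax) for s in spacers):
            continue
        span = (starts[0] + 1, starts[-1] + rlen)
        if any(a <= span[1] and b >= span[0] for a, b in accepted_spans):
            continue
        accepted_spans.append(span)
        arrays.append(
            CrisprArray(
                parent_id=record.id,
                repeat_consensus=consensus,
                n_repeats=len(starts),
                spacers=spacers,
                evidence=len(starts),
                start=span[0],
                end=span[1],
                repeat_starts=[s + 1 for s in starts],
            )
        )
    arrays.sort(key=lambda a: a.start)
    return arrays


# --- spacer ↔ protospacer matching ----------------------------------------


@dataclass
class SpacerMatch:
    spacer_id: str
    target_id: str
    identity: float  # percent over the full spacer
    aligned_fraction: float  # always 1.0 for accepted matches
    position: int  # 1-based start on the target's forward strand
    strand: str


def match_spacers(
    spacers: Mapping[str, str] | Sequence[tuple[str, str]],
    targets: Iterable[SequenceRecord],
    min_identity: float = 97.0,
    require_full: bool = True,
) -> list[SpacerMatch]:
    """Match CRISPR spacers to candidate protospacers.

    Exact Hamming comparison of the full spacer at every target offset on
    both strands; identity is computed over the spacer length, alignment
    must cover the entire spacer (edge-overhanging placements are never
    considered), and acceptance is strictly identity > ``min_identity``.
    The best placement per (spacer, target, strand) is reported.
    """
    items = list(spacers.items()) if isinstance(spacers, Mapping) else list(spacers)
    targets = list(targets)
    encoded = {
        t.id: np.frombuffer(t.seq.encode("ascii"), dtype=np.uint8) for t in targets
    }
    matches: list[SpacerMatch] = []
    for sid, spacer in items:
        L = len(spacer)
        if not require_full:
            raise NotImplementedError("only full-length spacer alignment is supported")
        pat_f = np.frombuffer(spacer.encode("ascii"), dtype=np.uint8)
        pat_r = np.frombuffer(revcomp(spacer).encode("ascii"), dtype=np.uint8)
        for t in targets:
            arr = encoded[t.id]
            if len(arr) < L:
                continue
            win = np.lib.stride_tricks.sliding_window_view(arr, L)
            for strand, pat in (("+", pat_f), ("-", pat_r)):
                mism = (win != pat).sum(axis=1)
                best = int(np.argmin(mism))
                identity = 100.0 * (L - int(mism[best])) / L
                if identity > min_identity:
                    matches.append(
                        SpacerMatch(
                            spacer_id=sid,
                            target_id=t.id,
                            identity=identity,
                            aligned_fraction=1.0,
                            position=best + 1,
                            strand=strand,
                        )
                    )
    return matches


# --- protein clustering ----------------------------------------------------


@dataclass
class ProteinCluster:
    level: int  # percent identity
    representative_id: str
    member_ids: list[str]  # at levels below 100 these are lower-level representatives


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 0
_aligner.mismatch_score = -1
_aligner.open_gap_score = -1
_aligner.extend_gap_score = -1


def protein_identity(a: str, b: str) -> float:
    """Percent identity of a unit-gap-cost global alignment:
    matches / alignment columns * 100."""
    if a == b:
        return 100.0
    aln = _aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def greedy_cluster(
    proteins: Sequence[tuple[str, str]], level: float
) -> list[ProteinCluster]:
    """Greedy incremental clustering at one identity level: sequences are
    taken longest-first; each joins the first cluster whose representative
    it matches at >= ``level`` percent identity, else founds a cluster."""
    ordered = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    clusters: list[ProteinCluster] = []
    reps: list[str] = []
    for pid, seq in ordered:
        placed = False
        for c, rep_seq in zip(clusters, reps):
            if protein_identity(seq, rep_seq) >= level:
                c.member_ids.append(pid)
                placed = True
                break
        if not placed:
            clusters.append(
                ProteinCluster(level=int(level), representative_id=pid, member_ids=[pid])
            )
            reps.append(seq)
    return clusters


def hierarchical_cluster(
    proteins: Iterable[SequenceRecord] | Mapping[str, str],
    levels: Sequence[int] = (100, 90, 80, 70, 60, 50, 40, 30),
    min_len: int = 200,
) -> dict[int, list[ProteinCluster]]:
    """Hierarchical identity clustering from high to low identity.

    Sequences shorter than or equal to ``min_len`` amino acids are dropped
    first. The top level clusters the input sequences; every later level
    clusters the previous level's representatives, so cluster counts are
    non-increasing as the level decreases.
    """
    if isinstance(proteins, Mapping):
        pool = [(k, v) for k, v in proteins.items()]
    else:
        pool = [(r.id, r.seq) for r in proteins]
    pool = [(k, v) for k, v in pool if len(v) > min_len]
    if not pool:
        raise ValueError(f"no proteins longer than {min_len} aa")
    seqs = dict(pool)
    out: dict[int, list[ProteinCluster]] = {}
    current = pool
    for level in sorted(levels, reverse=True):
        clusters = greedy_cluster(current, level)
        out[level] = clusters
        current = [(c.representative_id, seqs[c.representative_id]) for c in clusters]
    return out


def per_gb_rate(n_features: int, dataset_bp: int) -> float:
    """Features per Gb of sequence."""
    if dataset_bp <= 0:
        raise ValueError("dataset_bp must be positive")
    return n_features / (dataset_bp / 1e9)
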