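"""Independent brute-force oracles used by the test suite.

These deliberately use the simplest possible formulation — plain Python
loops and dictionaries, no shared code with the implementation — so that
agreement between the two routes is meaningful.
"""

from collections import Counter

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
STOPS = {"TAA", "TAG", "TGA"}
STARTS = {"ATG", "GTG", "TTG"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def orfs_bruteforce(seq: str, min_aa: int = 30):
    """All six-frame ORFs: maximal stop-free codon runs reported from the
    first start codon, including runs cut by the sequence edge.
    Returns a set of (frame, start, end, aa_len, has_stop) with 1-based
    closed forward-strand coordinates."""
    n = len(seq)
    out = set()
    for strand, s in ((1, seq), (-1, revcomp(seq))):
        for off in range(3):
            codons = []
            i = off
            while i + 3 <= n:
                codons.append((i, s[i : i + 3]))
                i += 3
            segment = []
            for idx, (pos, codon) in enumerate(codons + [(None, "TAA")]):
                terminated = codon in STOPS and pos is not None
                if codon in STOPS:
                    # close the current stop-free run
                    first_start = None
                    for j, (p2, c2) in enumerate(segment):
                        if c2 in STARTS:
                            first_start = j
                            break
                    if first_start is not None:
                        run = segment[first_start:]
                        if len(run) >= min_aa:
                            b0 = run[0][0]
                            b1 = run[-1][0] + 2 + (3 if terminated else 0)
                            if strand == 1:
                                start, end = b0 + 1, b1 + 1
                            else:
                                start, end = n - b1, n - b0
                            out.add(
                                (strand * (off + 1), start, end, len(run), terminated)
                            )
                    segment = []
                else:
                    segment.append((pos, codon))
    return out


def consensus_bruteforce(labels, parent_len, threshold=0.5, min_len=5000):
    """Majority vote over per-gene labels (None = no hit); returns the
    winning label or 'unclassified'."""
    n = len(labels)
    if parent_len < min_len or n == 0:
        return "unclassified"
    counts = Counter(l for l in labels if l is not None)
    if not counts:
        return "unclassified"
    best = max(counts.values())
    winners = [t for t, c in counts.items() if c == best]
    if len(winners) != 1:
        return "unclassified"
    if best / n < threshold:
        return "unclassified"
    return winners[0]


def gt_islands_bruteforce(is_gt, window=20, min_gt=5):
    """Merged islands over ALL qualifying windows (any <=window run of genes
    holding >= min_gt GT genes), trimmed to the first/last GT gene. Returns
    a set of (start_index, end_index, n_gt) in gene indices."""
    n = len(is_gt)
    windows = []
    for i in range(n):
        for j in range(i, min(n, i + window)):
            if sum(is_gt[i : j + 1]) >= min_gt:
                windows.append((i, j))
    if not windows:
        return set()
    windows.sort()
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    out = set()
    for a, b in merged:
        gts = [i for i in range(a, b + 1) if is_gt[i]]
        out.add((gts[0], gts[-1], len(gts)))
    return out


def rpkg_bruteforce(rows, contig_lens, metagenome_gb, min_identity=99.0, min_aln=50):
    """rows: list of (read_id, contig_id, identity, aln_len). Each read is
    assigned to its best alignment (identity desc, aln_len desc, contig_id
    asc) and counted iff identity >= min_identity and aln_len > min_aln."""
    best = {}
    for read_id, contig_id, identity, aln_len in rows:
        key = (-identity, -aln_len, contig_id)
        if read_id not in best or key < best[read_id][0]:
            best[read_id] = (key, contig_id, identity, aln_len)
    counts = Counter()
    for _, contig_id, identity, aln_len in best.values():
        if identity >= min_identity and aln_len > min_aln:
            counts[contig_id] += 1
    return {
        cid: counts.get(cid, 0) / (clen / 1000.0) / metagenome_gb
        for cid, clen in contig_lens.items()
    }


def spacer_matches_bruteforce(spacer, target, min_identity=97.0):
    """Best full-length Hamming placement per strand; returns a set of
    (strand, position_1based, identity_percent) for accepted placements."""
    out = set()
    L = len(spacer)
    for strand, pat in (("+", spacer), ("-", revcomp(spacer))):
        best = None
        for i in range(len(target) - L + 1):
            mism = sum(1 for a, b in zip(pat, target[i : i + L]) if a != b)
            if best is None or mism < best[0]:
                best = (mism, i)
        if best is not None:
            identity = 100.0 * (L - best[0]) / L
            if identity > min_identity:
                out.add((strand, best[1] + 1, round(identity, 6)))
    return out


def tnf_bruteforce(seq: str):
    """Canonical 4-mer frequency dictionary."""
    counts = Counter()
    for i in range(len(seq) - 3):
        kmer = seq[i : i + 4]
        if any(b not in "ACGT" for b in kmer):
            continue
        counts[min(kmer, revcomp(kmer))] += 1
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}
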