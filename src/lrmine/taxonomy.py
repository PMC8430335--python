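"""Consensus taxonomy for contigs and long reads, 16S fragment filtering,
and rank-level community profiles.

A contig (or read) is classified at a rank if at least a threshold
fraction of ALL its predicted genes — genes without a hit count against
the consensus — share the same best-hit taxon at that rank. The default
threshold is 0.5 with a 5-kb length floor; CRISPR-bearing sequences use
0.7. A tie at the top (two taxa with the same count) is conservatively
unclassified, since the majority rule cannot distinguish them.

Short 16S fragments are kept only when identity >= 80% and alignment
length >= 90 bp; everything else is discarded before profiling.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .io_core import GeneRecord

RANKS = ("domain", "phylum", "class", "order", "family", "genus")

#: consensus threshold applied to CRISPR-bearing sequences
CRISPR_CONSENSUS_THRESHOLD = 0.7


@dataclass
class ConsensusCall:
    parent_id: str
    taxon: str  # label or "unclassified"
    rank: str
    support: float
    n_genes: int


@dataclass
class SsuHit:
    read_id: str
    identity: float  # percent
    aln_len: int  # bp
    taxon_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity <= 100.0):
            raise ValueError("identity must be in [0, 100]")


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def taxon_at_rank(taxon_path: Sequence[str], rank: str) -> str | None:
    """Label of a taxon path at a rank, or None if the path is too shallow."""
    i = _rank_index(rank)
    if len(taxon_path) > i and taxon_path[i]:
        return taxon_path[i]
    return None


def consensus_taxon(
    genes: Sequence[GeneRecord],
    parent_len: int,
    rank: str = "phylum",
    threshold: float = 0.5,
    min_len_bp: int = 5000,
    parent_id: str | None = None,
) -> ConsensusCall:
    """Majority-rule consensus classification of one parent sequence.

    Genes with an empty taxon path (no hit) count in the denominator. The
    parent is unclassified when it is shorter than ``min_len_bp``, has no
    genes, fails the support threshold (``support >= threshold``), or two
    taxa tie for the top count.
    """
    pid = parent_id if parent_id is not None else (genes[0].parent_id if genes else "")
    n = len(genes)
    unclassified = ConsensusCall(
        parent_id=pid, taxon="unclassified", rank=rank, support=0.0, n_genes=n
    )
    if parent_len < min_len_bp or n == 0:
        return unclassified
    labels = [taxon_at_rank(g.taxon_path, rank) for g in genes]
    counts = Counter(l for l in labels if l is not None)
    if not counts:
        return unclassified
    ranked = counts.most_common()
    top_taxon, top = ranked[0]
    if len(ranked) > 1 and ranked[1][1] == top:
        return unclassified  # tie: the rule cannot distinguish the leaders
    support = top / n
    if support < threshold:
        return ConsensusCall(
            parent_id=pid, taxon="unclassified", rank=rank, support=support, n_genes=n
        )
    return ConsensusCall(
        parent_id=pid, taxon=top_taxon, rank=rank, support=support, n_genes=n
    )


def filter_ssu_hits(
    hits: Iterable[SsuHit], min_identity: float = 80.0, min_aln: int = 90
) -> list[SsuHit]:
    """Keep 16S hits with identity >= ``min_identity`` percent AND alignment
    length >= ``min_aln`` bp; both boundaries are inclusive."""
    return [h for h in hits if h.identity >= min_identity and h.aln_len >= min_aln]


def community_profile(
    calls: Iterable[ConsensusCall | SsuHit],
    rank: str = "phylum",
    min_abundance: float = 0.0,
) -> pd.DataFrame:
    """Relative-abundance table (taxon, abundance) over consensus calls or
    filtered 16S hits; includes an "unclassified" row, sums to 1. Rows with
    abundance below ``min_abundance`` are pooled into "other" (a display
    convention for profiles that only show taxa above e.g. 1%)."""
    counts: Counter[str] = Counter()
    total = 0
    for c in calls:
        if isinstance(c, ConsensusCall):
            label = c.taxon
        else:
            label = taxon_at_rank(c.taxon_path, rank) or "unclassified"
        counts[label] += 1
        total += 1
    if total == 0:
        raise ValueError("community_profile: no calls")
    rows = []
    other = 0.0
    for taxon, n in counts.most_common():
        ab = n / total
        if taxon != "unclassified" and ab < min_abundance:
            other += ab
        else:
            rows.append({"taxon": taxon, "abundance": ab})
    if other > 0:
        rows.append({"taxon": "other", "abundance": other})
    df = pd.DataFrame(rows, columns=["taxon", "abundance"])
    return df.sort_values("abundance", ascending=False, ignore_index=True)


def profile_l1_distance(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """L1 distance between two (taxon, abundance) profiles."""
    sa = a.set_index("taxon")["abundance"]
    sb = b.set_index("taxon")["abundance"]
    taxa = sa.index.union(sb.index)
    return float((sa.reindex(taxa, fill_value=0.0) - sb.reindex(taxa, fill_value=0.0)).abs().sum())
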