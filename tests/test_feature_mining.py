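import numpy as np
import pytest

from lrmine.feature_mining import (
    detect_crispr,
    greedy_cluster,
    hierarchical_cluster,
    match_spacers,
    per_gb_rate,
    protein_identity,
    scan_gt_islands,
)
from lrmine.io_core import GeneRecord, SequenceRecord, revcomp
from lrmine.synthetic_community import make_virome, plant_crispr_array

from .conftest import random_dna
from .oracles import gt_islands_bruteforce, spacer_matches_bruteforce


def gene_table(is_gt, parent="c1"):
    return [
        GeneRecord(
            gene_id=f"g{i:03d}", parent_id=parent,
            start=1 + 400 * i, end=350 + 400 * i,
            family="GT" if flag else None,
            evalue=1e-50 if flag else 1e-5,
        )
        for i, flag in enumerate(is_gt)
    ]


class TestGtIslands:
    def test_five_gts_within_twenty_genes(self):
        flags = [i in {1, 4, 8, 13, 17} for i in range(20)]  # 0-based positions
        islands = scan_gt_islands(gene_table(flags), parent_len=8000)
        assert len(islands) == 1
        assert islands[0].n_gt == 5
        assert islands[0].gene_window[0] == "g001"
        assert islands[0].gene_window[-1] == "g017"

    def test_four_gts_no_island(self):
        flags = [i in {1, 4, 8, 13} for i in range(20)]
        assert scan_gt_islands(gene_table(flags), parent_len=8000) == []

    def test_gts_too_spread_no_island(self):
        flags = [i in {0, 1, 2, 22, 23} for i in range(25)]
        assert scan_gt_islands(gene_table(flags), parent_len=12_000) == []

    def test_high_evalue_gts_ignored(self):
        genes = gene_table([True] * 6)
        for g in genes:
            g.evalue = 1e-30  # above the 1e-40 cutoff
        assert scan_gt_islands(genes, parent_len=8000) == []

    def test_short_parent_rejected(self):
        flags = [True] * 6
        assert scan_gt_islands(gene_table(flags), parent_len=4000) == []

    def test_matches_all_windows_oracle(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            flags = list(rng.random(n) < 0.25)
            islands = scan_gt_islands(gene_table(flags), parent_len=100_000)
            got = {
                (int(i.gene_window[0][1:]), int(i.gene_window[-1][1:]), i.n_gt)
                for i in islands
            }
            assert got == gt_islands_bruteforce(flags)


class TestDetectCrispr:
    def test_mutation_free_array_recovered_exactly(self, rng):
        virome = make_virome(7, n=8)
        host = SequenceRecord(id="h", seq=random_dna(rng, 11_000))
        modified, truth = plant_crispr_array(
            host, virome, n_repeats=5, seed=99, max_repeat_mutations=0
        )
        arrays = detect_crispr(modified)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.n_repeats == 5 and a.evidence == 5
        assert (a.start, a.end) == (truth.start, truth.end)
        assert a.spacers == truth.payload["spacers"]
        assert a.repeat_consensus == truth.payload["repeat_consensus"]

    def test_mutated_array_detected_at_locus(self, rng):
        virome = make_virome(7, n=8)
        host = SequenceRecord(id="h", seq=random_dna(rng, 11_000))
        modified, truth = plant_crispr_array(host, virome, n_repeats=5, seed=99)
        arrays = detect_crispr(modified)
        assert len(arrays) == 1
        a = arrays[0]
        assert a.n_repeats == 5
        # boundary may be off by one around a mutated terminal column
        assert abs(a.start - truth.start) <= 2 and abs(a.end - truth.end) <= 2

    def test_two_repeats_not_reported(self, rng):
        repeat = random_dna(rng, 30)
        spacer = random_dna(rng, 30)
        seq = random_dna(rng, 5000) + repeat + spacer + repeat + random_dna(rng, 5000)
        assert detect_crispr(SequenceRecord(id="h", seq=seq)) == []

    def test_random_sequence_rarely_fires(self):
        fired = 0
        for s in range(100):
            rng = np.random.default_rng(5000 + s)
            rec = SequenceRecord(id="x", seq=random_dna(rng, 10_000))
            if detect_crispr(rec):
                fired += 1
        assert fired <= 5

    def test_short_sequence_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_crispr(SequenceRecord(id="x", seq=random_dna(rng, 4000)))


class TestMatchSpacers:
    def test_exact_hit_full_identity(self, rng):
        target_seq = random_dna(rng, 2000)
        spacer = target_seq[500:530]
        m = match_spacers({"s1": spacer}, [SequenceRecord(id="t", seq=target_seq)])
        assert any(x.identity == 100.0 and x.position == 501 for x in m)

    def test_identity_threshold_arithmetic(self, rng):
        target_seq = random_dna(rng, 1000)
        s30 = target_seq[100:130]
        s40 = target_seq[300:340]
        mut30 = "ACGT".replace(s30[10], "")[0] .join([s30[:10], s30[11:]])
        mut40 = "ACGT".replace(s40[10], "")[0].join([s40[:10], s40[11:]])
        tgt = [SequenceRecord(id="t", seq=target_seq)]
        assert match_spacers({"a": mut30}, tgt) == []  # 29/30 = 96.7% < 97
        hits = match_spacers({"b": mut40}, tgt)  # 39/40 = 97.5% > 97
        assert hits and hits[0].identity == pytest.approx(97.5)

    def test_edge_truncated_hit_rejected(self, rng):
        spacer = random_dna(rng, 30)
        target = SequenceRecord(id="t", seq=random_dna(rng, 200) + spacer[:29])
        assert match_spacers({"s": spacer}, [target]) == []

    def test_reverse_strand_found(self, rng):
        target_seq = random_dna(rng, 500)
        spacer = revcomp(target_seq[200:232])
        m = match_spacers({"s": spacer}, [SequenceRecord(id="t", seq=target_seq)])
        assert any(x.strand == "-" and x.identity == 100.0 for x in m)

    def test_matches_sliding_oracle(self, rng):
        for _ in range(1000):
            target_seq = random_dna(rng, 250)
            L = int(rng.integers(20, 41))
            if rng.random() < 0.5:
                off = int(rng.integers(0, 250 - L))
                spacer = list(target_seq[off : off + L])
                for i in rng.choice(L, size=int(rng.integers(0, 2)), replace=False):
                    spacer[i] = "ACGT".replace(spacer[i], "")[int(rng.integers(3))]
                spacer = "".join(spacer)
            else:
                spacer = random_dna(rng, L)
            got = {
                (m.strand, m.position, round(m.identity, 6))
                for m in match_spacers({"s": spacer}, [SequenceRecord(id="t", seq=target_seq)])
            }
            assert got == spacer_matches_bruteforce(spacer, target_seq)


AA = list("ACDEFGHIKLMNPQRSTVWY")


def _protein(rng, n):
    return "".join(rng.choice(AA, size=n))


class TestHierarchicalCluster:
    def test_identical_sequences_one_cluster_at_every_level(self, rng):
        p = _protein(rng, 250)
        result = hierarchical_cluster({"a": p, "b": p, "c": p})
        for level, clusters in result.items():
            assert len(clusters) == 1, level

    def test_85pct_pair_splits_at_90_merges_at_80(self, rng):
        a = _protein(rng, 240)
        b = list(a)
        idx = rng.choice(240, size=36, replace=False)  # 85% identity
        for i in idx:
            b[i] = rng.choice([x for x in AA if x != b[i]])
        b = "".join(b)
        # equal-cost alignments with a compensating gap pair can add a
        # chance match, so identity may exceed 85.0 marginally
        assert 84.5 <= protein_identity(a, b) <= 86.0
        result = hierarchical_cluster({"a": a, "b": b})
        assert len(result[90]) == 2
        assert len(result[80]) == 1

    def test_cluster_count_non_increasing(self, rng):
        pool = {f"p{i}": _protein(rng, 210 + int(rng.integers(0, 60))) for i in range(12)}
        result = hierarchical_cluster(pool)
        counts = [len(result[l]) for l in sorted(result, reverse=True)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_length_filter_strict(self, rng):
        pool = {"short": _protein(rng, 200), "long": _protein(rng, 201)}
        result = hierarchical_cluster(pool)
        assert all(
            c.member_ids == ["long"] for c in result[100]
        )

    def test_all_filtered_raises(self, rng):
        with pytest.raises(ValueError):
            hierarchical_cluster({"s": _protein(rng, 50)})


class TestPerGbRate:
    def test_values(self):
        assert per_gb_rate(50, int(0.5e9)) == pytest.approx(100.0)
        assert per_gb_rate(0, int(1e9)) == 0.0
        assert per_gb_rate(10, int(2e9)) == per_gb_rate(20, int(4e9))

    def test_zero_size_raises(self):
        with pytest.raises(ValueError):
            per_gb_rate(1, 0)
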