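import math

import numpy as np
import pandas as pd
import pytest

from lrmine.binning import (
    Bin,
    ContigFeatures,
    ani,
    bin_contigs,
    bin_quality,
    canonical_tetramers,
    rpkg,
    rpkg_table,
    tetranucleotide_freqs,
)
from lrmine.io_core import SequenceRecord, gc_content, revcomp

from .conftest import random_dna
from .oracles import rpkg_bruteforce, tnf_bruteforce


class TestTnf:
    def test_136_canonical_classes(self):
        assert len(canonical_tetramers()) == 136

    def test_poly_a_mass_on_single_class(self):
        v = tetranucleotide_freqs("A" * 5000)
        classes = canonical_tetramers()
        assert v[classes.index("AAAA")] == pytest.approx(1.0)

    def test_revcomp_invariance(self, rng):
        seq = random_dna(rng, 6000)
        assert np.allclose(tetranucleotide_freqs(seq), tetranucleotide_freqs(revcomp(seq)))

    def test_matches_dictionary_oracle(self, rng):
        seq = random_dna(rng, 5000)
        v = tetranucleotide_freqs(seq)
        classes = canonical_tetramers()
        oracle = tnf_bruteforce(seq)
        for kmer, freq in oracle.items():
            assert v[classes.index(kmer)] == pytest.approx(freq)
        assert v.sum() == pytest.approx(1.0)

    def test_n_windows_skipped(self):
        v1 = tetranucleotide_freqs("ACGT" * 1500)
        v2 = tetranucleotide_freqs("ACGT" * 750 + "N" * 8 + "ACGT" * 750, min_len=5000)
        assert np.allclose(v1, v2, atol=1e-3)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            tetranucleotide_freqs("ACGT" * 100)


def _aln(rows):
    return pd.DataFrame(rows, columns=["read_id", "contig_id", "identity", "aln_len"])


class TestRpkg:
    def test_stated_arithmetic(self):
        rows = [(f"r{i}", "c1", 99.5, 80) for i in range(400)]
        assert rpkg(_aln(rows), contig_len=10_000, metagenome_gb=20.0) == pytest.approx(2.0)

    def test_boundaries_strict_and_inclusive(self):
        rows = [("r1", "c1", 98.9, 500), ("r2", "c1", 99.0, 50), ("r3", "c1", 99.0, 51)]
        val = rpkg(_aln(rows), contig_len=1000, metagenome_gb=1.0)
        assert val == pytest.approx(1 / 1 / 1)  # only r3 counts

    def test_zero_qualifying(self):
        rows = [("r1", "c1", 90.0, 500)]
        assert rpkg(_aln(rows), contig_len=1000, metagenome_gb=1.0) == 0.0

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            rpkg(_aln([("r", "c", 99.5, 100)]), contig_len=0, metagenome_gb=1.0)
        with pytest.raises(ValueError):
            rpkg(_aln([("r", "c", 99.5, 100)]), contig_len=10, metagenome_gb=0.0)

    def test_matches_bruteforce_on_random_tables(self, rng):
        for _ in range(1000):
            n = int(rng.integers(1, 25))
            rows = [
                (
                    f"r{int(rng.integers(0, 10))}",
                    f"c{int(rng.integers(0, 4))}",
                    float(np.round(rng.uniform(95, 100), 2)),
                    int(rng.integers(20, 200)),
                )
                for _ in range(n)
            ]
            lens = {f"c{i}": int(rng.integers(1000, 50_000)) for i in range(4)}
            gb = float(rng.uniform(0.5, 30))
            got = rpkg_table(_aln(rows), lens, gb)
            want = rpkg_bruteforce(rows, lens, gb)
            for cid in lens:
                assert got[cid] == pytest.approx(want[cid])

    def test_linearity(self, rng):
        rows = [(f"r{i}", "c1", 99.9, 100) for i in range(50)]
        base = rpkg(_aln(rows), contig_len=2000, metagenome_gb=4.0)
        doubled = rpkg(_aln(rows + [(f"s{i}", "c1", 99.9, 100) for i in range(50)]),
                       contig_len=2000, metagenome_gb=4.0)
        assert doubled == pytest.approx(2 * base)
        assert rpkg(_aln(rows), contig_len=4000, metagenome_gb=4.0) == pytest.approx(base / 2)
        assert rpkg(_aln(rows), contig_len=2000, metagenome_gb=8.0) == pytest.approx(base / 2)


class TestBinQuality:
    def _bin(self):
        return Bin(bin_id="b1", contig_ids={"c1"})

    def test_formula_arithmetic(self):
        markers = {"c1": [f"marker_{i:03d}" for i in range(28)]}
        universe = {f"marker_{i:03d}" for i in range(40)}
        b = bin_quality(self._bin(), markers, universe)
        assert b.completeness == pytest.approx(70.0)
        assert b.contamination == pytest.approx(0.0)
        assert b.quality == "medium"

    def test_medium_boundary_is_strict(self):
        universe = {f"m{i}" for i in range(40)}
        dup = {"c1": [f"m{i}" for i in range(40)] + ["m0", "m1"]}
        b = bin_quality(self._bin(), dup, universe)
        assert b.completeness == 100.0 and b.contamination == pytest.approx(5.0)
        assert b.quality == "low"  # contamination < 5 is strict
        half = {"c1": [f"m{i}" for i in range(20)]}
        b2 = bin_quality(self._bin(), half, universe)
        assert b2.completeness == 50.0 and b2.quality == "low"  # completeness > 50 strict

    def test_empty_bin_zero_completeness(self):
        b = bin_quality(Bin(bin_id="b", contig_ids=set()), {}, {"m1", "m2"})
        assert b.completeness == 0.0

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError):
            bin_quality(self._bin(), {}, set())


def _features_from_genomes(rng, gcs, coverages, n_per=6, kb=6):
    feats, labels = [], []
    for gi, (gc, cov) in enumerate(zip(gcs, coverages)):
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        for ci in range(n_per):
            seq = "".join(np.array(list("ACGT"))[rng.choice(4, kb * 1000, p=p)])
            feats.append(
                ContigFeatures(
                    contig_id=f"g{gi}_c{ci}",
                    tnf=tetranucleotide_freqs(seq),
                    gc=gc_content(seq),
                    rpkg={"s0": cov * float(rng.lognormal(0, 0.1))},
                )
            )
            labels.append(gi)
    return feats, labels


class TestBinContigs:
    def test_single_genome_single_bin(self, rng):
        feats, _ = _features_from_genomes(rng, [0.5], [20.0], n_per=8)
        bins = bin_contigs(feats)
        assert len(bins) == 1
        assert bins[0].contig_ids == {f.contig_id for f in feats}

    def test_three_genomes_separate(self, rng):
        feats, labels = _features_from_genomes(rng, [0.3, 0.5, 0.7], [5.0, 20.0, 80.0])
        bins = bin_contigs(feats)
        assert len(bins) == 3
        for b in bins:
            members = {l for f, l in zip(feats, labels) if f.contig_id in b.contig_ids}
            assert len(members) == 1

    def test_duplicating_contigs_keeps_bin_count(self, rng):
        feats, _ = _features_from_genomes(rng, [0.3, 0.6], [5.0, 40.0])
        bins = bin_contigs(feats)
        dup = feats + [
            ContigFeatures(f.contig_id + "_d", f.tnf, f.gc, dict(f.rpkg))
            for f in feats
        ]
        assert len(bin_contigs(dup)) == len(bins)

    def test_taxon_stratification_splits_first(self, rng):
        feats, _ = _features_from_genomes(rng, [0.45, 0.55], [10.0, 10.0])
        for f, label in zip(feats, ["PhylA"] * 6 + ["PhylB"] * 6):
            f.taxon = label
        bins = bin_contigs(feats)
        assert len(bins) == 2
        for b in bins:
            strata = {f.taxon for f in feats if f.contig_id in b.contig_ids}
            assert len(strata) == 1

    def test_order_invariance(self, rng):
        feats, _ = _features_from_genomes(rng, [0.3, 0.7], [5.0, 50.0])
        a = bin_contigs(feats)
        b = bin_contigs(feats[::-1])
        sets_a = sorted(tuple(sorted(x.contig_ids)) for x in a)
        sets_b = sorted(tuple(sorted(x.contig_ids)) for x in b)
        assert sets_a == sets_b

    def test_too_few_contigs_raises(self, rng):
        feats, _ = _features_from_genomes(rng, [0.5], [10.0], n_per=1)
        with pytest.raises(ValueError):
            bin_contigs(feats[:1])


class TestAni:
    def test_self_is_exactly_100(self, rng):
        ref = SequenceRecord(id="r", seq=random_dna(rng, 30_000))
        res = ani(ref, ref)
        assert res.ani == 100.0
        assert res.aligned_fraction == 1.0

    def test_self_unchanged_by_fragmentation(self, rng):
        seq = random_dna(rng, 30_000)
        ref = SequenceRecord(id="r", seq=seq)
        parts = [
            SequenceRecord(id=f"p{i}", seq=seq[i * 7000 : (i + 1) * 7000])
            for i in range(4)
        ]
        assert ani(parts, ref).ani == 100.0

    def test_unrelated_sequences_undefined(self, rng):
        a = SequenceRecord(id="a", seq=random_dna(rng, 20_000))
        b = SequenceRecord(id="b", seq=random_dna(rng, 20_000))
        res = ani(a, b)
        assert not res.defined and math.isnan(res.ani)

    def test_no_full_fragment_raises(self, rng):
        with pytest.raises(ValueError):
            ani(SequenceRecord(id="a", seq=random_dna(rng, 500)),
                SequenceRecord(id="b", seq=random_dna(rng, 5000)))
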