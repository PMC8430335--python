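import numpy as np
import pytest

from lrmine.io_core import gc_content, revcomp
from lrmine.orf_stats import STOP_CODONS, START_CODONS
from lrmine.synthetic_community import (
    STOP_CASSETTE_CODONS,
    STOP_WALL,
    CommunityTruth,
    ErrorModel,
    GenomeSpec,
    build_community,
    generate_genome,
    make_virome,
    plant_crispr_array,
    simulate_long_reads,
    simulate_short_reads,
)

RSTOPS = {"TTA", "CTA", "TCA"}  # forward-strand images of reverse-frame stops


class TestStopKernelConstants:
    def test_cassette_kills_all_noncoding_frames(self):
        s = "".join(STOP_CASSETTE_CODONS)
        assert all(c not in STOP_CODONS for c in STOP_CASSETTE_CODONS)
        fwd = {i % 3 for i in range(len(s) - 2) if s[i : i + 3] in STOP_CODONS}
        rev = {i % 3 for i in range(len(s) - 2) if s[i : i + 3] in RSTOPS}
        assert {1, 2} <= fwd and rev == {0, 1, 2}

    def test_wall_kills_all_six_frames(self):
        fwd = {i % 3 for i in range(len(STOP_WALL) - 2) if STOP_WALL[i : i + 3] in STOP_CODONS}
        rev = {i % 3 for i in range(len(STOP_WALL) - 2) if STOP_WALL[i : i + 3] in RSTOPS}
        assert fwd == {0, 1, 2} and rev == {0, 1, 2}
        assert len(STOP_WALL) % 3 == 0


class TestGenerateGenome:
    def test_gc_target_hit(self):
        for gc in (0.30, 0.50, 0.70):
            rec, _, _ = generate_genome(GenomeSpec(id="g", length=100_000, gc_target=gc), seed=5)
            assert abs(gc_content(rec) - gc) <= 0.02

    def test_marker_count_and_uniqueness(self):
        spec = GenomeSpec(id="g", length=120_000, gc_target=0.5, n_single_copy_markers=40)
        _, genes, _ = generate_genome(spec, seed=2)
        markers = [g for g in genes if g.family and g.family.startswith("marker_")]
        assert len(markers) == 40
        assert len({g.family for g in markers}) == 40
        assert all(g.end - g.start + 1 == 600 for g in markers)

    def test_determinism(self):
        spec = GenomeSpec(id="g", length=60_000, gc_target=0.45)
        a, ga, _ = generate_genome(spec, seed=9)
        b, gb, _ = generate_genome(spec, seed=9)
        assert a.seq == b.seq and ga == gb

    def test_genes_are_well_formed(self):
        spec = GenomeSpec(id="g", length=60_000, gc_target=0.5)
        rec, genes, _ = generate_genome(spec, seed=3)
        for g in genes[:50]:
            sub = rec.seq[g.start - 1 : g.end]
            assert sub[:3] in START_CODONS
            assert sub[-3:] in STOP_CODONS
            assert len(sub) % 3 == 0

    def test_crispr_without_virome_fails(self):
        spec = GenomeSpec(
            id="g", length=60_000, gc_target=0.5, planted_features=["crispr_array"]
        )
        with pytest.raises(ValueError, match="virome"):
            generate_genome(spec, seed=1)


class TestPlantCrisprArray:
    def test_array_arithmetic_and_virome_provenance(self, rng):
        virome = make_virome(3, n=6)
        host, _, _ = generate_genome(GenomeSpec(id="h", length=60_000, gc_target=0.5), seed=4)
        modified, feat = plant_crispr_array(host, virome, n_repeats=5, seed=8)
        pl = feat.payload
        assert len(pl["repeats"]) == 5 and len(pl["spacers"]) == 4
        assert len(modified) == len(host) + (feat.end - feat.start + 1)
        # every spacer is a verbatim copy of a recorded virome window
        vmap = {v.id: v.seq for v in virome}
        for spacer, src in zip(pl["spacers"], pl["spacer_sources"]):
            assert vmap[src["virome_id"]][src["offset"] : src["offset"] + src["length"]] == spacer
        # repeats near-identical to the consensus
        rlen = len(pl["repeat_consensus"])
        for r in pl["repeats"]:
            mism = sum(a != b for a, b in zip(r, pl["repeat_consensus"]))
            assert mism <= 1

    def test_virome_too_short_raises(self, rng):
        virome = [make_virome(1, n=1, length_range=(30, 35))[0]]
        host, _, _ = generate_genome(GenomeSpec(id="h", length=60_000, gc_target=0.5), seed=4)
        with pytest.raises(ValueError):
            plant_crispr_array(host, virome, spacer_len_range=(40, 60))


class TestLongReads:
    def test_error_free_reads_are_exact_substrings(self, small_community):
        truth = small_community
        model = ErrorModel(per_pass_table={15: 0.0})
        reads = simulate_long_reads(truth, model, n_reads=40, passes=15, seed=1,
                                    id_prefix="exact")
        for r in reads:
            p = truth.read_provenance[r.id]
            tmpl = truth.records[p.genome_id].seq[p.start - 1 : p.end]
            if p.strand == "-":
                tmpl = revcomp(tmpl)
            assert r.seq == tmpl
            assert p.n_errors == 0

    def test_mean_length_within_2pct(self):
        specs = [GenomeSpec(id="g", length=300_000, gc_target=0.5)]
        truth = build_community(specs, seed=3)
        model = ErrorModel(per_pass_table={15: 0.0})
        reads = simulate_long_reads(truth, model, n_reads=10_000, passes=15,
                                    mean_bp=5000.0, seed=5)
        mean = np.mean([len(r) for r in reads])
        assert abs(mean - 5000) / 5000 < 0.02

    def test_per_pass_error_rates_decrease(self, small_community):
        truth = small_community
        model = ErrorModel()
        realized = []
        for i, passes in enumerate((5, 10, 15)):
            t = CommunityTruth(
                genomes=truth.genomes, records=truth.records, genes=truth.genes,
                abundances=truth.abundances, features=truth.features, virome=truth.virome,
            )
            reads = simulate_long_reads(t, model, n_reads=300, passes=passes,
                                        seed=60 + i)
            total_bp = sum(p.end - p.start + 1 for p in t.read_provenance.values())
            errs = sum(p.n_errors for p in t.read_provenance.values())
            realized.append(errs / total_bp)
        assert realized[0] > realized[1] > realized[2]
        assert realized[0] == pytest.approx(0.01, rel=0.15)

    def test_abundance_recovery_within_3_sigma(self):
        specs = [GenomeSpec(id=f"g{i}", length=100_000, gc_target=0.5) for i in range(3)]
        truth = build_community(specs, seed=8)
        model = ErrorModel(per_pass_table={15: 0.0})
        n = 3000
        reads = simulate_long_reads(truth, model, n_reads=n, passes=15, seed=9)
        glens = {s.id: len(truth.records[s.id]) for s in specs}
        w = np.array([truth.abundances[s.id] * glens[s.id] for s in specs])
        w = w / w.sum()
        counts = {s.id: 0 for s in specs}
        for r in reads:
            counts[truth.read_provenance[r.id].genome_id] += 1
        for i, s in enumerate(specs):
            sigma = np.sqrt(n * w[i] * (1 - w[i]))
            assert abs(counts[s.id] - n * w[i]) <= 3 * sigma

    def test_unknown_pass_count_rejected(self, small_community):
        with pytest.raises(KeyError):
            simulate_long_reads(small_community, ErrorModel(), n_reads=1, passes=7, seed=0)


class TestShortReads:
    def test_fixed_length_and_exactness(self, small_community):
        truth = small_community
        r1, r2 = simulate_short_reads(truth, error_rate=0.0, n_pairs=300, seed=4)
        assert all(len(r) == 100 for r in r1 + r2)
        for r in r1[:50]:
            p = truth.read_provenance[r.id]
            assert truth.records[p.genome_id].seq[p.start - 1 : p.end] == r.seq
        for r in r2[:50]:
            p = truth.read_provenance[r.id]
            assert revcomp(truth.records[p.genome_id].seq[p.start - 1 : p.end]) == r.seq

    def test_observed_mismatch_rate_matches_binomial(self):
        specs = [GenomeSpec(id="g", length=150_000, gc_target=0.5)]
        truth = build_community(specs, seed=6)
        n_pairs = 6000  # >= 1.2 Mb sampled
        r1, r2 = simulate_short_reads(truth, error_rate=0.01, n_pairs=n_pairs, seed=7)
        mism = 0
        total = 0
        for r in r1 + r2:
            p = truth.read_provenance[r.id]
            tmpl = truth.records[p.genome_id].seq[p.start - 1 : p.end]
            if p.strand == "-":
                tmpl = revcomp(tmpl)
            mism += sum(a != b for a, b in zip(r.seq, tmpl))
            total += len(r.seq)
        assert 0.008 <= mism / total <= 0.012


class TestErrorModel:
    def test_rate_must_not_increase_with_passes(self):
        with pytest.raises(ValueError):
            ErrorModel(per_pass_table={5: 0.001, 10: 0.01})

    def test_rate_range(self):
        with pytest.raises(ValueError):
            ErrorModel(per_pass_table={5: 0.5})
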