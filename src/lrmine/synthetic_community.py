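"""Ground-truthed mock community generator.

Emulates the statistical structure a long-read vs short-read marine
metagenome comparison rests on: a handful of genomes with lognormal
abundances, long reads with lognormal lengths and pass-count-dependent
error rates (5/10/15 passes -> 99/99.9/99.95% accuracy), 100-bp paired
short reads, and planted features (single-copy markers, GT gene clusters,
CRISPR arrays whose spacers are copied from an emitted virome, rhodopsin
genes, rRNA-ITS operons). Every emitted read carries provenance, so each
downstream statistic can be scored against truth.

Genome construction
-------------------
Genomes are tiled with non-overlapping forward-strand genes (geometric
amino-acid length law, mean ``mean_protein_aa``) separated by 50-bp
intergenic gaps. Two fixed "stop kernel" constants keep six-frame ORF
calling clean: inside genes, every 24th..24th+5 codon is a sense-codon
cassette that places stop codons in all five non-coding frames, and every
intergenic gap carries a 15-bp wall with stops in all six frames. The
result is that error-free six-frame calling recovers essentially the
planted genes and nothing else, so the mean called protein length of a
read set is a known quantity. Codon usage is GC-biased to hit
``gc_target`` (+/- 0.02) with a per-genome Dirichlet jitter that gives
each genome a distinct tetranucleotide signature even at equal GC.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .io_core import GeneRecord, SequenceRecord, revcomp, write_fasta, write_fastq
from .orf_stats import START_CODONS, STOP_CODONS

logger = logging.getLogger("lrmine.synthetic")

#: in-frame sense-codon cassette placing a stop in every non-coding frame
#: (forward offsets 1 and 2, and TTA/CTA/TCA — the reverse complements of
#: the stops — at all three offsets); found by exhaustive search and
#: re-verified by a unit test.
STOP_CASSETTE_CODONS = ("CTT", "AGA", "CGT", "CAT", "TTA", "GAA")
#: intergenic wall with a stop in all six frames at any placement.
STOP_WALL = "TAATTAATTAATTAA"

_CASSETTE_PERIOD = 24  # codons between cassette starts inside a gene
_GAP_LEN = 50

_BASES = np.array(list("ACGT"))
_SENSE = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_SENSE_ARR = np.array(_SENSE)
_SENSE_GC = np.array([sum(b in "GC" for b in c) for c in _SENSE], dtype=float)


@dataclass
class ErrorModel:
    """Per-pass total error rates and the substitution:insertion:deletion mix.

    The default table maps the conventional CCS pass counts to base-call
    accuracies 99 / 99.9 / 99.95%."""

    per_pass_table: Mapping[int, float] = field(
        default_factory=lambda: {5: 0.01, 10: 0.001, 15: 0.0005}
    )
    sub_ins_del: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        rates = list(self.per_pass_table.values())
        # 0 is allowed as the error-free limit used by calibration runs
        if any(not (0.0 <= r < 0.3) for r in rates):
            raise ValueError("error rates must lie in [0, 0.3)")
        by_pass = sorted(self.per_pass_table.items())
        if any(b[1] > a[1] for a, b in zip(by_pass, by_pass[1:])):
            raise ValueError("error rate must be non-increasing in passes")


@dataclass
class GenomeSpec:
    id: str
    length: int
    gc_target: float
    markov_order: int = 1
    n_single_copy_markers: int = 0
    planted_features: list = field(default_factory=list)
    taxon_path: tuple[str, ...] = ()
    mean_protein_aa: float = 250.0

    def __post_init__(self) -> None:
        if not (0.2 <= self.gc_target <= 0.8):
            raise ValueError("gc_target must be in [0.2, 0.8]")
        if self.length < 1000:
            raise ValueError("genome length too short")


@dataclass
class PlantedFeature:
    kind: str  # rrna_operon | gt_cluster | crispr_array | rhodopsin_gene
    genome_id: str
    start: int  # 1-based closed
    end: int
    payload: dict = field(default_factory=dict)


@dataclass
class Provenance:
    read_id: str
    genome_id: str
    start: int
    end: int
    strand: str
    passes: int
    n_errors: int


@dataclass
class CommunityTruth:
    genomes: list[GenomeSpec]
    records: dict[str, SequenceRecord]
    genes: dict[str, list[GeneRecord]]
    abundances: dict[str, float]
    features: list[PlantedFeature]
    virome: list[SequenceRecord]
    read_provenance: dict[str, Provenance] = field(default_factory=dict)

    def features_of(self, kind: str) -> list[PlantedFeature]:
        return [f for f in self.features if f.kind == kind]


# ---------------------------------------------------------------------------
# codon sampling


def _codon_weights(g: float, jitter: np.ndarray | None) -> np.ndarray:
    p = np.where(
        np.isin(np.array([list(c) for c in _SENSE]), list("GC")), g / 2.0, (1.0 - g) / 2.0
    ).prod(axis=1)
    if jitter is not None:
        p = p * jitter
    return p / p.sum()


def _expected_codon_gc(g: float, jitter: np.ndarray | None) -> float:
    w = _codon_weights(g, jitter)
    return float((w * _SENSE_GC).sum() / 3.0)


def _solve_gc_bias(
    target_gc: float,
    fixed_gc_bp: float,
    fixed_bp: int,
    n_random_codons: int,
    n_gap_bases: int,
    total_bp: int,
    jitter: np.ndarray | None,
) -> float:
    """Base-level GC probability g such that the expected genome GC hits the
    target, given the fixed (kernel/wall/start/stop) base content."""

    def f(g: float) -> float:
        exp_gc = (
            fixed_gc_bp
            + 3.0 * n_random_codons * _expected_codon_gc(g, jitter)
            + n_gap_bases * g
        )
        return exp_gc / total_bp - target_gc

    lo, hi = 0.02, 0.98
    if f(lo) > 0 or f(hi) < 0:
        raise ValueError(
            f"gc_target {target_gc} unreachable given the fixed kernel content"
        )
    return float(brentq(f, lo, hi, xtol=1e-6))


def _sample_codons(rng: np.random.Generator, n: int, weights: np.ndarray) -> np.ndarray:
    return rng.choice(len(_SENSE), size=n, p=weights)


def _gene_codons(
    rng: np.random.Generator, aa_len: int, weights: np.ndarray
) -> list[str]:
    """Codon list for one gene: ATG, GC-biased sense codons with the stop
    cassette every _CASSETTE_PERIOD codons, then a stop codon."""
    idx = _sample_codons(rng, aa_len, weights)
    codons = list(_SENSE_ARR[idx])
    codons[0] = "ATG"
    for i in range(_CASSETTE_PERIOD - len(STOP_CASSETTE_CODONS), aa_len, _CASSETTE_PERIOD):
        for j, cc in enumerate(STOP_CASSETTE_CODONS):
            if i + j < aa_len and i + j > 0:
                codons[i + j] = cc
    codons.append(STOP_CODONS[rng.integers(3)])
    return codons


def _gap_seq(rng: np.random.Generator, g: float, length: int = _GAP_LEN) -> str:
    """Intergenic gap flanked by the all-frame stop wall on both ends, with
    random bases in the middle. Walls abut the neighbouring genes directly
    so no stop-free frame can run from a gene into a gap (and in the gene's
    own frame the wall reads ...TAA immediately before the ATG, pinning the
    called ORF start to the planted start)."""
    n_rand = max(0, length - 2 * len(STOP_WALL))
    p = np.array([(1 - g) / 2, g / 2, g / 2, (1 - g) / 2])
    bases = rng.choice(4, size=n_rand, p=p)
    return STOP_WALL + "".join(_BASES[bases]) + STOP_WALL


# ---------------------------------------------------------------------------
# CRISPR array construction


def build_crispr_array(
    rng: np.random.Generator,
    virome: Sequence[SequenceRecord],
    n_repeats: int = 5,
    repeat_len: int = 30,
    spacer_len_range: tuple[int, int] = (25, 40),
    gc: float = 0.4,
    max_repeat_mutations: int = 1,
) -> tuple[str, str, list[str], list[str], list[dict]]:
    """Assemble a CRISPR array: near-identical repeats interleaved with
    spacers copied verbatim from the virome.

    Returns (array_seq, repeat_consensus, repeats, spacers, spacer_sources).
    """
    if n_repeats < 3:
        raise ValueError("n_repeats must be >= 3")
    lo, hi = spacer_len_range
    usable = [v for v in virome if len(v) >= hi]
    if not usable:
        raise ValueError("virome sequences shorter than the requested spacer length")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    consensus = "".join(_BASES[rng.choice(4, size=repeat_len, p=p)])
    repeats = []
    for _ in range(n_repeats):
        r = list(consensus)
        if max_repeat_mutations > 0 and rng.random() < 0.5:
            i = int(rng.integers(repeat_len))
            r[i] = str(rng.choice([b for b in "ACGT" if b != r[i]]))
        repeats.append("".join(r))
    spacers, sources = [], []
    for _ in range(n_repeats - 1):
        slen = int(rng.integers(lo, hi + 1))
        v = usable[int(rng.integers(len(usable)))]
        off = int(rng.integers(0, len(v) - slen + 1))
        spacers.append(v.seq[off : off + slen])
        sources.append({"virome_id": v.id, "offset": off, "length": slen})
    parts = []
    for i, r in enumerate(repeats):
        parts.append(r)
        if i < len(spacers):
            parts.append(spacers[i])
    return "".join(parts), consensus, repeats, spacers, sources


def plant_crispr_array(
    genome: SequenceRecord,
    virome: Sequence[SequenceRecord],
    n_repeats: int = 5,
    repeat_len: int = 30,
    spacer_len_range: tuple[int, int] = (25, 40),
    position: int | None = None,
    seed: int | np.random.Generator = 0,
    max_repeat_mutations: int = 1,
) -> tuple[SequenceRecord, PlantedFeature]:
    """Insert a CRISPR array into an existing genome sequence and return the
    modified record plus the truth locus (1-based closed coordinates)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    array, consensus, repeats, spacers, sources = build_crispr_array(
        rng, virome, n_repeats=n_repeats, repeat_len=repeat_len,
        spacer_len_range=spacer_len_range, max_repeat_mutations=max_repeat_mutations,
    )
    pos = int(rng.integers(0, len(genome) + 1)) if position is None else position
    seq = genome.seq[:pos] + array + genome.seq[pos:]
    feature = PlantedFeature(
        kind="crispr_array",
        genome_id=genome.id,
        start=pos + 1,
        end=pos + len(array),
        payload={
            "repeat_consensus": consensus,
            "repeats": repeats,
            "spacers": spacers,
            "spacer_sources": sources,
        },
    )
    return SequenceRecord(id=genome.id, seq=seq, source=genome.source), feature


# ---------------------------------------------------------------------------
# genome generation


def _feature_params(entry) -> tuple[str, dict]:
    if isinstance(entry, str):
        return entry, {}
    kind, params = entry
    return kind, dict(params or {})


def generate_genome(
    spec: GenomeSpec,
    seed: int,
    virome: Sequence[SequenceRecord] = (),
    rhodopsin_template: np.ndarray | None = None,
    rrna_templates: tuple[str, str] | None = None,
) -> tuple[SequenceRecord, list[GeneRecord], list[PlantedFeature]]:
    """Generate one genome with its gene annotation and planted-feature truth.

    Deterministic given (spec, seed). Raises if a planted feature cannot be
    built (e.g. a CRISPR array requested without a virome).
    """
    rng = np.random.default_rng(seed)
    jitter = None
    if spec.markov_order > 0:
        jitter = rng.dirichlet(np.full(len(_SENSE), 8.0)) * len(_SENSE)

    # --- phase A: draw the structural layout (segment kinds and lengths)
    mean_aa = spec.mean_protein_aa
    segments: list[dict] = []  # {"kind": gap|gene, "aa": int, ...}
    total = 0
    while total < spec.length:
        segments.append({"kind": "gap"})
        total += _GAP_LEN
        aa = int(rng.geometric(1.0 / mean_aa))
        segments.append({"kind": "gene", "aa": aa, "family": None, "evalue": None})
        total += 3 * (aa + 1)

    gene_slots = [i for i, s in enumerate(segments) if s["kind"] == "gene"]

    # single-copy markers: unique 600-bp tagged genes, evenly spread
    if spec.n_single_copy_markers > 0:
        if spec.n_single_copy_markers > len(gene_slots):
            raise ValueError("not enough gene slots for the requested markers")
        marker_slots = np.linspace(
            0, len(gene_slots) - 1, spec.n_single_copy_markers
        ).astype(int)
        for m, si in enumerate(marker_slots):
            seg = segments[gene_slots[si]]
            seg["aa"] = 199  # 200 codons with stop = 600 bp
            seg["family"] = f"marker_{m:03d}"
            seg["evalue"] = 1e-60

    # planted features become extra segments appended at even spacings
    feature_segments: list[dict] = []
    for entry in spec.planted_features:
        kind, params = _feature_params(entry)
        if kind == "gt_cluster":
            n_gt = int(params.get("n_genes", 6))
            feature_segments.append({"kind": "gt_cluster", "n_genes": n_gt})
        elif kind == "crispr_array":
            if not virome:
                raise ValueError(
                    f"{spec.id}: crispr_array requested but no virome supplied"
                )
            feature_segments.append({"kind": "crispr", "params": params})
        elif kind == "rhodopsin_gene":
            feature_segments.append({"kind": "rhodopsin"})
        elif kind == "rrna_operon":
            feature_segments.append({"kind": "rrna"})
        else:
            raise ValueError(f"unknown planted feature kind {kind!r}")
    if feature_segments:
        # insert each feature (preceded by a gap) at an even position
        positions = np.linspace(1, len(segments) - 1, len(feature_segments) + 2)[
            1:-1
        ].astype(int)
        for fseg, pos in zip(feature_segments, sorted(positions, reverse=True)):
            segments.insert(pos, fseg)
            segments.insert(pos, {"kind": "gap"})

    # --- phase B: count fixed vs random base content and solve the GC bias
    fixed_gc = 0.0
    fixed_bp = 0
    n_random_codons = 0
    n_gap_bases = 0
    wall_gc = sum(b in "GC" for b in STOP_WALL)
    cassette_gc = sum(b in "GC" for c in STOP_CASSETTE_CODONS for b in c)

    def _gene_counts(aa: int) -> tuple[int, float, int]:
        """(fixed_bp, fixed_gc, random_codons) for a gene of aa codons."""
        n_cassette = 0
        for i in range(_CASSETTE_PERIOD - len(STOP_CASSETTE_CODONS), aa, _CASSETTE_PERIOD):
            n_cassette += sum(1 for j in range(len(STOP_CASSETTE_CODONS)) if 0 < i + j < aa)
        fixed = 3 * (n_cassette + 2)  # cassette codons + ATG + stop
        fgc = cassette_gc * (n_cassette / len(STOP_CASSETTE_CODONS)) + 1.0 + 2.0 / 3.0
        return fixed, fgc, aa - 1 - n_cassette

    for seg in segments:
        if seg["kind"] == "gap":
            fixed_bp += 2 * len(STOP_WALL)
            fixed_gc += 2 * wall_gc
            n_gap_bases += _GAP_LEN - 2 * len(STOP_WALL)
        elif seg["kind"] == "gene":
            fb, fg, nr = _gene_counts(seg["aa"])
            fixed_bp += fb
            fixed_gc += fg
            n_random_codons += nr
        elif seg["kind"] == "gt_cluster":
            for _ in range(seg["n_genes"]):
                fb, fg, nr = _gene_counts(220)
                fixed_bp += fb + _GAP_LEN
                fixed_gc += fg + 2 * wall_gc
                n_gap_bases += _GAP_LEN - 2 * len(STOP_WALL)
                n_random_codons += nr
        # crispr / rhodopsin / rrna segments are small; their composition is
        # close to the target and left out of the GC solve.

    total_bp_est = (
        fixed_bp + 3 * n_random_codons + n_gap_bases
    )
    g = _solve_gc_bias(
        spec.gc_target, fixed_gc, fixed_bp, n_random_codons, n_gap_bases,
        total_bp_est, jitter,
    )
    weights = _codon_weights(g, jitter)

    # --- phase C: emit sequence, genes, features
    parts: list[str] = []
    genes: list[GeneRecord] = []
    features: list[PlantedFeature] = []
    pos = 0  # 0-based offset of the next emitted base
    gi = 0

    def _emit_gene(aa: int, family: str | None, evalue: float | None,
                   codons: list[str] | None = None) -> None:
        nonlocal pos, gi
        cod = codons if codons is not None else _gene_codons(rng, aa, weights)
        seq = "".join(cod)
        parts.append(seq)
        genes.append(
            GeneRecord(
                gene_id=f"{spec.id}_g{gi:05d}",
                parent_id=spec.id,
                start=pos + 1,
                end=pos + len(seq),
                strand="+",
                taxon_path=spec.taxon_path,
                family=family,
                evalue=evalue,
            )
        )
        gi += 1
        pos += len(seq)

    def _emit_gap() -> None:
        nonlocal pos
        s = _gap_seq(rng, g)
        parts.append(s)
        pos += len(s)

    for seg in segments:
        if seg["kind"] == "gap":
            _emit_gap()
        elif seg["kind"] == "gene":
            _emit_gene(seg["aa"], seg["family"], seg["evalue"])
        elif seg["kind"] == "gt_cluster":
            start0 = pos
            first_gid = gi
            for k in range(seg["n_genes"]):
                _emit_gene(220, "GT", 1e-50)
                if k < seg["n_genes"] - 1:
                    _emit_gap()
            features.append(
                PlantedFeature(
                    kind="gt_cluster",
                    genome_id=spec.id,
                    start=start0 + 1,
                    end=pos,
                    payload={
                        "gene_ids": [
                            f"{spec.id}_g{j:05d}" for j in range(first_gid, gi)
                        ]
                    },
                )
            )
        elif seg["kind"] == "crispr":
            params = seg["params"]
            array, consensus, repeats, spacers, sources = build_crispr_array(
                rng,
                virome,
                n_repeats=int(params.get("n_repeats", 5)),
                repeat_len=int(params.get("repeat_len", 30)),
                spacer_len_range=tuple(params.get("spacer_len_range", (25, 40))),
                gc=spec.gc_target,
            )
            features.append(
                PlantedFeature(
                    kind="crispr_array",
                    genome_id=spec.id,
                    start=pos + 1,
                    end=pos + len(array),
                    payload={
                        "repeat_consensus": consensus,
                        "repeats": repeats,
                        "spacers": spacers,
                        "spacer_sources": sources,
                    },
                )
            )
            parts.append(array)
            pos += len(array)
        elif seg["kind"] == "rhodopsin":
            if rhodopsin_template is not None:
                cod = list(_SENSE_ARR[rhodopsin_template])
                # 2% codon-level divergence between planted copies
                nmut = rng.binomial(len(cod), 0.02)
                for i in rng.choice(len(cod), size=nmut, replace=False):
                    cod[int(i)] = str(_SENSE_ARR[rng.integers(len(_SENSE))])
                cod[0] = "ATG"
                cod.append(STOP_CODONS[rng.integers(3)])
                aa = len(cod) - 1
            else:
                aa = 300
                cod = None
            start0 = pos
            _emit_gene(aa, "rhodopsin", 1e-45, codons=cod)
            genes[-1] = genes[-1]  # gene already recorded
            features.append(
                PlantedFeature(
                    kind="rhodopsin_gene",
                    genome_id=spec.id,
                    start=start0 + 1,
                    end=pos,
                    payload={"gene_id": genes[-1].gene_id},
                )
            )
        elif seg["kind"] == "rrna":
            if rrna_templates is None:
                raise ValueError(f"{spec.id}: rrna_operon requested without templates")
            ssu, lsu = rrna_templates
            its = "".join(_BASES[rng.choice(4, size=250)])
            operon = ssu + its + lsu
            features.append(
                PlantedFeature(
                    kind="rrna_operon",
                    genome_id=spec.id,
                    start=pos + 1,
                    end=pos + len(operon),
                    payload={"its_start": pos + len(ssu) + 1, "its_end": pos + len(ssu) + len(its)},
                )
            )
            parts.append(operon)
            pos += len(operon)

    seq = "".join(parts)
    record = SequenceRecord(id=spec.id, seq=seq, source="genome")
    from .io_core import gc_content

    realized = gc_content(record)
    if abs(realized - spec.gc_target) > 0.02:
        raise RuntimeError(
            f"{spec.id}: realized GC {realized:.3f} misses target {spec.gc_target}"
        )
    return record, genes, features


# ---------------------------------------------------------------------------
# community assembly


def make_virome(
    seed: int | np.random.Generator,
    n: int = 25,
    length_range: tuple[int, int] = (5000, 20000),
    gc: float = 0.45,
) -> list[SequenceRecord]:
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    out = []
    for i in range(n):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append(
            SequenceRecord(
                id=f"virome_{i:03d}",
                seq="".join(_BASES[rng.choice(4, size=L, p=p)]),
                source="virome",
            )
        )
    return out


def build_community(
    specs: Sequence[GenomeSpec],
    seed: int,
    abundance_sigma: float = 1.0,
    virome_n: int = 25,
) -> CommunityTruth:
    """Generate all genomes, the virome and lognormal abundances.

    Genome seeds are derived deterministically from ``seed``; abundances
    follow LogNormal(0, ``abundance_sigma``) normalised to sum to 1.
    """
    rng = np.random.default_rng(seed)
    virome = make_virome(rng, n=virome_n)
    needs_rhod = any(
        any(_feature_params(e)[0] == "rhodopsin_gene" for e in s.planted_features)
        for s in specs
    )
    rhod_template = (
        rng.integers(0, len(_SENSE), size=299) if needs_rhod else None
    )
    needs_rrna = any(
        any(_feature_params(e)[0] == "rrna_operon" for e in s.planted_features)
        for s in specs
    )
    rrna_templates = None
    if needs_rrna:
        ssu = "".join(_BASES[rng.choice(4, size=1200)])
        lsu = "".join(_BASES[rng.choice(4, size=1000)])
        rrna_templates = (ssu, lsu)

    records: dict[str, SequenceRecord] = {}
    genes: dict[str, list[GeneRecord]] = {}
    features: list[PlantedFeature] = []
    for spec in specs:
        gseed = int(rng.integers(0, 2**31 - 1))
        rec, grecs, feats = generate_genome(
            spec, gseed, virome=virome,
            rhodopsin_template=rhod_template, rrna_templates=rrna_templates,
        )
        records[spec.id] = rec
        genes[spec.id] = grecs
        features.extend(feats)

    weights = rng.lognormal(mean=0.0, sigma=abundance_sigma, size=len(specs))
    weights = weights / weights.sum()
    abundances = {s.id: float(w) for s, w in zip(specs, weights)}
    return CommunityTruth(
        genomes=list(specs),
        records=records,
        genes=genes,
        abundances=abundances,
        features=features,
        virome=virome,
    )


# ---------------------------------------------------------------------------
# read simulation


def _inject_errors(
    seq: str,
    rate: float,
    sub_ins_del: Sequence[float],
    rng: np.random.Generator,
) -> tuple[str, int]:
    """Inject point errors at the given per-base rate with the stated
    substitution:insertion:deletion mix. Returns (mutated, n_errors)."""
    n = len(seq)
    if rate <= 0 or n == 0:
        return seq, 0
    n_err = int(rng.binomial(n, rate))
    if n_err == 0:
        return seq, 0
    w = np.asarray(sub_ins_del, dtype=float)
    w = w / w.sum()
    positions = np.sort(rng.choice(n, size=n_err, replace=False))[::-1]
    kinds = rng.choice(3, size=n_err, p=w)
    chars = list(seq)
    for p, k in zip(positions, kinds):
        p = int(p)
        if k == 0:  # substitution to a different base
            old = chars[p]
            alt = "ACGT".replace(old, "") if old in "ACGT" else "ACGT"
            chars[p] = alt[int(rng.integers(len(alt)))]
        elif k == 1:  # insertion after p
            chars.insert(p + 1, "ACGT"[int(rng.integers(4))])
        else:  # deletion
            del chars[p]
    return "".join(chars), n_err


def simulate_long_reads(
    truth: CommunityTruth,
    model: ErrorModel,
    n_reads: int,
    passes: int,
    mean_bp: float = 5400.0,
    sigma: float = 0.4,
    seed: int = 0,
    min_bp: int = 500,
    max_bp: int = 50000,
    id_prefix: str = "lr",
) -> list[SequenceRecord]:
    """Simulate CCS-like long reads.

    Read lengths are lognormal (parameterised by the target mean),
    truncated to [min_bp, max_bp]; source genomes are drawn with
    probability proportional to abundance x genome length; errors are
    injected at the per-pass rate with the model's sub:ins:del mix.
    Provenance (1-based closed genome coordinates of the error-free
    template, strand, passes, error count) is recorded in
    ``truth.read_provenance``.
    """
    if passes not in model.per_pass_table:
        raise KeyError(f"passes={passes} not in the error model table")
    rate = model.per_pass_table[passes]
    rng = np.random.default_rng(seed)
    ids = [g.id for g in truth.genomes]
    glens = np.array([len(truth.records[i]) for i in ids], dtype=float)
    w = np.array([truth.abundances[i] for i in ids]) * glens
    w = w / w.sum()
    if mean_bp > glens.min():
        logger.warning(
            "requested mean read length %.0f exceeds shortest genome (%d bp); "
            "reads will be truncated at genome ends", mean_bp, int(glens.min()),
        )
    mu = np.log(mean_bp) - sigma**2 / 2.0
    lengths = np.clip(rng.lognormal(mu, sigma, size=n_reads), min_bp, max_bp).astype(int)
    choices = rng.choice(len(ids), size=n_reads, p=w)
    strands = rng.choice(["+", "-"], size=n_reads)
    reads = []
    for i in range(n_reads):
        gid = ids[choices[i]]
        gseq = truth.records[gid].seq
        L = min(int(lengths[i]), len(gseq))
        start0 = int(rng.integers(0, len(gseq) - L + 1))
        template = gseq[start0 : start0 + L]
        if strands[i] == "-":
            template = revcomp(template)
        read_seq, n_err = _inject_errors(template, rate, model.sub_ins_del, rng)
        rid = f"{id_prefix}_{i:07d}"
        if rid in truth.read_provenance:
            raise ValueError(f"duplicate read id {rid}")
        reads.append(SequenceRecord(id=rid, seq=read_seq, source="long_read"))
        truth.read_provenance[rid] = Provenance(
            read_id=rid, genome_id=gid, start=start0 + 1, end=start0 + L,
            strand=str(strands[i]), passes=passes, n_errors=n_err,
        )
    return reads


def simulate_short_reads(
    truth: CommunityTruth,
    error_rate: float,
    n_pairs: int,
    read_len: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    seed: int = 0,
    id_prefix: str = "sr",
) -> tuple[list[SequenceRecord], list[SequenceRecord]]:
    """Paired fixed-length short reads with substitution-only errors."""
    rng = np.random.default_rng(seed)
    ids = [g.id for g in truth.genomes]
    glens = np.array([len(truth.records[i]) for i in ids], dtype=float)
    w = np.array([truth.abundances[i] for i in ids]) * glens
    w = w / w.sum()
    choices = rng.choice(len(ids), size=n_pairs, p=w)
    r1s, r2s = [], []
    for i in range(n_pairs):
        gid = ids[choices[i]]
        gseq = truth.records[gid].seq
        insert = int(max(read_len, rng.normal(insert_mean, insert_sd)))
        insert = min(insert, len(gseq))
        start0 = int(rng.integers(0, len(gseq) - insert + 1))
        frag = gseq[start0 : start0 + insert]
        fwd = frag[:read_len]
        rev = revcomp(frag[-read_len:])
        fwd, e1 = _inject_errors(fwd, error_rate, (1, 0, 0), rng)
        rev, e2 = _inject_errors(rev, error_rate, (1, 0, 0), rng)
        rid = f"{id_prefix}_{i:07d}"
        for mate, seq_, nerr, s_, e_ in (
            ("1", fwd, e1, start0 + 1, start0 + read_len),
            ("2", rev, e2, start0 + insert - read_len + 1, start0 + insert),
        ):
            mid = f"{rid}/{mate}"
            if mid in truth.read_provenance:
                raise ValueError(f"duplicate read id {mid}")
            truth.read_provenance[mid] = Provenance(
                read_id=mid, genome_id=gid, start=s_, end=e_,
                strand="+" if mate == "1" else "-", passes=0, n_errors=nerr,
            )
        r1s.append(SequenceRecord(id=f"{rid}/1", seq=fwd, source="short_read"))
        r2s.append(SequenceRecord(id=f"{rid}/2", seq=rev, source="short_read"))
    return r1s, r2s


# ---------------------------------------------------------------------------
# truth-derived tables


def gene_hits_for_reads(
    truth: CommunityTruth,
    reads: Iterable[SequenceRecord],
    miscall_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, list[GeneRecord]]:
    """Fabricate per-read best-hit gene tables from provenance: every genome
    gene overlapping the read span yields one gene record whose taxon path
    is the source genome's (or, at ``miscall_rate``, another genome's).
    Coordinates refer to the error-free template and are only meaningful
    for reads without indel errors."""
    rng = np.random.default_rng(seed)
    taxa = [g.taxon_path for g in truth.genomes]
    starts = {
        gid: np.array([g.start for g in glist])
        for gid, glist in truth.genes.items()
    }
    ends = {
        gid: np.array([g.end for g in glist]) for gid, glist in truth.genes.items()
    }
    out: dict[str, list[GeneRecord]] = {}
    for read in reads:
        prov = truth.read_provenance.get(read.id)
        if prov is None:
            raise KeyError(f"no provenance for read {read.id}")
        glist = truth.genes[prov.genome_id]
        lo = int(np.searchsorted(ends[prov.genome_id], prov.start, side="left"))
        hi = int(np.searchsorted(starts[prov.genome_id], prov.end, side="right"))
        hits = []
        for k, g in enumerate(glist[lo:hi]):
            path = g.taxon_path
            if miscall_rate > 0 and rng.random() < miscall_rate:
                path = taxa[int(rng.integers(len(taxa)))]
            hits.append(
                GeneRecord(
                    gene_id=f"{read.id}_h{k:04d}",
                    parent_id=read.id,
                    start=max(1, g.start - prov.start + 1),
                    end=min(len(read), g.end - prov.start + 1),
                    strand=g.strand,
                    taxon_path=path,
                    family=g.family,
                    evalue=g.evalue,
                )
            )
        out[read.id] = hits
    return out


def save_community(truth: CommunityTruth, outdir: str | Path) -> None:
    """Write genomes.fasta, virome.fasta, genes.tsv, truth.json."""
    from .io_core import write_genes_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(truth.records.values(), outdir / "genomes.fasta")
    write_fasta(truth.virome, outdir / "virome.fasta")
    write_genes_tsv(
        [g for glist in truth.genes.values() for g in glist], outdir / "genes.tsv"
    )
    payload = {
        "abundances": truth.abundances,
        "features": [
            {
                "kind": f.kind,
                "genome_id": f.genome_id,
                "start": f.start,
                "end": f.end,
                "payload": f.payload,
            }
            for f in truth.features
        ],
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(payload, fh, indent=1)


def write_provenance_tsv(truth: CommunityTruth, path: str | Path) -> None:
    import pandas as pd

    rows = [vars(p) for p in truth.read_provenance.values()]
    pd.DataFrame(
        rows,
        columns=["read_id", "genome_id", "start", "end", "strand", "passes", "n_errors"],
    ).to_csv(path, sep="\t", index=False)
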