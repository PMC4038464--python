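"""Suffix index, read splitting and collinear placement against brute force."""

import itertools

import numpy as np
import pytest

from steatoseq import splitmap
from steatoseq.sequence import revcomp
from steatoseq.splitmap import (build_suffix_index, candidate_placements,
                                locate_exact, map_reads, place_read,
                                split_read)

from conftest import random_genome


# -- independent oracles -----------------------------------------------------


def naive_suffix_order(text: bytes) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_scan(genome: dict[str, str], query: str) -> list[tuple[str, int]]:
    hits = []
    for chrom, seq in genome.items():
        start = 0
        while True:
            pos = seq.find(query, start)
            if pos == -1:
                break
            hits.append((chrom, pos))
            start = pos + 1
    return sorted(hits)


def brute_force_placements(genome, parts, max_gap):
    """Exhaustive enumeration of all 3-part hit combinations, both strands."""
    p = len(parts.parts[0])
    found = []
    for strand in "+-":
        if strand == "+":
            plist = parts.parts
        else:
            plist = tuple(revcomp(x) for x in reversed(parts.parts))
        hit_lists = [naive_scan(genome, x) for x in plist]
        for combo in itertools.product(*hit_lists):
            chroms = {c for c, _ in combo}
            if len(chroms) != 1:
                continue
            starts = [s for _, s in combo]
            gaps = [b - (a + p) for a, b in zip(starts[:-1], starts[1:])]
            if all(0 <= g <= max_gap for g in gaps):
                found.append((combo[0][0], strand, tuple(starts)))
    return sorted(found)


# -- suffix array ------------------------------------------------------------


def test_suffix_array_small_example():
    """'ACGTAC' suffixes sort to [4,0,5,1,2,3] (sentinel positions aside)."""
    idx = build_suffix_index({"chr1": "ACGTAC"})
    real = [int(i) for i in idx.sa if idx.text[i:i + 1] != b"#"]
    assert real == [4, 0, 5, 1, 2, 3]


def test_suffix_array_single_base():
    idx = build_suffix_index({"chr1": "A"})
    assert sorted(int(i) for i in idx.sa) == [0, 1]  # base + sentinel
    assert locate_exact(idx, "A") == [("chr1", 0)]


@pytest.mark.parametrize("length,alphabet", [(50, "ACGT"), (300, "ACGT"),
                                             (1000, "ACGTN"), (5000, "ACGT")])
def test_suffix_array_matches_naive_sort(rng, length, alphabet):
    genome = {"c1": random_genome(rng, length, alphabet),
              "c2": random_genome(rng, max(10, length // 3), alphabet)}
    idx = build_suffix_index(genome)
    assert list(idx.sa) == naive_suffix_order(idx.text)
    assert sorted(idx.sa) == list(range(len(idx.text)))  # permutation


def test_empty_genome_rejected():
    with pytest.raises(ValueError):
        build_suffix_index({})
    with pytest.raises(ValueError):
        build_suffix_index({"chr1": ""})


# -- exact lookup ------------------------------------------------------------


def test_locate_repeated_query():
    idx = build_suffix_index({"chr1": "ACGTACGT"})
    assert locate_exact(idx, "ACGT") == [("chr1", 0), ("chr1", 4)]


def test_locate_absent_and_whole_chromosome():
    idx = build_suffix_index({"chr1": "ACGTACGT"})
    assert locate_exact(idx, "TTTT") == []
    assert locate_exact(idx, "ACGTACGT") == [("chr1", 0)]


def test_locate_query_with_n_is_unmappable():
    idx = build_suffix_index({"chr1": "ACGNACGT"})
    assert locate_exact(idx, "ACGN") == []
    # N in the reference is never matched either
    assert locate_exact(idx, "GNAC") == []


def test_locate_never_spans_chromosomes(rng):
    genome = {"a": "ACGT", "b": "TTTT"}
    idx = build_suffix_index(genome)
    # "GTTT" exists only across the sentinel; must not be found
    assert locate_exact(idx, "GTTT") == []


@pytest.mark.parametrize("trial", range(8))
def test_locate_matches_naive_scan(rng, trial):
    genome = {"c1": random_genome(rng, 400), "c2": random_genome(rng, 150)}
    idx = build_suffix_index(genome)
    for qlen in (1, 2, 5, 12):
        seq = genome["c1"]
        start = int(rng.integers(0, len(seq) - qlen))
        query = seq[start:start + qlen]
        assert locate_exact(idx, query) == naive_scan(genome, query)


# -- read splitting ----------------------------------------------------------


def test_split_100bp_read_offsets():
    read = random_genome(np.random.default_rng(0), 100)
    parts = split_read(read)
    assert parts.offsets_in_read == (2, 34, 66)
    assert parts.parts == (read[2:34], read[34:66], read[66:98])
    assert all(len(p) == 32 for p in parts.parts)


def test_split_homopolymer():
    parts = split_read("A" * 100)
    assert parts.parts == ("A" * 32,) * 3


def test_split_indivisible_length_errors():
    with pytest.raises(ValueError, match="divisible"):
        split_read("A" * 101)


# -- placement ---------------------------------------------------------------


def _toy_genome_with_read(rng, intron=0):
    """A genome and a read copied from it with an optional intron gap."""
    seq = random_genome(rng, 3000)
    pos = 500
    if intron:
        # parts 1+2 contiguous, part 3 resumes after the intron
        read = seq[pos - 2: pos + 64] + seq[pos + 64 + intron: pos + 64 + intron + 34]
    else:
        read = seq[pos - 2: pos + 98]
    assert len(read) == 100
    return {"chr1": seq}, read, pos


def test_place_exonic_read_at_origin(rng):
    genome, read, pos = _toy_genome_with_read(rng)
    idx = build_suffix_index(genome)
    pl = place_read(idx, split_read(read))
    assert pl is not None and pl.unique
    assert pl.chromosome == "chr1" and pl.strand == "+"
    assert pl.part_starts == (pos, pos + 32, pos + 64)
    assert pl.gaps == (0, 0)


def test_place_read_spanning_intron(rng):
    genome, read, pos = _toy_genome_with_read(rng, intron=50)
    idx = build_suffix_index(genome)
    pl = place_read(idx, split_read(read), max_gap=1000)
    assert pl is not None
    assert pl.gaps == (0, 50)


def test_duplicated_locus_is_ambiguous(rng):
    core = random_genome(rng, 120)
    genome = {"chr1": random_genome(rng, 300) + core
              + random_genome(rng, 300) + core + random_genome(rng, 100)}
    idx = build_suffix_index(genome)
    pl = place_read(idx, split_read(core[:100]))
    assert pl is None  # two consistent placements -> discarded


def test_reverse_complement_read_places_on_minus_strand(rng):
    genome, read, pos = _toy_genome_with_read(rng)
    idx = build_suffix_index(genome)
    pl = place_read(idx, split_read(revcomp(read)))
    assert pl is not None and pl.strand == "-"
    assert pl.part_starts == (pos, pos + 32, pos + 64)


def test_strand_symmetry(rng):
    """Mapping against the reverse-complemented genome mirrors coordinates."""
    genome, read, _pos = _toy_genome_with_read(rng)
    n = len(genome["chr1"])
    idx_fwd = build_suffix_index(genome)
    idx_rev = build_suffix_index({"chr1": revcomp(genome["chr1"])})
    pl = place_read(idx_fwd, split_read(read))
    pl_rev = place_read(idx_rev, split_read(read))
    assert pl is not None and pl_rev is not None
    assert pl_rev.strand == {"+": "-", "-": "+"}[pl.strand]
    mirrored = tuple(sorted(n - (s + 32) for s in pl.part_starts))
    assert pl_rev.part_starts == mirrored


def test_min_parts_two_rescues_damaged_part(rng):
    genome, read, pos = _toy_genome_with_read(rng)
    idx = build_suffix_index(genome)
    damaged = read[:40] + "N" + read[41:]  # N inside part 2
    parts = split_read(damaged)
    assert place_read(idx, parts) is None
    pl = place_read(idx, parts, min_parts=2)
    assert pl is not None
    assert pl.part_starts[1] is None
    assert pl.part_starts[0] == pos and pl.part_starts[2] == pos + 64


@pytest.mark.parametrize("trial", range(10))
def test_candidates_equal_brute_force(rng, trial):
    """Exhaustive hit-combination enumeration agrees with the mapper."""
    genome = {"c1": random_genome(rng, 1500, "ACGT"),
              "c2": random_genome(rng, 800, "ACGT")}
    idx = build_suffix_index(genome)
    seq = genome["c1"] if trial % 2 else genome["c2"]
    pos = int(rng.integers(2, len(seq) - 98))
    read = seq[pos - 2: pos + 98]
    if trial % 3 == 0:
        read = revcomp(read)
    parts = split_read(read)
    got = sorted((c.chromosome, c.strand, tuple(c.part_starts))
                 for c in candidate_placements(idx, parts, max_gap=200))
    assert got == brute_force_placements(genome, parts, max_gap=200)


def test_batch_mapper_equals_reference(rng, small_config):
    """The vectorised batch path and per-read placement agree read by read."""
    from steatoseq import synthdata
    from steatoseq.sequence import decode

    genome, models = synthdata.make_reference(small_config)
    expr = synthdata.simulate_true_expression(small_config,
                                              [m.gene_id for m in models])
    reads, _ = synthdata.simulate_reads(genome, models, expr.true_expression,
                                        small_config)
    codes = reads["ctrl_1"].codes[:400]
    idx = build_suffix_index(genome)
    table, stats = map_reads(idx, codes)
    placed = {int(ri): (int(ci), st, tuple(int(s) for s in row))
              for ri, ci, st, row in zip(table.read_indices, table.chrom_idx,
                                         table.strand, table.starts)}
    n_unique = 0
    for i in range(len(codes)):
        pl = place_read(idx, split_read(decode(codes[i])))
        if pl is None:
            assert i not in placed
        else:
            n_unique += 1
            ci, st, starts = placed[i]
            assert idx.chrom_names[ci] == pl.chromosome
            assert st == pl.strand
            assert starts == pl.part_starts
    assert stats["unique"] == n_unique == len(placed)
    assert stats["total"] == len(codes)
    assert stats["unique"] + stats["ambiguous"] + stats["unplaced"] == stats["total"]


def test_sam_export(tmp_path, rng):
    import pysam
    from steatoseq.sequence import encode

    genome, read, pos = _toy_genome_with_read(rng, intron=50)
    idx = build_suffix_index(genome)
    codes = np.array([encode(read)])
    table, _ = map_reads(idx, codes, max_gap=1000)
    path = tmp_path / "out.sam"
    splitmap.write_sam(table, ["r1"], codes, {"chr1": len(genome["chr1"])}, path)
    with pysam.AlignmentFile(str(path)) as fh:
        rec = next(fh)
    assert rec.reference_start == pos
    assert rec.cigarstring == "64M50N32M"
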