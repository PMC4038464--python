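"""Split-read exact mapper over a suffix array.

Each 100 bp single-end read is trimmed by 2 bp at both ends, split into
three 32 bp parts, and every part is matched exactly against the genome via
binary search over a suffix array. A read is placed when its three parts hit
one chromosome and strand, in read order, with both inter-part gaps inside
``[0, max_gap]`` (gaps absorb introns); reads with no consistent placement or
with more than one are counted but discarded. There is no mismatch tolerance
within a part — splitting the read is itself the device that tolerates a
damaged read end — though ``min_parts=2`` optionally rescues reads with one
unmatchable part.

``place_read`` is the per-read reference implementation;
:func:`map_reads` is an equivalent vectorised path that packs 32-mers into
uint64 keys and resolves the common one-hit-per-part case with
``searchsorted``, falling back to ``place_read``'s candidate enumeration for
repetitive reads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .sequence import decode, encode, pack_kmers, pack_rows, revcomp_codes

SENTINEL = b"#"  # sorts before A/C/G/T/N, never matched by ACGT queries
DEFAULT_MAX_GAP = 100_000


# -- suffix index ------------------------------------------------------------


@dataclass
class SuffixIndex:
    """Concatenated reference with sentinel separators and its suffix array."""

    text: bytes                      # upper-case reference, '#' after each chromosome
    sa: np.ndarray                   # int64 suffix start offsets, lexicographic
    boundaries: dict[str, tuple[int, int]]  # chromosome -> (start, end) in text
    chrom_names: list[str]
    chrom_of: np.ndarray             # int32 per text position, -1 at sentinels
    chrom_start: np.ndarray          # int64 text offset of each chromosome

    # lazily built 32-mer lookup table (sorted packed keys + text positions)
    _kmer_k: int | None = field(default=None, repr=False)
    _kmer_keys: np.ndarray | None = field(default=None, repr=False)
    _kmer_pos: np.ndarray | None = field(default=None, repr=False)

    def kmer_table(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        if self._kmer_k != k:
            codes = _text_codes(self.text)
            keys, valid = pack_kmers(codes, k)
            pos = np.nonzero(valid)[0]
            keys = keys[valid]
            order = np.argsort(keys, kind="stable")
            self._kmer_keys = keys[order]
            self._kmer_pos = pos[order]
            self._kmer_k = k
        return self._kmer_keys, self._kmer_pos


def _text_codes(text: bytes) -> np.ndarray:
    raw = np.frombuffer(text, dtype=np.uint8)
    table = np.full(256, 5, dtype=np.uint8)  # sentinel/other -> 5 (invalid)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    table[ord("N")] = 4
    return table[raw]


def _suffix_array(raw: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over a uint8 sequence (O(n log^2 n))."""
    n = len(raw)
    rank = raw.astype(np.int64)
    sa = np.arange(n)
    k = 1
    tmp = np.empty(n, np.int64)
    while True:
        key2 = np.full(n, -1, np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        tmp[order[0]] = 0
        prev, cur = order[:-1], order[1:]
        tmp[cur] = np.cumsum((rank[cur] != rank[prev]) | (key2[cur] != key2[prev]))
        rank, sa = tmp.copy(), order
        if rank[sa[-1]] == n - 1:
            return sa
        k *= 2


def build_suffix_index(genome: dict[str, str]) -> SuffixIndex:
    """Index a reference: concatenate chromosomes with '#' sentinels, sort suffixes."""
    if not genome:
        raise ValueError("cannot index an empty genome")
    pieces = []
    boundaries: dict[str, tuple[int, int]] = {}
    names = []
    offset = 0
    for name, seq in genome.items():
        if not seq:
            raise ValueError(f"chromosome {name!r} is empty")
        up = seq.upper()
        if set(up) - set("ACGTN"):
            raise ValueError(f"chromosome {name!r} contains non-ACGTN characters")
        pieces.append(up.encode() + SENTINEL)
        boundaries[name] = (offset, offset + len(up))
        names.append(name)
        offset += len(up) + 1
    text = b"".join(pieces)
    sa = _suffix_array(np.frombuffer(text, dtype=np.uint8))

    chrom_of = np.full(len(text), -1, dtype=np.int32)
    chrom_start = np.zeros(len(names), dtype=np.int64)
    for ci, name in enumerate(names):
        s, e = boundaries[name]
        chrom_of[s:e] = ci
        chrom_start[ci] = s
    return SuffixIndex(text=text, sa=sa, boundaries=boundaries,
                       chrom_names=names, chrom_of=chrom_of,
                       chrom_start=chrom_start)


def locate_exact(index: SuffixIndex, query: str) -> list[tuple[str, int]]:
    """All exact occurrences of ``query`` as (chromosome, 0-based start).

    Binary search over the suffix array; queries containing N (or any
    non-ACGT character) return no hits, signalling an unmappable part.
    """
    if not query:
        raise ValueError("empty query")
    q = query.upper().encode()
    if set(q) - set(b"ACGT"):
        return []
    text, sa = index.text, index.sa
    m = len(q)

    def prefix_less(i: int) -> bool:          # suffix < query
        return text[sa[i]: sa[i] + m] < q

    def prefix_leq(i: int) -> bool:           # suffix prefix <= query
        return text[sa[i]: sa[i] + m] <= q

    def bisect(pred) -> int:
        lo, hi = 0, len(sa)
        while lo < hi:
            mid = (lo + hi) // 2
            if pred(mid):
                lo = mid + 1
            else:
                hi = mid
        return lo

    first = bisect(prefix_less)
    last = bisect(prefix_leq)
    hits = []
    for pos in sa[first:last]:
        ci = index.chrom_of[pos]
        # a match of pure ACGT can never contain a sentinel, so it always
        # lies inside one chromosome
        hits.append((index.chrom_names[ci], int(pos - index.chrom_start[ci])))
    hits.sort()
    return hits


# -- read splitting ----------------------------------------------------------


@dataclass(frozen=True)
class ReadPartSet:
    """The trimmed read cut into equal contiguous parts."""

    read_id: str
    parts: tuple[str, ...]
    trim: int
    offsets_in_read: tuple[int, ...]

    @property
    def part_length(self) -> int:
        return len(self.parts[0])


def split_read(read: str, trim: int = 2, n_parts: int = 3,
               read_id: str = "") -> ReadPartSet:
    """Trim ``trim`` bases from each end and cut into ``n_parts`` equal parts.

    A 100 bp read with the defaults becomes read[2:34], read[34:66],
    read[66:98].
    """
    core = len(read) - 2 * trim
    if core <= 0 or core % n_parts != 0:
        raise ValueError(
            f"read length {len(read)} minus 2*{trim} trim = {core} "
            f"is not divisible into {n_parts} equal parts"
        )
    p = core // n_parts
    offsets = tuple(trim + i * p for i in range(n_parts))
    parts = tuple(read[o:o + p] for o in offsets)
    return ReadPartSet(read_id=read_id, parts=parts, trim=trim,
                       offsets_in_read=offsets)


# -- placement ---------------------------------------------------------------


@dataclass(frozen=True)
class Placement:
    """Collinear genomic placement of a read's parts (0-based, half-open)."""

    read_id: str
    chromosome: str
    strand: str
    part_starts: tuple[int | None, ...]  # ascending genomic order; None = rescued part
    part_length: int
    unique: bool = True

    @property
    def gaps(self) -> tuple[int, ...]:
        present = [s for s in self.part_starts if s is not None]
        return tuple(b - (a + self.part_length)
                     for a, b in zip(present[:-1], present[1:]))

    @property
    def left(self) -> int:
        return min(s for s in self.part_starts if s is not None)


def _rc_parts(parts: ReadPartSet) -> ReadPartSet:
    """Parts of the reverse-complemented read (order reversed, each rc'd)."""
    rc = tuple(decode(revcomp_codes(encode(p))) for p in reversed(parts.parts))
    return ReadPartSet(read_id=parts.read_id, parts=rc, trim=parts.trim,
                       offsets_in_read=parts.offsets_in_read)


def _combine(hit_lists: list[list[tuple[str, int]]], p: int,
             max_gap: int) -> list[tuple[str, tuple[int, ...]]]:
    """All chromosome-consistent ascending combinations with gaps in [0, max_gap]."""
    out = []
    for chrom, s1 in hit_lists[0]:
        for chrom2, s2 in hit_lists[1]:
            if chrom2 != chrom or not (0 <= s2 - (s1 + p) <= max_gap):
                continue
            if len(hit_lists) == 2:
                out.append((chrom, (s1, s2)))
                continue
            for chrom3, s3 in hit_lists[2]:
                if chrom3 == chrom and 0 <= s3 - (s2 + p) <= max_gap:
                    out.append((chrom, (s1, s2, s3)))
    return out


def _strand_candidates(index: SuffixIndex, parts: ReadPartSet, strand: str,
                       max_gap: int, min_parts: int) -> list[Placement]:
    use = parts if strand == "+" else _rc_parts(parts)
    hits = [locate_exact(index, part) for part in use.parts]
    p = use.part_length
    placements = [
        Placement(read_id=parts.read_id, chromosome=chrom, strand=strand,
                  part_starts=starts, part_length=p)
        for chrom, starts in _combine(hits, p, max_gap)
    ]
    if placements or min_parts >= 3:
        return placements
    # rescue: drop one part, remaining two must stay consistent
    rescued = []
    n = len(use.parts)
    for skip in range(n):
        kept = [hits[i] for i in range(n) if i != skip]
        span = max_gap if skip in (0, n - 1) else 2 * max_gap + p
        for chrom, (sa_, sb) in _combine(kept, p, span):
            if skip not in (0, n - 1) and sb - (sa_ + p) < p:
                continue  # no room for the skipped middle part
            starts: list[int | None] = [None] * n
            ki = 0
            for i in range(n):
                if i != skip:
                    starts[i] = (sa_, sb)[ki]  # ascending genomic chain order
                    ki += 1
            rescued.append(Placement(read_id=parts.read_id, chromosome=chrom,
                                     strand=strand, part_starts=tuple(starts),
                                     part_length=p))
    return rescued


def candidate_placements(index: SuffixIndex, parts: ReadPartSet,
                         max_gap: int = DEFAULT_MAX_GAP,
                         min_parts: int = 3) -> list[Placement]:
    """Every consistent placement of the parts on either strand."""
    full = (_strand_candidates(index, parts, "+", max_gap, 3)
            + _strand_candidates(index, parts, "-", max_gap, 3))
    if full or min_parts >= 3:
        return full
    return (_strand_candidates(index, parts, "+", max_gap, min_parts)
            + _strand_candidates(index, parts, "-", max_gap, min_parts))


def place_read(index: SuffixIndex, parts: ReadPartSet,
               max_gap: int = DEFAULT_MAX_GAP,
               min_parts: int = 3) -> Placement | None:
    """Unique consistent placement of a read, or None.

    None covers both the unplaced read (no consistent combination) and the
    multi-mapping read (several combinations); :func:`map_reads` keeps the
    two apart in its summary statistics.
    """
    if min_parts not in (2, 3):
        raise ValueError("min_parts must be 2 or 3")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    cands = candidate_placements(index, parts, max_gap, min_parts)
    if len(cands) == 1:
        return cands[0]
    return None


# -- batch mapping -----------------------------------------------------------


@dataclass
class PlacementTable:
    """Columnar uniquely-placed reads (chromosome-local coordinates)."""

    read_indices: np.ndarray   # int64 row index into the input ReadSet
    chrom_idx: np.ndarray      # int32 index into chrom_names
    strand: np.ndarray         # '+' / '-' per placement
    starts: np.ndarray         # (n, 3) int64 ascending genomic part starts
    part_length: int
    chrom_names: list[str]

    def __len__(self) -> int:
        return len(self.read_indices)

    def to_placements(self, read_ids: list[str]) -> list[Placement]:
        return [
            Placement(read_id=read_ids[ri], chromosome=self.chrom_names[ci],
                      strand=st, part_starts=tuple(int(s) for s in row),
                      part_length=self.part_length)
            for ri, ci, st, row in zip(self.read_indices, self.chrom_idx,
                                       self.strand, self.starts)
        ]


def map_reads(index: SuffixIndex, codes: np.ndarray,
              max_gap: int = DEFAULT_MAX_GAP, min_parts: int = 3,
              trim: int = 2, n_parts: int = 3) -> tuple[PlacementTable, dict]:
    """Map a batch of reads (code matrix) and return placements plus summary.

    Vectorised for the dominant case of exactly one hit per part per strand;
    reads with repetitive parts are resolved by the per-read reference path.
    """
    n_reads, L = codes.shape if codes.ndim == 2 else (0, 0)
    stats = {"total": int(n_reads), "unique": 0, "ambiguous": 0, "unplaced": 0}
    empty = PlacementTable(np.empty(0, np.int64), np.empty(0, np.int32),
                           np.empty(0, "U1"), np.empty((0, n_parts), np.int64),
                           0, index.chrom_names)
    if n_reads == 0:
        return empty, stats
    core = L - 2 * trim
    if core % n_parts != 0:
        raise ValueError(f"read length {L} minus trim not divisible by {n_parts}")
    p = core // n_parts
    if p > 32:
        raise ValueError("part length > 32 unsupported by the packed lookup")
    keys_sorted, pos_sorted = index.kmer_table(p)

    def strand_hits(strand_codes):
        los, his = [], []
        for j in range(n_parts):
            part = strand_codes[:, trim + j * p: trim + (j + 1) * p]
            k, valid = pack_rows(part)
            lo = np.searchsorted(keys_sorted, k, side="left")
            hi = np.searchsorted(keys_sorted, k, side="right")
            lo[~valid] = 0
            hi[~valid] = 0
            los.append(lo)
            his.append(hi)
        return np.stack(los), np.stack(his)

    rc = revcomp_codes(codes)
    results = []  # per strand: (n_candidates, s1, s2, s3 text positions)
    needs_fallback = np.zeros(n_reads, dtype=bool)
    for strand_codes in (codes, rc):
        lo, hi = strand_hits(strand_codes)
        cnt = hi - lo
        simple = (cnt == 1).all(axis=0)
        multi = (cnt > 1).any(axis=0) & (cnt > 0).all(axis=0)
        needs_fallback |= multi
        s = np.zeros((n_parts, n_reads), dtype=np.int64)
        for j in range(n_parts):
            s[j, simple] = pos_sorted[lo[j, simple]]
        ok = simple.copy()
        same = index.chrom_of[s[0]] >= 0
        for j in range(1, n_parts):
            gap = s[j] - (s[j - 1] + p)
            ok &= (gap >= 0) & (gap <= max_gap)
            same &= index.chrom_of[s[j]] == index.chrom_of[s[0]]
        ok &= same
        results.append((ok.astype(np.int64), s))

    ncand = results[0][0] + results[1][0]

    # exact candidate counts for repetitive reads via the reference path
    fb_placements: dict[int, list[Placement]] = {}
    if needs_fallback.any() or min_parts == 2:
        fb_idx = np.nonzero(needs_fallback | (ncand == 0) if min_parts == 2
                            else needs_fallback)[0]
        for ri in fb_idx:
            parts = split_read(decode(codes[ri]), trim=trim, n_parts=n_parts,
                               read_id=str(ri))
            cands = candidate_placements(index, parts, max_gap, min_parts)
            fb_placements[int(ri)] = cands
            ncand[ri] = len(cands)

    unique = ncand == 1
    stats["unique"] = int(unique.sum())
    stats["ambiguous"] = int((ncand > 1).sum())
    stats["unplaced"] = int((ncand == 0).sum())

    fast_unique = unique & ~np.isin(np.arange(n_reads), list(fb_placements))
    rows_idx = []
    rows_chrom = []
    rows_strand = []
    rows_starts = []
    for si, strand in enumerate("+-"):
        okv, s = results[si]
        take = fast_unique & (okv == 1)
        if si == 1:
            take &= results[0][0] == 0
        if not take.any():
            continue
        text_pos = s[:, take].T  # ascending already (collinear chain)
        ci = index.chrom_of[text_pos[:, 0]]
        local = text_pos - index.chrom_start[ci][:, None]
        rows_idx.append(np.nonzero(take)[0])
        rows_chrom.append(ci.astype(np.int32))
        rows_strand.append(np.full(int(take.sum()), strand, dtype="U1"))
        rows_starts.append(local)
    for ri, cands in fb_placements.items():
        if len(cands) == 1 and all(s is not None for s in cands[0].part_starts):
            pl = cands[0]
            rows_idx.append(np.array([ri], np.int64))
            rows_chrom.append(np.array([index.chrom_names.index(pl.chromosome)],
                                       np.int32))
            rows_strand.append(np.array([pl.strand], "U1"))
            rows_starts.append(np.array([pl.part_starts], np.int64))

    if not rows_idx:
        empty.part_length = p
        return empty, stats
    table = PlacementTable(
        read_indices=np.concatenate(rows_idx),
        chrom_idx=np.concatenate(rows_chrom),
        strand=np.concatenate(rows_strand),
        starts=np.concatenate(rows_starts),
        part_length=p,
        chrom_names=index.chrom_names,
    )
    order = np.argsort(table.read_indices, kind="stable")
    table.read_indices = table.read_indices[order]
    table.chrom_idx = table.chrom_idx[order]
    table.strand = table.strand[order]
    table.starts = table.starts[order]
    return table, stats


# -- export ------------------------------------------------------------------


def write_placements_tsv(table: PlacementTable, read_ids: list[str], path) -> None:
    with open(path, "w") as fh:
        fh.write("read\tchrom\tstrand\ts1\ts2\ts3\n")
        for ri, ci, st, row in zip(table.read_indices, table.chrom_idx,
                                   table.strand, table.starts):
            fh.write(f"{read_ids[ri]}\t{table.chrom_names[ci]}\t{st}\t"
                     + "\t".join(str(int(s)) for s in row) + "\n")


def read_placements_tsv(path, chrom_names: list[str],
                        part_length: int = 32) -> tuple[PlacementTable, list[str]]:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    name_to_idx = {n: i for i, n in enumerate(chrom_names)}
    table = PlacementTable(
        read_indices=np.arange(len(df), dtype=np.int64),
        chrom_idx=df["chrom"].map(name_to_idx).to_numpy(np.int32),
        strand=df["strand"].to_numpy("U1"),
        starts=df[["s1", "s2", "s3"]].to_numpy(np.int64),
        part_length=part_length,
        chrom_names=chrom_names,
    )
    return table, df["read"].tolist()


def write_sam(table: PlacementTable, read_ids: list[str], codes: np.ndarray,
              genome_lengths: dict[str, int], path, trim: int = 2) -> None:
    """Placements as SAM records with N-gapped CIGARs (e.g. 32M50N32M...)."""
    import pysam
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": genome_lengths[n]}
               for n in table.chrom_names],
    }
    p = table.part_length
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for ri, ci, st, row in zip(table.read_indices, table.chrom_idx,
                                   table.strand, table.starts):
            a = pysam.AlignedSegment(out.header)
            a.query_name = read_ids[ri]
            seq_codes = codes[ri]
            if st == "-":
                seq_codes = revcomp_codes(seq_codes)
            seq = decode(seq_codes)
            a.query_sequence = seq[trim:len(seq) - trim]
            a.flag = 16 if st == "-" else 0
            a.reference_id = int(ci)
            a.reference_start = int(row[0])
            cigar = []
            for j, s in enumerate(row):
                if j > 0:
                    gap = int(s - (row[j - 1] + p))
                    if gap > 0:
                        cigar.append((3, gap))       # N
                        cigar.append((0, p))         # M
                    else:
                        cigar[-1] = (0, cigar[-1][1] + p)
                else:
                    cigar.append((0, p))
            a.cigartuples = cigar
            a.mapping_quality = 60
            out.write(a)


def write_mapping_summary(stats: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(stats, fh, indent=2, sort_keys=True)
        fh.write("\n")
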