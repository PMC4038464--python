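"""Transcript models and deterministic GTF / BED12 round-tripping.

The annotation writer emits one ``transcript`` line and one ``exon`` line per
exon, in (chromosome, start) order with a fixed attribute layout, so that
write -> read -> write is byte-identical. The reader rebuilds models from the
``exon`` features alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TranscriptModel:
    """A transcript as an ordered chain of exons on one chromosome.

    Coordinates are 0-based half-open throughout; conversion to the 1-based
    inclusive GTF convention happens only at (de)serialisation.
    """

    gene_id: str
    transcript_id: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        prev_end = -1
        for start, end in self.exons:
            if not (0 <= start < end):
                raise ValueError(f"bad exon interval [{start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be sorted and disjoint")
            prev_end = end
        if not self.exons:
            raise ValueError("transcript needs at least one exon")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def spliced_sequence(self, chrom_seq: str) -> str:
        """Concatenated exon sequence in genomic order (sense strand)."""
        return "".join(chrom_seq[s:e] for s, e in self.exons)

    def to_genomic(self, offset: int) -> int:
        """Map a spliced-transcript offset to its genomic coordinate."""
        if offset < 0 or offset >= self.spliced_length:
            raise IndexError(f"offset {offset} outside spliced transcript")
        consumed = 0
        for s, e in self.exons:
            if offset < consumed + (e - s):
                return s + (offset - consumed)
            consumed += e - s
        raise AssertionError("unreachable")

    def block_of(self, offset: int) -> int:
        """Index of the exon containing a spliced offset."""
        consumed = 0
        for i, (s, e) in enumerate(self.exons):
            if offset < consumed + (e - s):
                return i
            consumed += e - s
        raise IndexError(f"offset {offset} outside spliced transcript")


# -- GTF ---------------------------------------------------------------------

_SOURCE = "steatoseq"


def write_gtf(models: list[TranscriptModel], path) -> None:
    models = sorted(models, key=lambda m: (m.chromosome, m.start, m.transcript_id))
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            fh.write("\t".join([
                m.chromosome, _SOURCE, "transcript",
                str(m.start + 1), str(m.end), ".", m.strand, ".", attrs,
            ]) + "\n")
            for s, e in m.exons:
                fh.write("\t".join([
                    m.chromosome, _SOURCE, "exon",
                    str(s + 1), str(e), ".", m.strand, ".", attrs,
                ]) + "\n")


def _parse_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in attr.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        try:
            key, value = chunk.split(" ", 1)
        except ValueError:
            raise ValueError(f"malformed GTF attribute at line {lineno}: {chunk!r}")
        out[key] = value.strip().strip('"')
    return out


def read_gtf(path) -> list[TranscriptModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"GTF line {lineno}: expected 9 columns, got {len(cols)}")
            chrom, _source, feature, start, end, _score, strand, _frame, attr = cols
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr, lineno)
            tid = attrs.get("transcript_id")
            gid = attrs.get("gene_id")
            if tid is None or gid is None:
                raise ValueError(f"GTF line {lineno}: missing gene_id/transcript_id")
            rec = exons.setdefault(tid, {"gene_id": gid, "chrom": chrom,
                                         "strand": strand, "exons": []})
            rec["exons"].append((int(start) - 1, int(end)))
    models = []
    for tid, rec in exons.items():
        models.append(TranscriptModel(
            gene_id=rec["gene_id"], transcript_id=tid,
            chromosome=rec["chrom"], strand=rec["strand"],
            exons=tuple(sorted(rec["exons"])),
        ))
    models.sort(key=lambda m: (m.chromosome, m.start, m.transcript_id))
    return models


def write_bed12(models: list[TranscriptModel], path) -> None:
    models = sorted(models, key=lambda m: (m.chromosome, m.start, m.transcript_id))
    with open(path, "w") as fh:
        for m in models:
            sizes = ",".join(str(e - s) for s, e in m.exons) + ","
            starts = ",".join(str(s - m.start) for s, e in m.exons) + ","
            fh.write("\t".join([
                m.chromosome, str(m.start), str(m.end), m.transcript_id, "0",
                m.strand, str(m.start), str(m.end), "0",
                str(len(m.exons)), sizes, starts,
            ]) + "\n")
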