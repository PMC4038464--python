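"""Synthetic study generator.

Produces every input the analysis pipeline consumes, with recorded ground
truth: a toy multi-exon reference (FASTA + GTF), single-end 100 bp liver
RNA-seq reads for a five-sample design (two untreated controls, two paired
ethanol-treated samples, one transgenic sample), oil-red-O stained field
images with dark-red droplets and pale-blue nuclei, and qPCR / steatosis
incidence tables. Every artifact is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .config import SimulationConfig
from .sequence import decode, encode, revcomp_codes

SAMPLES = ("ctrl_1", "ctrl_2", "etoh_1", "etoh_2", "tg_1")
CONDITIONS = ("control", "control", "ethanol", "ethanol", "transgenic")
PAIRS = ("1", "2", "1", "2", "")


class SizingError(ValueError):
    """Requested gene models cannot be packed into the chromosomes."""


class PlacementError(RuntimeError):
    """Could not place non-overlapping image objects within bounded retries."""


def sample_metadata() -> pd.DataFrame:
    """The fixed five-sample design with condition labels and pairing keys."""
    return pd.DataFrame(
        {"condition": CONDITIONS, "pair": PAIRS},
        index=pd.Index(SAMPLES, name="sample"),
    )


@dataclass
class ReadSet:
    """Simulated reads for one sample, as integer base codes."""

    ids: list[str]
    codes: np.ndarray  # (n_reads, read_length) uint8, A=0 C=1 G=2 T=3 N=4

    def __len__(self) -> int:
        return len(self.ids)

    def sequences(self) -> list[str]:
        return [decode(row) for row in self.codes]


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must recover."""

    true_expression: pd.DataFrame | None = None
    metadata: pd.DataFrame | None = None
    upr_genes: set[str] = field(default_factory=set)
    noise_genes: set[str] = field(default_factory=set)
    # per sample: dict with 'transcript_idx', 'offset', 'strand' arrays;
    # transcript_idx indexes into `transcripts`
    read_origins: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    transcripts: list[str] = field(default_factory=list)
    excluded_transcripts: list[str] = field(default_factory=list)
    droplets: list[dict] = field(default_factory=list)  # cy, cx, radius, area
    nuclei: int | None = None
    nucleus_centers: list[tuple[int, int]] = field(default_factory=list)


# -- reference ---------------------------------------------------------------


def make_reference(config: SimulationConfig) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Random genome and non-overlapping multi-exon gene models.

    Genes are laid out left to right with random intergenic gaps; a
    :class:`SizingError` is raised when the requested genes cannot fit.
    """
    rng = np.random.default_rng([config.seed, 1])
    genes_per_chrom = np.full(config.n_chromosomes, config.n_genes // config.n_chromosomes)
    genes_per_chrom[: config.n_genes % config.n_chromosomes] += 1

    genome: dict[str, str] = {}
    models: list[TranscriptModel] = []
    gene_no = 0
    for ci in range(config.n_chromosomes):
        chrom = f"chr{ci + 1}"
        cursor = 0
        for _ in range(genes_per_chrom[ci]):
            cursor += int(rng.integers(config.intergenic_gap[0], config.intergenic_gap[1] + 1))
            n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            exons = []
            pos = cursor
            for ei in range(n_exons):
                if ei > 0:
                    pos += int(rng.integers(config.intron_length[0], config.intron_length[1] + 1))
                elen = int(rng.integers(config.exon_length[0], config.exon_length[1] + 1))
                exons.append((pos, pos + elen))
                pos += elen
            if pos > config.chrom_length:
                raise SizingError(
                    f"gene {gene_no + 1} would end at {pos} > chrom_length "
                    f"{config.chrom_length}; reduce n_genes or gene sizes"
                )
            gene_no += 1
            gid = f"gene{gene_no:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(TranscriptModel(
                gene_id=gid, transcript_id=f"{gid}.t1", chromosome=chrom,
                strand=strand, exons=tuple(exons),
            ))
            cursor = pos
        seq_codes = rng.integers(0, 4, size=config.chrom_length, dtype=np.uint8)
        genome[chrom] = decode(seq_codes)
    return genome, models


# -- expression and reads ----------------------------------------------------


def simulate_true_expression(config: SimulationConfig,
                             gene_ids: list[str]) -> GroundTruth:
    """Log-normal baseline with near-zero noise genes and induced UPR genes.

    UPR genes carry the configured natural-log fold induction in the two
    ethanol samples and the transgenic sample; noise genes sit in a
    low-expression cluster that creates the noise peak the differential
    expression step estimates.
    """
    rng = np.random.default_rng([config.seed, 2])
    n = len(gene_ids)
    n_upr = int(round(config.upr_gene_fraction * n))
    n_noise = int(round(config.noise_gene_fraction * n))
    perm = rng.permutation(n)
    upr_idx = perm[:n_upr]
    noise_idx = perm[n_upr:n_upr + n_noise]

    baseline = np.exp(rng.normal(config.baseline_meanlog, config.baseline_sdlog, size=n))
    baseline[noise_idx] = np.exp(rng.normal(config.noise_meanlog, config.noise_sdlog,
                                            size=n_noise))
    expr = np.tile(baseline[:, None], (1, len(SAMPLES)))
    induced_samples = [i for i, c in enumerate(CONDITIONS) if c != "control"]
    for si in induced_samples:
        expr[upr_idx, si] *= np.exp(config.upr_ln_fold)

    frame = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene"),
                         columns=list(SAMPLES))
    return GroundTruth(
        true_expression=frame,
        metadata=sample_metadata(),
        upr_genes={gene_ids[i] for i in upr_idx},
        noise_genes={gene_ids[i] for i in noise_idx},
    )


def simulate_reads(genome: dict[str, str],
                   models: list[TranscriptModel],
                   true_expression: pd.DataFrame,
                   config: SimulationConfig) -> tuple[dict[str, ReadSet], GroundTruth]:
    """Draw error-free (or uniformly perturbed) reads from spliced transcripts.

    Per sample the read count is Poisson(depth); reads are assigned to genes
    proportionally to true expression, start uniformly over valid spliced
    positions, and are reverse-complemented with probability 0.5 (the library
    is treated as unstranded). Transcripts shorter than the read length are
    excluded and recorded in the truth.
    """
    rng = np.random.default_rng([config.seed, 3])
    L = config.read_length
    by_gene = {m.gene_id: m for m in models}
    truth = GroundTruth(true_expression=true_expression, metadata=sample_metadata())

    usable: list[TranscriptModel] = []
    for gid in true_expression.index:
        m = by_gene[gid]
        if m.spliced_length < L:
            truth.excluded_transcripts.append(m.transcript_id)
        else:
            usable.append(m)
    truth.transcripts = [m.transcript_id for m in usable]

    # concatenated spliced transcript codes for fast slicing
    spliced = [encode(m.spliced_sequence(genome[m.chromosome])) for m in usable]
    lengths = np.array([len(s) for s in spliced])
    starts = np.concatenate([[0], np.cumsum(lengths)[:-1]])
    concat = np.concatenate(spliced) if spliced else np.empty(0, np.uint8)

    reads: dict[str, ReadSet] = {}
    for si, sample in enumerate(SAMPLES):
        weights = true_expression.loc[[m.gene_id for m in usable], sample].to_numpy(float)
        total = weights.sum()
        n_reads = int(rng.poisson(config.depth))
        if total <= 0 or n_reads == 0:
            counts = np.zeros(len(usable), dtype=np.int64)
        else:
            counts = rng.multinomial(n_reads, weights / total)
        t_idx = np.repeat(np.arange(len(usable)), counts)
        max_off = lengths[t_idx] - L
        offsets = (rng.random(len(t_idx)) * (max_off + 1)).astype(np.int64)
        sense = rng.random(len(t_idx)) < 0.5

        idx = starts[t_idx][:, None] + offsets[:, None] + np.arange(L)[None, :]
        codes = concat[idx] if len(t_idx) else np.empty((0, L), np.uint8)
        if len(t_idx):
            codes[~sense] = revcomp_codes(codes[~sense])
        if config.sequencing_error_rate > 0 and len(t_idx):
            err = rng.random(codes.shape) < config.sequencing_error_rate
            shift = rng.integers(1, 4, size=codes.shape, dtype=np.uint8)
            codes[err] = (codes[err] + shift[err]) % 4

        ids = [f"{sample}:r{i:06d}" for i in range(len(t_idx))]
        reads[sample] = ReadSet(ids=ids, codes=codes)
        truth.read_origins[sample] = {
            "transcript_idx": t_idx,
            "offset": offsets,
            "strand": np.where(sense, "+", "-"),
        }
    return reads, truth


# -- stained-field images ----------------------------------------------------

_DROPLET_RGB = (150, 40, 60)    # dark red: low green -> high droplet signal
_NUCLEUS_RGB = (140, 205, 235)  # pale blue-cyan: blue-dominant, green ~ background
_BG_BASE = 215.0


def _disk_pixels(cy: float, cx: float, r: float, size: int):
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    yy, xx = np.mgrid[max(y0, 0):min(y1, size), max(x0, 0):min(x1, size)]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2
    return yy[inside], xx[inside]


def simulate_field_image(config: SimulationConfig,
                         field_index: int = 0) -> tuple[np.ndarray, GroundTruth]:
    """One RGB stained field: red droplets and blue nuclei on a gradient.

    Droplet disks are placed by rejection sampling so they never touch each
    other or a nucleus (overlap would make the count ambiguous against
    truth); the recorded droplet area is the exact rasterised pixel count.
    """
    rng = np.random.default_rng([config.seed, 1000 + field_index])
    size = config.field_size
    n_drop = int(rng.integers(config.droplet_count[0], config.droplet_count[1] + 1))
    n_nuc = int(rng.integers(config.nucleus_count[0], config.nucleus_count[1] + 1))

    theta = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    ramp = (np.cos(theta) * xx + np.sin(theta) * yy) / max(size - 1, 1)
    bg = _BG_BASE + config.background_gradient_amplitude * (ramp - ramp.mean())
    bg = bg + rng.normal(0, config.background_noise_sd, size=(size, size))

    img = np.clip(np.stack([bg, bg, bg], axis=-1), 0, 255).astype(np.uint8)

    placed: list[tuple[float, float, float]] = []  # cy, cx, effective radius

    def place(radius: float, margin: float, max_tries: int = 400):
        # integer centers: rasterised disks then have exact, reproducible
        # pixel areas (radius 1 -> the 5-pixel plus shape)
        for _ in range(max_tries):
            cy = int(rng.integers(int(np.ceil(margin)), size - int(np.ceil(margin))))
            cx = int(rng.integers(int(np.ceil(margin)), size - int(np.ceil(margin))))
            if all((cy - py) ** 2 + (cx - px) ** 2 > (radius + pr + 3.0) ** 2
                   for py, px, pr in placed):
                placed.append((cy, cx, radius))
                return cy, cx
        raise PlacementError(
            f"could not place object of radius {radius:.1f} without overlap; "
            "reduce counts or radii"
        )

    truth = GroundTruth()
    for _ in range(n_nuc):
        r = rng.uniform(*config.nucleus_radius)
        cy, cx = place(r, margin=r + 2)
        ys, xs = _disk_pixels(cy, cx, r, size)
        img[ys, xs] = _NUCLEUS_RGB
        truth.nucleus_centers.append((cy, cx))
    truth.nuclei = n_nuc

    for _ in range(n_drop):
        r = rng.uniform(*config.droplet_radius)
        cy, cx = place(r, margin=r + 2)
        ys, xs = _disk_pixels(cy, cx, r, size)
        img[ys, xs] = _DROPLET_RGB
        truth.droplets.append({
            "cy": float(cy), "cx": float(cx), "radius": float(r),
            "area": int(len(ys)),
        })
    return img, truth


# -- assay tables ------------------------------------------------------------


def simulate_assay_tables(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """qPCR Ct table and binary steatosis incidence table.

    Ct values are true cycle numbers plus Gaussian noise; the configured
    fold change is encoded as a -log2(fold) shift of the case samples' gene
    Ct. Incidence counts are Binomial(group size, group probability).
    """
    rng = np.random.default_rng([config.seed, 4])
    rows = []
    ct_ref = 20.0
    for gi in range(config.ct_n_genes):
        gene = f"qgene{gi + 1}"
        base_ct = float(rng.uniform(24, 28))
        for group, shift in (("control", 0.0), ("case", -np.log2(config.ct_true_fold))):
            for si in range(config.ct_group_size):
                rows.append({
                    "sample": f"{group}_{si + 1}",
                    "group": group,
                    "gene": gene,
                    "ct_gene": base_ct + shift + float(rng.normal(0, config.ct_noise_sd)),
                    "ct_ref": ct_ref + float(rng.normal(0, config.ct_noise_sd)),
                })
    ct_table = pd.DataFrame(rows)

    labels = ("control", "ethanol")
    inc_rows = []
    for label, p, n in zip(labels, config.incidence_probabilities,
                           config.incidence_group_sizes):
        pos = int(rng.binomial(n, p))
        inc_rows.append({"group": label, "positive": pos, "negative": n - pos})
    incidence = pd.DataFrame(inc_rows)
    return ct_table, incidence


# -- writers -----------------------------------------------------------------


def write_fasta(genome: dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fastq(reads: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for rid, row in zip(reads.ids, reads.codes):
            seq = decode(row)
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path) -> ReadSet:
    from Bio import SeqIO
    ids, codes = [], []
    for rec in SeqIO.parse(str(path), "fastq"):
        ids.append(rec.id)
        codes.append(encode(str(rec.seq).upper()))
    return ReadSet(ids=ids, codes=np.array(codes, dtype=np.uint8)
                   if codes else np.empty((0, 0), np.uint8))


def write_png(image: np.ndarray, path) -> None:
    from PIL import Image
    Image.fromarray(image, mode="RGB").save(str(path), format="PNG")


def read_png(path) -> np.ndarray:
    from PIL import Image
    return np.asarray(Image.open(str(path)).convert("RGB"))
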