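"""Configuration for the synthetic study generator.

A single :class:`SimulationConfig` pins every tunable of the synthetic
study — reference geometry, expression model, sequencing depth, stained-field
image parameters and assay-table parameters — so that any generated artifact
is a pure function of ``(config, seed)``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic zebrafish-liver study.

    The defaults describe the toy scale the test suite runs at: one 400 kb
    chromosome carrying 200 non-overlapping multi-exon genes, five liver
    samples (two untreated controls, two paired ethanol-treated samples and
    one transgenic sample) sequenced to 100,000 single-end 100 bp reads
    each, plus oil-red-O stained fields and qPCR/steatosis-scoring tables.
    A 5% UPR gene fraction keeps responders a small minority of the
    expression mass (as in a real transcriptome), and the 30% noise-gene
    fraction forms the low-expression peak the noise estimator keys on.
    """

    seed: int = 0

    # --- reference geometry ---
    n_chromosomes: int = 1
    chrom_length: int = 400_000
    n_genes: int = 200
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 300)
    intergenic_gap: tuple[int, int] = (50, 300)

    # --- expression model ---
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 1.0
    noise_meanlog: float = 1.8
    noise_sdlog: float = 0.4
    upr_gene_fraction: float = 0.05
    upr_ln_fold: float = 1.0
    noise_gene_fraction: float = 0.3

    # --- sequencing ---
    read_length: int = 100
    depth: int = 100_000
    sequencing_error_rate: float = 0.0

    # --- mapper geometry (used to validate read_length) ---
    part_length: int = 32
    trim: int = 2

    # --- stained-field images ---
    field_size: int = 256
    droplet_count: tuple[int, int] = (8, 20)
    droplet_radius: tuple[float, float] = (2.0, 5.0)
    nucleus_count: tuple[int, int] = (3, 8)
    nucleus_radius: tuple[float, float] = (5.0, 8.0)
    background_gradient_amplitude: float = 25.0
    background_noise_sd: float = 2.0

    # --- assay tables ---
    ct_noise_sd: float = 0.25
    ct_true_fold: float = 4.0
    ct_n_genes: int = 4
    ct_group_size: int = 6
    incidence_probabilities: tuple[float, float] = (0.13, 0.53)
    incidence_group_sizes: tuple[int, int] = (100, 100)

    def __post_init__(self) -> None:
        if self.read_length < 3 * self.part_length + 2 * self.trim:
            raise ValueError(
                f"read_length ({self.read_length}) must be >= "
                f"3*part_length + 2*trim = {3 * self.part_length + 2 * self.trim}"
            )
        for name in ("exons_per_gene", "exon_length", "intron_length",
                     "intergenic_gap", "droplet_count", "droplet_radius",
                     "nucleus_count", "nucleus_radius"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: lower bound {lo} exceeds upper bound {hi}")
        if self.exon_length[0] < 1:
            raise ValueError("exon lengths must be >= 1")
        for name in ("upr_gene_fraction", "noise_gene_fraction",
                     "sequencing_error_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        for p in self.incidence_probabilities:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"incidence probability {p} outside [0, 1]")
        if self.upr_gene_fraction + self.noise_gene_fraction > 1.0:
            raise ValueError("upr_gene_fraction + noise_gene_fraction exceed 1")
        if min(self.incidence_group_sizes) < 1 or self.ct_group_size < 1:
            raise ValueError("group sizes must be >= 1")
        if self.n_chromosomes < 1 or self.n_genes < 1 or self.chrom_length < 1:
            raise ValueError("counts and lengths must be positive")

    # -- serialisation ------------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for f in fields(cls):
            if f.name in raw and isinstance(raw[f.name], list):
                raw[f.name] = tuple(raw[f.name])
        return cls(**raw)

    def replace(self, **kwargs) -> "SimulationConfig":
        data = asdict(self)
        data.update(kwargs)
        for f in fields(self):
            if isinstance(data[f.name], list):
                data[f.name] = tuple(data[f.name])
        return SimulationConfig(**data)
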