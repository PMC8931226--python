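"""Core record types for the phosphonate trait-cycling pipeline.

Coordinates are 0-based, half-open throughout the library; the GFF3
boundary in :mod:`phoscycle.io` converts to/from the 1-based inclusive
convention of the format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Controlled vocabulary of gene-family labels. ``pepM`` marks the
#: phosphoenolpyruvate mutase biosynthesis biomarker; ``ppd``/``pdh``/``mpnS``
#: are downstream biosynthesis genes; ``phn*`` are catabolic families;
#: ``pglC``/``pglL``/``wzx`` are glycosylation/export genes found near
#: biosynthesis cassettes; ``marker01``..``marker10`` are the single-copy
#: normalization families; ``other`` is background.
GENE_FAMILIES = frozenset(
    {
        "pepM",
        "ppd",
        "pdh",
        "mpnS",
        "phnG",
        "phnH",
        "phnI",
        "phnJ",
        "phnK",
        "phnL",
        "phnM",
        "phnW",
        "phnX",
        "phnY",
        "phnZ",
        "pglC",
        "pglL",
        "wzx",
        "other",
    }
    | {f"marker{i:02d}" for i in range(1, 11)}
)

#: The ten single-copy families used for per-genome normalization of
#: metagenome read counts.
MARKER_FAMILIES = tuple(f"marker{i:02d}" for i in range(1, 11))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class GeneFeature:
    """One protein-coding feature on a contig (0-based half-open)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    family: str
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid coordinates [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.family not in GENE_FAMILIES:
            raise ValueError(f"{self.gene_id}: unknown family {self.family!r}")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GenomeRecord:
    """One (possibly incomplete) genome assembly: the unit of trait calling.

    ``completeness`` is the estimated recovered fraction of the true genome
    (the ``c`` of the corrected-prevalence formula); ``assembly_length`` is
    the realized assembly size in bp (the ``g``).
    """

    genome_id: str
    clade: str
    contigs: list[tuple[str, int]]
    genes: list[GeneFeature]
    completeness: float
    assembly_length: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.completeness <= 1.0):
            raise ValueError(
                f"{self.genome_id}: completeness {self.completeness} not in (0, 1]"
            )
        total = sum(length for _, length in self.contigs)
        if self.assembly_length == 0:
            self.assembly_length = total
        elif self.assembly_length != total:
            raise ValueError(
                f"{self.genome_id}: assembly_length {self.assembly_length} "
                f"!= sum of contig lengths {total}"
            )
        lengths = dict(self.contigs)
        for gene in self.genes:
            if gene.contig_id not in lengths:
                raise ValueError(
                    f"{self.genome_id}: gene {gene.gene_id} on unknown contig "
                    f"{gene.contig_id}"
                )
            if gene.end > lengths[gene.contig_id]:
                raise ValueError(
                    f"{self.genome_id}: gene {gene.gene_id} exceeds contig bounds"
                )

    def genes_by_family(self, family: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.family == family]


@dataclass
class HitRecord:
    """Best homology hit of a query (gene or read) to a family."""

    query_id: str
    family: str
    score: float
    above_cutoff: bool

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"{self.query_id}: non-finite score")


@dataclass
class TraitCall:
    """Per-genome producer/consumer verdict with pathway evidence.

    ``operon_length_bp`` is the gap-inclusive span of the biosynthesis
    cassette (the ``p`` of the corrected-prevalence formula); zero for
    non-producers.
    """

    genome_id: str
    is_producer: bool = False
    pepm_genes: list[tuple[str, bool]] = field(default_factory=list)
    adjacent_biosynthesis: set[str] = field(default_factory=set)
    is_consumer: bool = False
    pathways: set[str] = field(default_factory=set)
    operon_length_bp: int = 0
    cross_contig_cassette: bool = False
    clade: str = ""

    @property
    def dual_trait(self) -> bool:
        return self.is_producer and self.is_consumer


@dataclass
class Spectrum:
    """A 1-D NMR spectrum: chemical shift (ppm) vs intensity.

    The ppm axis is normalized to strictly ascending order on
    construction; descending input (the instrument convention) is
    reversed together with the intensities.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D arrays of equal length")
        d = np.diff(self.ppm)
        if np.all(d < 0):
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")
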