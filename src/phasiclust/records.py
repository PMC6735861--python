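"""Core record types shared across the pipeline.

All genomic coordinates inside the package are 0-based half-open (BED
convention). GFF3 input/output converts 1-based inclusive coordinates at the
boundary; nothing else in the package ever sees 1-based positions.
"""
from __future__ import annotations

from dataclasses import dataclass, field

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One genome placement of a small-RNA read.

    Parameters
    ----------
    chrom, start, length, strand
        Placement of the read; ``start`` is 0-based, the read occupies
        ``[start, start + length)``.
    mismatches
        Edit distance of the alignment (SAM ``NM`` tag; 0 if absent).
    n_placements
        Number of reported genome placements of this read (SAM ``NH`` tag;
        1 if absent). Quantification may weight each placement by
        ``1 / n_placements``.
    seq
        Optional read sequence (needed only for exon–exon-junction template
        matching; genome placement alone suffices everywhere else).
    """

    chrom: str
    start: int
    length: int
    strand: str
    mismatches: int = 0
    n_placements: int = 1
    seq: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.n_placements < 1:
            raise ValueError("n_placements must be >= 1")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")

    @property
    def end(self) -> int:
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' end (strand-aware)."""
        return self.start if self.strand == "+" else self.start + self.length - 1

    @property
    def weight(self) -> float:
        return 1.0 / self.n_placements


@dataclass
class SampleLibrary:
    """One sequencing library: a collection of aligned reads plus metadata.

    ``genotype`` is ``WT``, ``rdr1`` or ``rdr2``; ``serotype`` is the
    surface-antigen expression state the culture was grown in (A/B/D/H in the
    study design this package emulates).
    """

    sample_id: str
    reads: list[AlignedRead]
    serotype: str = ""
    genotype: str = "WT"
    replicate: int = 1

    @property
    def total_aligned(self) -> int:
        return len(self.reads)

    def with_reads(self, reads) -> "SampleLibrary":
        """Copy of this library holding a different read collection."""
        return SampleLibrary(
            sample_id=self.sample_id,
            reads=list(reads),
            serotype=self.serotype,
            genotype=self.genotype,
            replicate=self.replicate,
        )


@dataclass(frozen=True)
class GeneModel:
    """Gene with exon structure; introns are the gaps between exons.

    Exons are 0-based half-open intervals, normalised to sorted order at
    construction; overlapping exons are rejected.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = tuple(sorted((int(s), int(e)) for s, e in self.exons))
        for s, e in exons:
            if e <= s:
                raise ValueError(f"empty exon [{s},{e}) in {self.gene_id}")
        for (s0, e0), (s1, e1) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in {self.gene_id}")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def introns(self) -> tuple:
        """Gaps between consecutive exons, 0-based half-open."""
        return tuple(
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        )


@dataclass
class SRC:
    """A siRNA-producing cluster: a genomic interval with aligned sRNA mass."""

    src_id: str
    chrom: str
    start: int
    end: int
    n_alignments: int
    source_samples: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"SRC {self.src_id}: end must exceed start")
        self.source_samples = frozenset(self.source_samples)

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def interval(self):
        return (self.start, self.end)


@dataclass(frozen=True)
class GeneSRCLink:
    """One gene–SRC overlap with the boundary-rule verdict applied to it."""

    gene_id: str
    src_id: str
    overlap_bp: int
    gene_frac: float
    src_frac: float
    action: str  # 'trim' | 'retain' | 'discard'


@dataclass(frozen=True)
class PhasingWindow:
    """One evaluated phasing window (fixed width, best register reported)."""

    chrom: str
    start: int
    width: int
    register: int
    phased_abundance: float
    unphased_abundance: float
    occupied_plus: int
    occupied_minus: int
    n_reads: int
    p_score: float

    @property
    def k(self) -> int:
        """Occupied phased positions, both strands pooled."""
        return self.occupied_plus + self.occupied_minus

    @property
    def end(self) -> int:
        return self.start + self.width


@dataclass
class PhasedRegion:
    """A merged run of passing phasing windows."""

    chrom: str
    start: int
    end: int
    best_p_score: float
    n_windows: int
    src_ids: tuple = ()


@dataclass(frozen=True)
class JunctionQuant:
    """Per-gene sRNA mass at exon–exon junctions versus introns."""

    gene_id: str
    eej_count: float
    intron_count: float
    n_eej: int
    n_introns: int
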