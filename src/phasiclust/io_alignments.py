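"""Reading, filtering and downsampling of alignments and annotations.

Small-RNA alignments come in as SAM/BAM (via pysam) or as a simplified
BED6-like table; gene annotations come in as GFF3 (via gffutils). Everything
is converted to the package's internal records with 0-based half-open
coordinates at this boundary.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import gffutils
import numpy as np
import pysam

from .records import AlignedRead, GeneModel, SampleLibrary

#: read lengths accepted at parse time; narrower analysis filters come later
PARSE_MIN_LEN = 15
PARSE_MAX_LEN = 35


def load_alignments(
    path,
    sample_id: str | None = None,
    serotype: str = "",
    genotype: str = "WT",
    replicate: int = 1,
    keep_sequences: bool = False,
) -> SampleLibrary:
    """Load a SAM/BAM file (or BED6-like table) into a :class:`SampleLibrary`.

    Mapped records become :class:`AlignedRead`; unmapped records are skipped.
    Mismatch counts come from the ``NM`` tag (0 if absent) and placement
    counts from ``NH`` (1 if absent). A BED6 path (``.bed``/``.tsv``) is read
    as chrom/start/end/name/score/strand with the name column ignored.
    """
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    if path.suffix.lower() in (".bed", ".tsv", ".txt"):
        reads = _load_bed_like(path)
    else:
        reads = _load_sam(path, keep_sequences=keep_sequences)
    if not reads:
        warnings.warn(f"no mapped reads in {path}", stacklevel=2)
    return SampleLibrary(
        sample_id=sample_id,
        reads=reads,
        serotype=serotype,
        genotype=genotype,
        replicate=replicate,
    )


def _load_sam(path: Path, keep_sequences: bool = False) -> list:
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            try:
                length = rec.query_length or rec.infer_query_length() or 0
                if not (PARSE_MIN_LEN <= length <= PARSE_MAX_LEN):
                    continue
                seq = None
                if keep_sequences and rec.query_sequence:
                    seq = rec.query_sequence
                reads.append(
                    AlignedRead(
                        chrom=rec.reference_name,
                        start=rec.reference_start,
                        length=length,
                        strand="-" if rec.is_reverse else "+",
                        mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                        n_placements=int(rec.get_tag("NH")) if rec.has_tag("NH") else 1,
                        seq=seq,
                    )
                )
            except (ValueError, TypeError) as exc:  # malformed record
                raise ValueError(f"malformed SAM record #{i} in {path}: {exc}") from exc
    return reads


def _load_bed_like(path: Path) -> list:
    reads = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"malformed BED record at line {i + 1} of {path}")
            try:
                chrom, start, end, _name, _score, strand = parts[:6]
                start, end = int(start), int(end)
                length = end - start
                if not (PARSE_MIN_LEN <= length <= PARSE_MAX_LEN):
                    continue
                reads.append(
                    AlignedRead(chrom=chrom, start=start, length=length, strand=strand)
                )
            except ValueError as exc:
                raise ValueError(
                    f"malformed BED record at line {i + 1} of {path}: {exc}"
                ) from exc
    return reads


def filter_reads(
    lib: SampleLibrary,
    min_len: int = 21,
    max_len: int = 25,
    max_mismatch: int = 0,
    max_placements: int = 100,
) -> SampleLibrary:
    """Apply the study's read-retention rules.

    Reads shorter than 21 nt are treated as likely degradation products and
    removed; only error-free alignments are kept by default, and heavily
    multi-mapping reads (more than ``max_placements`` placements) are
    discarded. Idempotent.
    """
    if min_len > max_len:
        raise ValueError(f"min_len ({min_len}) exceeds max_len ({max_len})")
    kept = [
        r
        for r in lib.reads
        if min_len <= r.length <= max_len
        and r.mismatches <= max_mismatch
        and r.n_placements <= max_placements
    ]
    return lib.with_reads(kept)


def downsample(libs: list, seed: int) -> list:
    """Downsample every library to the size of the smallest one.

    Sampling is uniform without replacement and deterministic for a fixed
    seed; a library already at the minimum size is returned unchanged. This
    makes cluster and phasing calls comparable across sequencing runs.
    """
    for lib in libs:
        if lib.total_aligned == 0:
            raise ValueError(f"library {lib.sample_id!r} is empty; cannot downsample")
    target = min(lib.total_aligned for lib in libs)
    rng = np.random.default_rng(seed)
    out = []
    for lib in libs:
        if lib.total_aligned == target:
            out.append(lib)
            continue
        idx = np.sort(rng.choice(lib.total_aligned, size=target, replace=False))
        out.append(lib.with_reads([lib.reads[i] for i in idx]))
    return out


def load_annotation(gff3_path) -> list:
    """Load gene models from GFF3 (gene + exon features).

    GFF3 1-based inclusive coordinates are converted to 0-based half-open;
    exons are sorted and introns derived per gene. An exon lying outside its
    gene span is an error.
    """
    db = gffutils.create_db(
        str(gff3_path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for gene in db.features_of_type("gene"):
        gene_start, gene_end = gene.start - 1, gene.end
        exons = []
        for exon in db.children(gene, featuretype="exon"):
            s, e = exon.start - 1, exon.end
            if s < gene_start or e > gene_end:
                raise ValueError(
                    f"exon [{exon.start},{exon.end}] outside gene span of {gene.id}"
                )
            exons.append((s, e))
        if not exons:
            exons = [(gene_start, gene_end)]
        genes.append(
            GeneModel(gene_id=gene.id, chrom=gene.seqid, strand=gene.strand, exons=tuple(exons))
        )
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def write_gff3(genes: list, path) -> None:
    """Write gene models as GFF3 (gene/mRNA/exon rows, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            base = f"{g.chrom}\tphasiclust\t"
            tail = f"\t.\t{g.strand}\t."
            fh.write(
                base + f"gene\t{g.start + 1}\t{g.end}" + tail + f"\tID={g.gene_id}\n"
            )
            fh.write(
                base
                + f"mRNA\t{g.start + 1}\t{g.end}"
                + tail
                + f"\tID={g.gene_id}.t1;Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    base
                    + f"exon\t{s + 1}\t{e}"
                    + tail
                    + f"\tID={g.gene_id}.e{i};Parent={g.gene_id}.t1\n"
                )
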