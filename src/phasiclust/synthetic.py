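"""Synthetic genomes, libraries and expression tables with planted structure.

Every downstream stage of the pipeline is testable against data generated
here, with the statistical structure the analysis assumes: 21–25 nt reads
with a 23-nt mode, clusters of 100–1000 bp, phased clusters with 23-nt
registers on both strands (2-nt Dicer overhang between strands), per-sample
abundance multipliers emulating serotype-specific accumulation, and
RDR-mutant siRNA depletion coupled to mRNA derepression.

The generator is deterministic for a fixed seed, down to byte-identical
fixture files.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .io_alignments import write_gff3
from .records import AlignedRead, GeneModel, SampleLibrary

DEFAULT_CYCLE = 23
#: default read-length distribution: unimodal with the 23-nt mode observed
#: for Dicer products in *Paramecium*
DEFAULT_LENGTH_DIST = {21: 0.08, 22: 0.17, 23: 0.50, 24: 0.17, 25: 0.08}
MIN_INTERGENIC = 200
MIN_EXON = 60
MIN_INTRON = 20


@dataclass
class SimClusterSpec:
    """One planted siRNA-producing locus.

    ``register_offset`` fixes the phase register relative to the locus start;
    ``n_cycles`` sets the locus length (``n_cycles * 23`` bp);
    ``mean_reads`` is the expected read count per sample before multipliers;
    ``per_sample_multiplier`` keys may be sample ids or serotypes (sample id
    wins; missing keys default to 1; 0 silences the locus in that sample);
    ``mutant_depletion`` is the fraction of reads removed in non-WT samples.
    """

    locus_id: str
    chrom: str
    start: int
    gene_linked: bool = False
    phased: bool = False
    register_offset: int = 0
    n_cycles: int = 5
    mean_reads: float = 60.0
    sense_fraction: float = 0.5
    per_sample_multiplier: dict = field(default_factory=dict)
    mutant_depletion: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.register_offset < DEFAULT_CYCLE):
            raise ValueError("register_offset must be in [0, 22]")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.phased and self.n_cycles < 3:
            raise ValueError(
                "phased loci need n_cycles >= 3 so the >=3-phased-bins rule can fire"
            )
        if not (0.0 <= self.sense_fraction <= 1.0):
            raise ValueError("sense_fraction must be in [0, 1]")
        if not (0.0 <= self.mutant_depletion <= 1.0):
            raise ValueError("mutant_depletion must be in [0, 1]")
        if self.mean_reads <= 0:
            raise ValueError("mean_reads must be positive")
        if any(v < 0 for v in self.per_sample_multiplier.values()):
            raise ValueError("per_sample_multiplier values must be >= 0")

    @property
    def length(self) -> int:
        return self.n_cycles * DEFAULT_CYCLE

    @property
    def end(self) -> int:
        return self.start + self.length

    def multiplier(self, sample: "SimSampleSpec") -> float:
        if sample.sample_id in self.per_sample_multiplier:
            return self.per_sample_multiplier[sample.sample_id]
        return self.per_sample_multiplier.get(sample.serotype, 1.0)


@dataclass
class SimSampleSpec:
    """One simulated sequencing library (serotype, genotype, replicate)."""

    sample_id: str
    serotype: str = "A"
    genotype: str = "WT"
    replicate: int = 1
    total_reads: int = 0  # informative only; actual totals are Poisson sums
    length_distribution: dict = field(default_factory=lambda: dict(DEFAULT_LENGTH_DIST))
    background_rate: float = 0.5  # degradation-like noise reads per kb
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genotype not in ("WT", "rdr1", "rdr2"):
            raise ValueError(f"unknown genotype {self.genotype!r}")
        total = sum(self.length_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("length_distribution must sum to 1")
        if any(not (21 <= k <= 25) for k in self.length_distribution):
            raise ValueError("length_distribution keys must be 21-25")


def simulate_genome(
    n_chroms: int,
    chrom_length: int,
    n_genes: int,
    exons_per_gene: int,
    seed: int,
    max_exon: int = 200,
    max_intron: int = 40,
) -> tuple:
    """Random genome plus non-overlapping gene models.

    Genes are distributed round-robin over chromosomes with >= 200 bp
    intergenic gaps; exons are >= 60 bp and introns >= 20 bp (the tiny
    introns typical of a streamlined ciliate macronuclear genome). Strands
    are assigned at random. Deterministic for a fixed seed. Raises if the
    genes cannot be packed under the spacing constraint.
    """
    rng = np.random.default_rng(seed)
    genome = {
        f"chr{i + 1}": "".join(rng.choice(list("ACGT"), size=chrom_length))
        for i in range(n_chroms)
    }
    per_chrom = [n_genes // n_chroms + (1 if i < n_genes % n_chroms else 0) for i in range(n_chroms)]
    genes = []
    gene_no = 0
    for ci, chrom in enumerate(sorted(genome)):
        k = per_chrom[ci]
        if k == 0:
            continue
        lengths = []
        structures = []
        for _ in range(k):
            exon_lens = rng.integers(MIN_EXON, max_exon + 1, size=exons_per_gene)
            intron_lens = (
                rng.integers(MIN_INTRON, max_intron + 1, size=exons_per_gene - 1)
                if exons_per_gene > 1
                else np.array([], dtype=int)
            )
            structures.append((exon_lens, intron_lens))
            lengths.append(int(exon_lens.sum() + intron_lens.sum()))
        needed = sum(lengths) + (k + 1) * MIN_INTERGENIC
        if needed > chrom_length:
            raise ValueError(
                f"cannot place {k} genes on {chrom} ({chrom_length} bp): "
                f"{needed} bp needed with >= {MIN_INTERGENIC} bp intergenic gaps"
            )
        slack = chrom_length - needed
        extra = rng.multinomial(slack, np.ones(k + 1) / (k + 1))
        pos = MIN_INTERGENIC + int(extra[0])
        for gi in range(k):
            exon_lens, intron_lens = structures[gi]
            exons = []
            p = pos
            for j, el in enumerate(exon_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if j < len(intron_lens):
                    p += int(intron_lens[j])
            gene_no += 1
            genes.append(
                GeneModel(
                    gene_id=f"G{gene_no:04d}",
                    chrom=chrom,
                    strand="+" if rng.random() < 0.5 else "-",
                    exons=tuple(exons),
                )
            )
            pos = p + MIN_INTERGENIC + int(extra[gi + 1])
    return genome, genes


def _draw_lengths(rng, dist: dict, n: int) -> np.ndarray:
    keys = np.array(sorted(dist))
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(keys, size=n, p=probs)


def simulate_reads(
    genome: dict,
    genes: list,
    cluster_specs: list,
    sample: SimSampleSpec,
    overhang: int = 2,
) -> list:
    """Simulate one library of aligned reads.

    Phased loci place plus-strand 5' ends on ``start + 23*c + offset`` and
    minus-strand 5' ends on the same grid shifted by the Dicer overhang
    (default +2 nt); unphased loci draw 5' ends uniformly over the locus.
    Read counts are Poisson(mean_reads x multiplier), thinned by
    ``mutant_depletion`` in non-WT samples; background reads are scattered
    genome-wide at ``background_rate`` per kb. All reads are error-free
    single placements. Deterministic for the sample's seed.
    """
    rng = np.random.default_rng(sample.seed)
    chrom_lens = {c: len(s) for c, s in genome.items()}
    reads: list[AlignedRead] = []
    for spec in cluster_specs:
        if spec.chrom not in chrom_lens:
            raise ValueError(f"locus {spec.locus_id}: unknown chromosome {spec.chrom}")
        if spec.start < 0 or spec.end > chrom_lens[spec.chrom]:
            raise ValueError(f"locus {spec.locus_id} outside genome bounds")
        sense_strand = "+"
        if spec.gene_linked:
            host = next(
                (
                    g
                    for g in genes
                    if g.chrom == spec.chrom and g.start <= spec.start and spec.end <= g.end
                ),
                None,
            )
            if host is None:
                raise ValueError(
                    f"gene_linked locus {spec.locus_id} lies in no gene body"
                )
            sense_strand = host.strand
        n = rng.poisson(spec.mean_reads * spec.multiplier(sample))
        if sample.genotype != "WT" and spec.mutant_depletion > 0 and n > 0:
            n = rng.binomial(n, 1.0 - spec.mutant_depletion)
        if n == 0:
            continue
        on_sense = rng.random(n) < spec.sense_fraction
        if spec.phased:
            cycles = rng.integers(0, spec.n_cycles, size=n)
            grid = spec.start + DEFAULT_CYCLE * cycles + spec.register_offset
            for i in range(n):
                strand = sense_strand if on_sense[i] else ("-" if sense_strand == "+" else "+")
                if strand == "+":
                    fp = int(grid[i])
                    start = fp
                else:
                    fp = int(grid[i]) + overhang
                    start = fp - DEFAULT_CYCLE + 1
                reads.append(
                    AlignedRead(chrom=spec.chrom, start=start, length=DEFAULT_CYCLE, strand=strand)
                )
        else:
            lengths = _draw_lengths(rng, sample.length_distribution, n)
            fps = rng.integers(spec.start, spec.end, size=n)
            for i in range(n):
                strand = sense_strand if on_sense[i] else ("-" if sense_strand == "+" else "+")
                L = int(lengths[i])
                start = int(fps[i]) if strand == "+" else int(fps[i]) - L + 1
                start = max(start, 0)
                reads.append(AlignedRead(chrom=spec.chrom, start=start, length=L, strand=strand))

    genome_kb = sum(chrom_lens.values()) / 1e3
    n_bg = rng.poisson(sample.background_rate * genome_kb)
    if n_bg > 0:
        chroms = sorted(chrom_lens)
        probs = np.array([chrom_lens[c] for c in chroms], dtype=float)
        probs /= probs.sum()
        picks = rng.choice(len(chroms), size=n_bg, p=probs)
        lengths = _draw_lengths(rng, sample.length_distribution, n_bg)
        for i in range(n_bg):
            chrom = chroms[picks[i]]
            L = int(lengths[i])
            start = int(rng.integers(0, max(chrom_lens[chrom] - L, 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(AlignedRead(chrom=chrom, start=start, length=L, strand=strand))
    return reads


def simulate_junction_reads(
    genome: dict,
    gene: GeneModel,
    n: int,
    seed: int,
    length: int = 23,
    flank: int = 18,
) -> list:
    """Mature-mRNA-derived reads spanning the gene's exon-exon junctions.

    Each read's *sequence* is a substring of the spliced junction template
    (last ``flank`` nt of the upstream exon + first ``flank`` nt of the
    downstream exon) crossing the splice point; its genome *placement* is put
    entirely inside the upstream exon, so it never overlaps an intron. Such
    reads exercise the junction-template matching path.
    """
    if gene.n_exons < 2:
        raise ValueError("gene has no exon-exon junction")
    rng = np.random.default_rng(seed)
    seq = genome[gene.chrom]
    reads = []
    junctions = list(zip(gene.exons, gene.exons[1:]))
    for i in range(n):
        (up_s, up_e), (dn_s, dn_e) = junctions[int(rng.integers(0, len(junctions)))]
        f_up = min(flank, up_e - up_s)
        f_dn = min(flank, dn_e - dn_s)
        template = (seq[up_e - f_up : up_e] + seq[dn_s : dn_s + f_dn]).upper()
        # offset chosen so the read crosses the splice point (at f_up)
        lo = max(0, f_up - length + 1)
        hi = min(f_up - 1, len(template) - length)
        off = int(rng.integers(lo, hi + 1))
        placement = max(up_s, up_e - length)
        reads.append(
            AlignedRead(
                chrom=gene.chrom,
                start=placement,
                length=length,
                strand="+",
                seq=template[off : off + length],
            )
        )
    return reads


def simulate_expression(
    genes: list,
    samples: list,
    cluster_specs: list,
    seed: int,
    base_log_mean: float = 4.0,
    base_log_sigma: float = 1.0,
    serotype_sigma: float = 0.3,
    replicate_sigma: float = 0.1,
    derepression: float = 1.5,
) -> pd.DataFrame:
    """Gene x sample mRNA TPM table for simulated samples.

    Per gene: a lognormal baseline, scaled by a per-serotype lognormal factor
    and replicate-level lognormal noise. Genes hosting a phased cluster with
    ``mutant_depletion > 0`` get their TPM multiplied by ``derepression`` in
    non-WT samples, emulating the loss of cis-acting silencing when the
    siRNAs disappear.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    baseline = np.exp(rng.normal(base_log_mean, base_log_sigma, size=len(genes)))
    serotypes = sorted({s.serotype for s in samples})
    sero_factor = {
        st: np.exp(rng.normal(0.0, serotype_sigma, size=len(genes))) for st in serotypes
    }
    derepressed = set()
    for spec in cluster_specs:
        if spec.phased and spec.gene_linked and spec.mutant_depletion > 0:
            for g in genes:
                if g.chrom == spec.chrom and g.start <= spec.start and spec.end <= g.end:
                    derepressed.add(g.gene_id)
    cols = {}
    for s in samples:
        vals = baseline * sero_factor[s.serotype]
        vals = vals * np.exp(rng.normal(0.0, replicate_sigma, size=len(genes)))
        if s.genotype != "WT":
            mask = np.array([g in derepressed for g in gene_ids])
            vals = np.where(mask, vals * derepression, vals)
        cols[s.sample_id] = vals
    df = pd.DataFrame(cols, index=pd.Index(gene_ids, name="gene_id"))
    return df


def simulate_contrast_counts(
    n_phased: int = 50,
    n_unphased: int = 50,
    depletion: float = 0.6,
    derepression: float = 1.5,
    n_reps: int = 3,
    mean_count: float = 200.0,
    seed: int = 0,
) -> dict:
    """Count-level mutant-contrast experiment with planted effects.

    sRNA counts per locus are Poisson around a lognormal per-locus baseline;
    phased loci lose ``depletion`` of their siRNA mass in mutant samples
    while their genes gain ``derepression``-fold mRNA. Returns a dict with
    ``srna_counts`` (locus x sample), ``mrna_tpm`` (gene x sample),
    ``phased`` flags and the WT/mutant sample name lists.
    """
    rng = np.random.default_rng(seed)
    n = n_phased + n_unphased
    loci = [f"L{i:04d}" for i in range(n)]
    genes = [f"G{i:04d}" for i in range(n)]
    phased = pd.Series([i < n_phased for i in range(n)], index=loci)
    base = np.exp(rng.normal(np.log(mean_count), 0.5, size=n))
    wt_cols = [f"WT_{r + 1}" for r in range(n_reps)]
    mut_cols = [f"MUT_{r + 1}" for r in range(n_reps)]
    srna = {}
    for c in wt_cols:
        srna[c] = rng.poisson(base)
    mut_mean = np.where(phased.to_numpy(), base * (1.0 - depletion), base)
    for c in mut_cols:
        srna[c] = rng.poisson(mut_mean)
    srna_counts = pd.DataFrame(srna, index=pd.Index(loci, name="src_id"))

    mrna_base = np.exp(rng.normal(np.log(100.0), 0.5, size=n))
    mrna = {}
    for c in wt_cols:
        mrna[c] = mrna_base * np.exp(rng.normal(0.0, 0.15, size=n))
    mut_mrna = np.where(phased.to_numpy(), mrna_base * derepression, mrna_base)
    for c in mut_cols:
        mrna[c] = mut_mrna * np.exp(rng.normal(0.0, 0.15, size=n))
    mrna_tpm = pd.DataFrame(mrna, index=pd.Index(genes, name="gene_id"))
    return {
        "srna_counts": srna_counts,
        "mrna_tpm": mrna_tpm,
        "phased": phased,
        "wt_samples": wt_cols,
        "mutant_samples": mut_cols,
    }


def write_fixtures(
    genome: dict,
    genes: list,
    reads_by_sample: dict,
    out_dir,
    expression: pd.DataFrame | None = None,
) -> dict:
    """Write FASTA + GFF3 + one SAM per sample (+ optional expression TSV).

    Fixture files are byte-identical for identical inputs; they round-trip
    through :mod:`phasiclust.io_alignments` losslessly (same read multiset).
    Returns the paths written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    fasta = out_dir / "genome.fa"
    records = [
        SeqRecord(Seq(genome[c]), id=c, description="") for c in sorted(genome)
    ]
    SeqIO.write(records, str(fasta), "fasta")
    paths["fasta"] = fasta

    gff3 = out_dir / "genes.gff3"
    write_gff3(genes, gff3)
    paths["gff3"] = gff3

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": len(genome[c])} for c in sorted(genome)],
        }
    )
    paths["sam"] = {}
    for sample_id in sorted(reads_by_sample):
        sam = out_dir / f"{sample_id}.sam"
        reads = sorted(
            reads_by_sample[sample_id], key=lambda r: (r.chrom, r.start, r.strand, r.length)
        )
        with pysam.AlignmentFile(str(sam), "w", header=header) as fh:
            for i, r in enumerate(reads):
                a = pysam.AlignedSegment(header)
                a.query_name = f"{sample_id}.r{i + 1}"
                a.flag = 16 if r.strand == "-" else 0
                a.reference_id = header.get_tid(r.chrom)
                a.reference_start = r.start
                a.mapping_quality = 255
                a.cigartuples = [(0, r.length)]
                a.query_sequence = (
                    r.seq if r.seq is not None else genome[r.chrom][r.start : r.end].upper()
                )
                a.set_tags([("NM", r.mismatches, "i"), ("NH", r.n_placements, "i")])
                fh.write(a)
        paths["sam"][sample_id] = sam

    if expression is not None:
        tsv = out_dir / "expression.tsv"
        expression.sort_index().to_csv(tsv, sep="\t")
        paths["expression"] = tsv
    return paths


def study_design(seed: int = 0) -> dict:
    """The default emulated study: genome, genes, loci and samples.

    Mirrors the experimental design the pipeline targets: four WT serotypes
    (A, B, D, H) with two sRNA replicates each for cluster definition, plus
    rdr1/rdr2 mutants (two replicates, serotype A). Planted loci include
    universal phased gene-linked clusters (depleted in mutants), universal
    unphased clusters, and serotype-private clusters.
    """
    genome, genes = simulate_genome(
        n_chroms=2, chrom_length=50_000, n_genes=24, exons_per_gene=3, seed=seed,
        max_exon=400,
    )
    rng = np.random.default_rng(seed + 1)
    hosts = [g for g in genes if g.length >= 6 * DEFAULT_CYCLE]
    if len(hosts) < 16:
        raise ValueError("study design needs >= 16 host genes; re-seed")
    specs: list[SimClusterSpec] = []
    li = 0

    def _partial_start(g, n_cycles):
        return g.start + int(rng.integers(0, g.length - n_cycles * DEFAULT_CYCLE + 1))

    for g in hosts[:6]:  # universal phased clusters along the whole gene body
        li += 1
        nc = g.length // DEFAULT_CYCLE
        specs.append(
            SimClusterSpec(
                locus_id=f"P{li:03d}",
                chrom=g.chrom,
                start=g.start,
                gene_linked=True,
                phased=True,
                register_offset=int(rng.integers(0, DEFAULT_CYCLE)),
                n_cycles=nc,
                mean_reads=6.0 * nc,
                sense_fraction=0.5,
                mutant_depletion=0.6,
            )
        )
    for g in hosts[6:12]:  # universal unphased gene clusters, partial coverage
        li += 1
        # cover 15-45% of the gene so the 10/80 retain rule keeps the pair
        nc = max(5, int(rng.uniform(0.15, 0.45) * g.length / DEFAULT_CYCLE))
        specs.append(
            SimClusterSpec(
                locus_id=f"U{li:03d}",
                chrom=g.chrom,
                start=_partial_start(g, nc),
                gene_linked=True,
                phased=False,
                n_cycles=nc,
                mean_reads=80.0,
                sense_fraction=float(rng.uniform(0.3, 0.7)),
            )
        )
    # serotype-private unphased gene clusters (one per serotype)
    for st, g in zip("ABDH", hosts[12:16]):
        li += 1
        nc = int(rng.integers(5, 9))
        specs.append(
            SimClusterSpec(
                locus_id=f"S{li:03d}",
                chrom=g.chrom,
                start=_partial_start(g, nc),
                gene_linked=True,
                phased=False,
                n_cycles=nc,
                mean_reads=60.0,
                sense_fraction=0.5,
                per_sample_multiplier={x: (1.0 if x == st else 0.0) for x in "ABDH"},
            )
        )
    # two intergenic unphased clusters
    for chrom, start in ((sorted(genome)[0], 40), (sorted(genome)[1], 60)):
        li += 1
        specs.append(
            SimClusterSpec(
                locus_id=f"I{li:03d}",
                chrom=chrom,
                start=start,
                phased=False,
                n_cycles=6,
                mean_reads=50.0,
                sense_fraction=0.5,
            )
        )

    samples = []
    for st in "ABDH":
        for rep in (1, 2):
            samples.append(
                SimSampleSpec(
                    sample_id=f"{st}_wt_{rep}",
                    serotype=st,
                    genotype="WT",
                    replicate=rep,
                    seed=seed * 1000 + ord(st) * 10 + rep,
                )
            )
    for gt in ("rdr1", "rdr2"):
        for rep in (1, 2):
            samples.append(
                SimSampleSpec(
                    sample_id=f"A_{gt}_{rep}",
                    serotype="A",
                    genotype=gt,
                    replicate=rep,
                    seed=seed * 1000 + {"rdr1": 901, "rdr2": 911}[gt] + rep,
                )
            )
    return {"genome": genome, "genes": genes, "cluster_specs": specs, "samples": samples}


def simulate_study(out_dir, seed: int = 0) -> dict:
    """Generate and write the full default study; returns design + paths."""
    design = study_design(seed)
    reads = {
        s.sample_id: simulate_reads(
            design["genome"], design["genes"], design["cluster_specs"], s
        )
        for s in design["samples"]
    }
    expression = simulate_expression(
        design["genes"], design["samples"], design["cluster_specs"], seed=seed + 2
    )
    paths = write_fixtures(
        design["genome"], design["genes"], reads, out_dir, expression=expression
    )
    design["reads"] = reads
    design["expression"] = expression
    design["paths"] = paths
    return design
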