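"""Quantification and normalisation of small-RNA mass in intervals.

Two per-sample abundance measures are computed for each SRC:

* ``scaled_count`` — a per-million scaled count,
  ``raw * 1e6 / (total_aligned - exclusion_counts)``, where
  ``exclusion_counts`` removes reads attributable to exogenous (feeding)
  constructs before the scale factor is formed (0 for endogenous-only runs);
* ``tpm`` — a length-normalised per-million measure,
  ``(raw/len_kb) * 1e6 / sum_j (raw_j/len_j_kb)``, which sums to 1e6 per
  sample and feeds the "> 1 TPM" serotype-specific threshold.

Multi-mapping placements are weighted ``1/n_placements`` by default; an
unweighted mode counts every retained placement with weight 1.
"""
from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .records import AlignedRead, GeneModel, JunctionQuant, SampleLibrary

DICER_LENGTHS = range(21, 26)


def count_in_intervals(lib: SampleLibrary, intervals, weighted: bool = True) -> np.ndarray:
    """Count read placements per interval (overlap >= 1 bp).

    ``intervals`` is a sequence of objects with ``chrom``/``start``/``end``
    (e.g. :class:`~phasiclust.records.SRC`) or ``(chrom, start, end)``
    tuples; counts are returned in input order. A placement overlapping two
    intervals counts in both.
    """
    norm = [_as_interval(iv) for iv in intervals]
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for idx, (chrom, start, end) in enumerate(norm):
        trees[chrom].addi(start, end, idx)
    counts = np.zeros(len(norm))
    for r in lib.reads:
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        w = r.weight if weighted else 1.0
        for hit in tree.overlap(r.start, r.end):
            counts[hit.data] += w
    return counts


def _as_interval(iv):
    if hasattr(iv, "chrom"):
        return (iv.chrom, iv.start, iv.end)
    chrom, start, end = iv
    return (chrom, int(start), int(end))


def normalize_tpm(
    counts,
    lengths,
    total_aligned: float | None = None,
    exclusion_counts: float = 0.0,
) -> tuple:
    """Compute (scaled_count, tpm) arrays from raw counts and bp lengths.

    ``scaled_count`` needs ``total_aligned`` (library size); if omitted, the
    sum of counts is used. Raises if ``total_aligned <= exclusion_counts``.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    if counts.shape != lengths.shape:
        raise ValueError("counts and lengths must align")
    if np.any(lengths <= 0):
        raise ValueError("interval lengths must be positive")
    if total_aligned is None:
        total_aligned = float(counts.sum())
    if total_aligned <= exclusion_counts:
        raise ValueError(
            f"total aligned ({total_aligned}) must exceed exclusion counts "
            f"({exclusion_counts})"
        )
    scaled = counts * 1e6 / (total_aligned - exclusion_counts)
    rate = counts / (lengths / 1e3)
    denom = rate.sum()
    tpm = rate * 1e6 / denom if denom > 0 else np.zeros_like(rate)
    return scaled, tpm


def length_histogram(lib: SampleLibrary, interval, weighted: bool = True) -> Counter:
    """(length, strand) -> weighted count for reads overlapping an interval."""
    chrom, start, end = _as_interval(interval)
    hist: Counter = Counter()
    for r in lib.reads:
        if r.chrom == chrom and r.start < end and r.end > start:
            hist[(r.length, r.strand)] += r.weight if weighted else 1.0
    return hist


def dicer_call(length_hist, dominance: float = 0.8):
    """Predominant read length of a cluster, or ``'N'`` if none dominates.

    ``length_hist`` maps lengths (or ``(length, strand)`` keys) to counts
    over 21–25 nt. Returns the modal length when its mass is at least
    ``dominance`` of the total and the mode is unique; ties and empty
    histograms give ``'N'``. Invariant to uniform scaling of the histogram.
    """
    pooled: Counter = Counter()
    for key, n in dict(length_hist).items():
        length = key[0] if isinstance(key, tuple) else key
        if length not in DICER_LENGTHS:
            raise ValueError(f"length {length} outside 21-25 nt")
        pooled[int(length)] += n
    total = sum(pooled.values())
    if total <= 0:
        return "N"
    best = max(pooled.values())
    modes = [ln for ln, n in pooled.items() if n == best]
    if len(modes) > 1 or best < dominance * total:
        return "N"
    return modes[0]


def strand_counts(lib: SampleLibrary, interval, weighted: bool = True) -> tuple:
    """(sense, antisense) weighted counts relative to the + strand."""
    hist = length_histogram(lib, interval, weighted=weighted)
    sense = sum(n for (_, strand), n in hist.items() if strand == "+")
    anti = sum(n for (_, strand), n in hist.items() if strand == "-")
    return sense, anti


def quantify_clusters(
    lib: SampleLibrary,
    srcs,
    weighted: bool = True,
    exclusion_counts: float = 0.0,
) -> pd.DataFrame:
    """Full per-SRC quantification table for one sample.

    Columns: src_id, sample_id, raw_count, scaled_count, tpm, dicer_call,
    sense_count, antisense_count.
    """
    counts = count_in_intervals(lib, srcs, weighted=weighted)
    lengths = [s.end - s.start for s in srcs]
    scaled, tpm = normalize_tpm(
        counts, lengths, total_aligned=lib.total_aligned, exclusion_counts=exclusion_counts
    )
    rows = []
    for src, raw, sc, t in zip(srcs, counts, scaled, tpm):
        hist = length_histogram(lib, src, weighted=weighted)
        sense = sum(n for (_, st), n in hist.items() if st == "+")
        anti = sum(n for (_, st), n in hist.items() if st == "-")
        rows.append(
            {
                "src_id": src.src_id,
                "sample_id": lib.sample_id,
                "raw_count": raw,
                "scaled_count": sc,
                "tpm": t,
                "dicer_call": dicer_call(hist) if hist else "N",
                "sense_count": sense,
                "antisense_count": anti,
            }
        )
    return pd.DataFrame(rows)


def serotype_specific(tpm: pd.Series, threshold_tpm: float = 1.0) -> pd.Index:
    """SRCs expressed in this sample: TPM strictly greater than threshold."""
    tpm = pd.Series(tpm)
    return tpm.index[tpm > threshold_tpm]


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def quantify_eej_intron(
    lib: SampleLibrary,
    genes,
    genome: dict | None = None,
    flank: int = 18,
    mode: str = "template",
    weighted: bool = True,
) -> dict:
    """Quantify sRNA mass at exon–exon junctions (EEJ) versus introns.

    An EEJ reference is the last ``flank`` nt of the upstream exon
    concatenated with the first ``flank`` nt of the downstream exon (36 nt at
    the default). In ``template`` mode a read is assigned to the junction iff
    its sequence (or reverse complement) matches the template end-to-end with
    0 mismatches while spanning the splice point by >= 1 nt on each side —
    the signature of a mature-mRNA-derived small RNA, since a contiguous
    genome alignment cannot cross an intron. ``genomic`` mode instead counts
    reads overlapping the 2*flank genomic window around each splice site.
    Intron counts are genome-placement overlaps with intron intervals.

    Exons shorter than ``flank`` truncate the flank with a warning. Returns
    ``{gene_id: JunctionQuant}``.
    """
    import warnings

    if mode not in ("template", "genomic"):
        raise ValueError(f"unknown EEJ mode {mode!r}")
    if mode == "template" and genome is None:
        raise ValueError("template mode requires genome sequences")

    out: dict[str, JunctionQuant] = {}
    reads_by_chrom: dict[str, list] = defaultdict(list)
    for r in lib.reads:
        reads_by_chrom[r.chrom].append(r)

    for g in genes:
        n_eej = max(g.n_exons - 1, 0)
        introns = g.introns
        intron_count = 0.0
        for (istart, iend) in introns:
            for r in reads_by_chrom.get(g.chrom, ()):
                if r.start < iend and r.end > istart:
                    intron_count += r.weight if weighted else 1.0
        eej_count = 0.0
        if n_eej > 0:
            for (up_s, up_e), (dn_s, dn_e) in zip(g.exons, g.exons[1:]):
                f_up = min(flank, up_e - up_s)
                f_dn = min(flank, dn_e - dn_s)
                if f_up < flank or f_dn < flank:
                    warnings.warn(
                        f"{g.gene_id}: exon shorter than flank {flank}; truncated",
                        stacklevel=2,
                    )
                if mode == "genomic":
                    for r in reads_by_chrom.get(g.chrom, ()):
                        if r.start < up_e + f_dn and r.end > up_e - f_up:
                            eej_count += r.weight if weighted else 1.0
                    continue
                seq = genome[g.chrom]
                template = seq[up_e - f_up : up_e] + seq[dn_s : dn_s + f_dn]
                template = template.upper()
                eej_count += _match_junction_reads(
                    lib.reads, template, f_up, weighted=weighted
                )
        out[g.gene_id] = JunctionQuant(
            gene_id=g.gene_id,
            eej_count=eej_count,
            intron_count=intron_count,
            n_eej=n_eej,
            n_introns=len(introns),
        )
    return out


def _match_junction_reads(reads, template: str, junction_pos: int, weighted: bool) -> float:
    total = 0.0
    for r in reads:
        if r.seq is None:
            continue
        for s in (r.seq.upper(), _revcomp(r.seq.upper())):
            pos = template.find(s)
            matched = False
            while pos != -1:
                # must cover the splice point by >= 1 nt on each side
                if pos < junction_pos and pos + len(s) > junction_pos:
                    total += r.weight if weighted else 1.0
                    matched = True
                    break
                pos = template.find(s, pos + 1)
            if matched:
                break
    return total
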