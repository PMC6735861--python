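"""Shared fixtures and brute-force oracles for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from phasiclust.records import AlignedRead, SampleLibrary


def make_read(chrom="chr1", start=0, length=23, strand="+", mismatches=0, n_placements=1, seq=None):
    return AlignedRead(
        chrom=chrom,
        start=start,
        length=length,
        strand=strand,
        mismatches=mismatches,
        n_placements=n_placements,
        seq=seq,
    )


def make_library(reads, sample_id="s1", **kw):
    return SampleLibrary(sample_id=sample_id, reads=list(reads), **kw)


def random_library(rng, n_reads, chrom_len=10_000, sample_id="s1"):
    """Small random library for oracle-equivalence testing."""
    reads = []
    for _ in range(n_reads):
        length = int(rng.integers(21, 26))
        start = int(rng.integers(0, chrom_len - length))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(make_read(start=start, length=length, strand=strand))
    return make_library(reads, sample_id=sample_id)


def brute_force_clusters(reads, mincov, pad, chrom_len=20_000):
    """Per-base-coverage oracle for cluster calling.

    Scan coverage for islands, merge islands separated by < pad uncovered
    bases, count reads overlapping each merged region, keep regions with
    >= mincov alignments, report the span of their reads.
    """
    cov = np.zeros(chrom_len, dtype=int)
    for r in reads:
        cov[r.start : r.end] += 1
    covered = cov > 0
    islands = []
    i = 0
    while i < chrom_len:
        if covered[i]:
            j = i
            while j < chrom_len and covered[j]:
                j += 1
            islands.append([i, j])
            i = j
        else:
            i += 1
    merged = []
    for s, e in islands:
        if merged and s - merged[-1][1] < pad:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    out = []
    for s, e in merged:
        inside = [r for r in reads if r.start < e and r.end > s]
        if len(inside) >= mincov:
            out.append(
                (min(r.start for r in inside), max(r.end for r in inside), len(inside))
            )
    return out


@pytest.fixture(scope="session")
def toy_genome_genes():
    from phasiclust.synthetic import simulate_genome

    return simulate_genome(1, 100_000, 20, 3, seed=7)


@pytest.fixture(scope="session")
def study(tmp_path_factory):
    """The default synthetic study, written once per session."""
    from phasiclust.synthetic import simulate_study

    out = tmp_path_factory.mktemp("study")
    return simulate_study(out, seed=11)
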