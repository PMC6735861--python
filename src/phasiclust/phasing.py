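"""Phased-siRNA detection with the phase-score (P-score) statistic.

Phasing is the signature of processive Dicer cleavage along one dsRNA
precursor: read 5' ends recur every cycle length (23 nt, the predominant
siRNA length in *Paramecium*). Detection slides a window of 11 cycles
(253 bp at the default) over the genome; within a window each of the 23
possible registers partitions positions into one phased bin per cycle and 22
off-register bins. For the best register the score

    P-score = (k - 2) * ln(1 + 10 * P / (1 + U))      (0 when k <= 2)

is computed, where P is the read abundance in phased bins, U the abundance
everywhere else in the window, and k the number of distinct occupied phased
positions pooled over both strands (11 per strand, 22 possible). Minus-strand
reads participate through a configurable Dicer-overhang offset (default 2 nt)
so that the two strands of one duplex fall in the same register.

A window is called phased iff its score exceeds ``min_score`` AND each strand
occupies at least ``min_bins_per_strand`` distinct phased positions AND the
window holds at least ``min_reads`` reads in total. Passing windows are
merged into phased regions when separated by less than ``merge_dist`` bp.
"""
from __future__ import annotations

import math
from collections import defaultdict

import numpy as np

from .records import AlignedRead, PhasedRegion, PhasingWindow, SampleLibrary

DEFAULT_CYCLE = 23
DEFAULT_N_CYCLES = 11


def p_score(P: float, U: float, k: int) -> float:
    """The phase score for one window/register.

    Strictly increasing in ``P`` and ``k`` and strictly decreasing in ``U``
    (for k >= 3); identically 0 for k <= 2, because fewer than three occupied
    cycles carry no evidence of periodicity.
    """
    if P < 0 or U < 0:
        raise ValueError("abundances must be non-negative")
    if k < 0:
        raise ValueError("k must be non-negative")
    if k <= 2:
        return 0.0
    return (k - 2) * math.log1p(10.0 * P / (1.0 + U))


def phase_coordinate(
    read: AlignedRead,
    window_start: int,
    minus_offset: int = 2,
    width: int = DEFAULT_CYCLE * DEFAULT_N_CYCLES,
) -> int:
    """Position of a read's 5' end within a window, overhang-corrected.

    Plus-strand reads map to ``5'pos - window_start``; minus-strand reads to
    ``(5'pos - window_start - minus_offset) mod width``, so the two strands
    of one Dicer duplex share a register. The read's 5' end must lie inside
    the window.
    """
    fp = read.five_prime
    if not (window_start <= fp < window_start + width):
        raise ValueError(
            f"read 5' position {fp} outside window [{window_start}, "
            f"{window_start + width})"
        )
    if read.strand == "+":
        return fp - window_start
    return (fp - window_start - minus_offset) % width


def phase_position(
    read: AlignedRead,
    window_start: int,
    register: int,
    minus_offset: int = 2,
    cycle: int = DEFAULT_CYCLE,
    n_cycles: int = DEFAULT_N_CYCLES,
) -> tuple:
    """(cycle index, in_register) of a read for one register of a window."""
    coord = phase_coordinate(read, window_start, minus_offset, cycle * n_cycles)
    return coord // cycle, coord % cycle == register


def evaluate_window(
    reads,
    window_start: int,
    chrom: str,
    minus_offset: int = 2,
    cycle: int = DEFAULT_CYCLE,
    n_cycles: int = DEFAULT_N_CYCLES,
    weighted: bool = False,
) -> PhasingWindow:
    """Score one window: best register over all ``cycle`` registers.

    ``reads`` must all have 5' ends inside the window. Ties between registers
    break toward the smaller register index.
    """
    width = cycle * n_cycles
    coords_plus, w_plus, coords_minus, w_minus = [], [], [], []
    for r in reads:
        coord = phase_coordinate(r, window_start, minus_offset, width)
        if r.strand == "+":
            coords_plus.append(coord)
            w_plus.append(r.weight if weighted else 1.0)
        else:
            coords_minus.append(coord)
            w_minus.append(r.weight if weighted else 1.0)

    cp = np.asarray(coords_plus, dtype=int)
    cm = np.asarray(coords_minus, dtype=int)
    wp = np.asarray(w_plus)
    wm = np.asarray(w_minus)
    total = float(wp.sum() + wm.sum())

    # per-register abundance of 5' ends, pooled over strands
    reg_mass = np.zeros(cycle)
    if cp.size:
        reg_mass += np.bincount(cp % cycle, weights=wp, minlength=cycle)
    if cm.size:
        reg_mass += np.bincount(cm % cycle, weights=wm, minlength=cycle)
    # distinct occupied phased positions per register, per strand
    occ_plus = np.zeros(cycle, dtype=int)
    occ_minus = np.zeros(cycle, dtype=int)
    if cp.size:
        occ_plus = np.bincount(np.unique(cp) % cycle, minlength=cycle)
    if cm.size:
        occ_minus = np.bincount(np.unique(cm) % cycle, minlength=cycle)

    best = None
    for r in range(cycle):
        P = float(reg_mass[r])
        U = total - P
        k = int(occ_plus[r] + occ_minus[r])
        score = p_score(P, U, k)
        if best is None or score > best.p_score:
            best = PhasingWindow(
                chrom=chrom,
                start=window_start,
                width=width,
                register=r,
                phased_abundance=P,
                unphased_abundance=U,
                occupied_plus=int(occ_plus[r]),
                occupied_minus=int(occ_minus[r]),
                n_reads=len(reads),
                p_score=score,
            )
    return best


def detect_phased(
    lib: SampleLibrary,
    min_score: float = 10.0,
    min_bins_per_strand: int = 3,
    min_reads: int = 20,
    merge_dist: int = 100,
    minus_offset: int = 2,
    cycle: int = DEFAULT_CYCLE,
    n_cycles: int = DEFAULT_N_CYCLES,
    weighted: bool = False,
    anchors: str = "reads",
    srcs=None,
) -> list:
    """Detect phased regions in one (filtered, downsampled) library.

    Windows are anchored at every genomic position holding a read 5' end
    (``anchors='dense'`` scans every base between the first and last 5' end
    instead — same pass/fail set, far more windows). A window passes iff its
    best-register P-score exceeds ``min_score``, each strand occupies at
    least ``min_bins_per_strand`` distinct phased positions, and the window
    holds at least ``min_reads`` reads. Passing windows merge into
    :class:`PhasedRegion` when separated by less than ``merge_dist`` bp; the
    best score per region is kept. If ``srcs`` is given, each region records
    the SRC ids it overlaps.
    """
    if anchors not in ("reads", "dense"):
        raise ValueError(f"unknown anchors mode {anchors!r}")
    width = cycle * n_cycles
    by_chrom: dict[str, list] = defaultdict(list)
    for r in lib.reads:
        by_chrom[r.chrom].append(r)

    regions: list[PhasedRegion] = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda r: r.five_prime)
        fps = np.array([r.five_prime for r in reads])
        if anchors == "reads":
            starts = np.unique(fps)
        else:
            starts = np.arange(fps.min(), fps.max() + 1)
        passing: list[PhasingWindow] = []
        for w in starts:
            lo = np.searchsorted(fps, w, side="left")
            hi = np.searchsorted(fps, w + width, side="left")
            if hi - lo < min_reads:
                continue
            win = evaluate_window(
                reads[lo:hi],
                int(w),
                chrom,
                minus_offset=minus_offset,
                cycle=cycle,
                n_cycles=n_cycles,
                weighted=weighted,
            )
            if (
                win.p_score > min_score
                and win.occupied_plus >= min_bins_per_strand
                and win.occupied_minus >= min_bins_per_strand
            ):
                passing.append(win)
        regions.extend(_merge_windows(passing, merge_dist))

    if srcs is not None:
        for region in regions:
            region.src_ids = tuple(
                s.src_id
                for s in srcs
                if s.chrom == region.chrom and s.start < region.end and s.end > region.start
            )
    return regions


def _merge_windows(windows: list, merge_dist: int) -> list:
    if not windows:
        return []
    windows = sorted(windows, key=lambda w: w.start)
    regions: list[PhasedRegion] = []
    cur = PhasedRegion(
        chrom=windows[0].chrom,
        start=windows[0].start,
        end=windows[0].end,
        best_p_score=windows[0].p_score,
        n_windows=1,
    )
    for w in windows[1:]:
        if w.start - cur.end < merge_dist:
            cur.end = max(cur.end, w.end)
            cur.best_p_score = max(cur.best_p_score, w.p_score)
            cur.n_windows += 1
        else:
            regions.append(cur)
            cur = PhasedRegion(
                chrom=w.chrom, start=w.start, end=w.end, best_p_score=w.p_score, n_windows=1
            )
    regions.append(cur)
    return regions
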