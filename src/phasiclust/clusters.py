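"""SRC calling, unification, annotation and boundary modification.

The cluster model: any maximal run of genome positions covered by at least
one read seeds an island; islands closer than the padding distance are merged
into one cluster; merged clusters carrying at least ``mincov`` alignments
become SRCs. Across samples, per-sample SRC sets are unified with
mergeBed-default semantics (overlapping or book-ended intervals merge).

Boundary modification removes non-specific gene overlaps before any
gene-level analysis: per gene–SRC pair, if the gene is covered by more than
80% of its length and the SRC by at least 20%, the SRC is trimmed to the gene
boundary; if the gene is covered by at least 10% and the SRC by more than
80%, the SRC is retained unchanged; all other pairs are discarded from gene
association. An SRC overlapping no gene at all drops out of gene-level
analyses entirely.
"""
from __future__ import annotations

from collections import defaultdict

from intervaltree import IntervalTree

from .records import SRC, GeneSRCLink, SampleLibrary

GENE_COVER_TRIM = 0.8  # gene_frac strictly above this (with src_frac >= 0.2) => trim
SRC_COVER_TRIM = 0.2
GENE_COVER_RETAIN = 0.1  # gene_frac at least this (with src_frac > 0.8) => retain
SRC_COVER_RETAIN = 0.8


def call_clusters(
    lib: SampleLibrary,
    mincov: int = 20,
    pad: int = 100,
    pad_inclusive: bool = False,
    mincov_mode: str = "alignments",
) -> list:
    """Call SRCs from one (filtered, downsampled) library.

    Islands of coverage are merged when the uncovered gap between them is
    strictly smaller than ``pad`` (``pad_inclusive=True`` switches to <=);
    merged islands with at least ``mincov`` alignments are emitted, with
    coordinates spanning their reads. ``mincov_mode='depth'`` filters on the
    maximum per-base depth instead of the total alignment count.
    """
    if mincov < 1:
        raise ValueError(f"mincov must be >= 1, got {mincov}")
    if pad < 0:
        raise ValueError(f"pad must be >= 0, got {pad}")
    if mincov_mode not in ("alignments", "depth"):
        raise ValueError(f"unknown mincov_mode {mincov_mode!r}")

    by_chrom: dict[str, list] = defaultdict(list)
    for r in lib.reads:
        by_chrom[r.chrom].append(r)

    srcs: list[SRC] = []
    for chrom in sorted(by_chrom):
        reads = sorted(by_chrom[chrom], key=lambda r: (r.start, r.end))
        groups: list[list] = []
        cur: list = []
        cur_end = None
        for r in reads:
            # gap <= 0 keeps contiguous coverage in one island; gap < pad
            # implements the padding merge in the same sweep.
            if cur_end is not None:
                gap = r.start - cur_end
                merge = gap <= 0 or (gap <= pad if pad_inclusive else gap < pad)
            else:
                merge = False
            if merge:
                cur.append(r)
                cur_end = max(cur_end, r.end)
            else:
                if cur:
                    groups.append(cur)
                cur = [r]
                cur_end = r.end
        if cur:
            groups.append(cur)

        for grp in groups:
            if mincov_mode == "alignments":
                cov = len(grp)
            else:
                cov = _max_depth(grp)
            if cov < mincov:
                continue
            start = min(r.start for r in grp)
            end = max(r.end for r in grp)
            srcs.append(
                SRC(
                    src_id="",
                    chrom=chrom,
                    start=start,
                    end=end,
                    n_alignments=len(grp),
                    source_samples=frozenset({lib.sample_id}),
                )
            )
    for i, src in enumerate(srcs, start=1):
        src.src_id = f"{lib.sample_id}.SRC{i:05d}"
    return srcs


def _max_depth(reads) -> int:
    events: dict[int, int] = defaultdict(int)
    for r in reads:
        events[r.start] += 1
        events[r.end] -= 1
    depth = best = 0
    for pos in sorted(events):
        depth += events[pos]
        best = max(best, depth)
    return best


def unify_clusters(cluster_sets: list) -> list:
    """Unify per-sample SRC sets into one consistent annotation set.

    mergeBed-default semantics: overlapping *or book-ended* intervals merge
    (distance 0). ``source_samples`` is unioned and alignment counts summed.
    Idempotent, order-independent; output intervals are sorted and pairwise
    separated by at least 1 bp.
    """
    flat = [s for cs in cluster_sets for s in cs]
    flat.sort(key=lambda s: (s.chrom, s.start, s.end))
    merged: list[SRC] = []
    for s in flat:
        if merged and merged[-1].chrom == s.chrom and s.start <= merged[-1].end:
            m = merged[-1]
            m.end = max(m.end, s.end)
            m.n_alignments += s.n_alignments
            m.source_samples = m.source_samples | s.source_samples
        else:
            merged.append(
                SRC(
                    src_id="",
                    chrom=s.chrom,
                    start=s.start,
                    end=s.end,
                    n_alignments=s.n_alignments,
                    source_samples=s.source_samples,
                )
            )
    for i, src in enumerate(merged, start=1):
        src.src_id = f"SRC{i:05d}"
    return merged


def _feature_trees(features) -> dict:
    """Build per-chromosome interval trees from (chrom, start, end, id) rows."""
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for chrom, start, end, fid in features:
        if end > start:
            trees[chrom].addi(start, end, fid)
    return trees


def annotate_clusters(srcs: list, features_by_category: dict) -> dict:
    """Overlap SRCs against annotation categories with distinct counting.

    ``features_by_category`` maps a category name to an iterable of
    ``(chrom, start, end, feature_id)`` rows. Every SRC is assigned every
    category it overlaps by >= 1 bp (no precedence masking); per category the
    result is ``(distinct overlapped features, SRCs overlapping the
    category)``. SRCs overlapping nothing are reported under ``intergenic``.
    """
    trees = {cat: _feature_trees(feats) for cat, feats in features_by_category.items()}
    result: dict[str, tuple] = {}
    hit_any: set[str] = set()
    for cat in features_by_category:
        feat_ids: set = set()
        src_ids: set = set()
        for src in srcs:
            tree = trees[cat].get(src.chrom)
            if tree is None:
                continue
            hits = tree.overlap(src.start, src.end)
            if hits:
                src_ids.add(src.src_id)
                feat_ids.update(h.data for h in hits)
        result[cat] = (len(feat_ids), len(src_ids))
        hit_any |= src_ids
    n_intergenic = sum(1 for src in srcs if src.src_id not in hit_any)
    result["intergenic"] = (n_intergenic, n_intergenic)
    return result


def classify_pair(gene_frac: float, src_frac: float) -> str:
    """Boundary-rule verdict for one gene–SRC pair.

    The trim rule (gene covered > 80%, SRC covered >= 20%) takes precedence
    over the retain rule (gene covered >= 10%, SRC covered > 80%); pairs
    matching neither are discarded from gene association. Inequality
    strictness follows the stated thresholds exactly.
    """
    if gene_frac > GENE_COVER_TRIM and src_frac >= SRC_COVER_TRIM:
        return "trim"
    if gene_frac >= GENE_COVER_RETAIN and src_frac > SRC_COVER_RETAIN:
        return "retain"
    return "discard"


def adjust_boundaries(srcs: list, genes: list) -> tuple:
    """Apply the boundary-modification rules to unified SRCs.

    Returns ``(modified_srcs, links)``. One modified SRC is emitted per
    non-discard gene–SRC pair: the SRC∩gene intersection for ``trim`` pairs,
    the original interval for ``retain`` pairs. When a single SRC yields
    records for several genes its id is suffixed with the gene id, so the
    modified set can be requantified per gene association. Trimming never
    extends an interval. SRCs overlapping no gene are dropped.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    trees = _feature_trees((g.chrom, g.start, g.end, g.gene_id) for g in genes)

    links: list[GeneSRCLink] = []
    modified: list[SRC] = []
    for src in srcs:
        tree = trees.get(src.chrom)
        hits = sorted(h.data for h in tree.overlap(src.start, src.end)) if tree else []
        kept_pairs = []
        for gene_id in hits:
            g = gene_by_id[gene_id]
            ov = min(src.end, g.end) - max(src.start, g.start)
            if ov <= 0:
                continue
            gene_frac = ov / g.length
            src_frac = ov / src.length
            action = classify_pair(gene_frac, src_frac)
            links.append(
                GeneSRCLink(
                    gene_id=gene_id,
                    src_id=src.src_id,
                    overlap_bp=ov,
                    gene_frac=gene_frac,
                    src_frac=src_frac,
                    action=action,
                )
            )
            if action != "discard":
                kept_pairs.append((gene_id, g, action))
        multi = len(kept_pairs) > 1
        for gene_id, g, action in kept_pairs:
            if action == "trim":
                start = max(src.start, g.start)
                end = min(src.end, g.end)
            else:
                start, end = src.start, src.end
            new_id = f"{src.src_id}:{gene_id}" if multi else src.src_id
            modified.append(
                SRC(
                    src_id=new_id,
                    chrom=src.chrom,
                    start=start,
                    end=end,
                    n_alignments=src.n_alignments,
                    source_samples=src.source_samples,
                )
            )
    return modified, links
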