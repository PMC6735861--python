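"""Integration of SRCs with gene models, mRNA expression and mutant data.

This module defines GSRCs (genes consistently overlapped by SRCs in every
serotype), stratifies them by siRNA coverage of the gene body, correlates
per-gene sRNA accumulation with mRNA expression (Pearson +
Benjamini–Hochberg), contrasts RDR mutants against wild type with
size-factor-normalised log2 fold changes and rank-sum group tests, and
computes set-intersection and hypergeometric-enrichment summaries.
"""
from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .records import GeneModel

COVERAGE_CUTS = (46.0, 88.0)  # percent cutoffs for classes I/II/III


def define_gsrcs(links_by_serotype: dict) -> tuple:
    """Identify GSRCs: genes with >= 1 linked SRC in *every* serotype.

    ``links_by_serotype`` maps serotype -> iterable of
    :class:`~phasiclust.records.GeneSRCLink` (discard pairs are ignored).
    Returns ``(gsrc_ids, present_in)`` where ``present_in`` maps every gene
    seen in any serotype to the set of serotypes it is linked in, for
    set-intersection reporting.
    """
    if len(links_by_serotype) < 2:
        raise ValueError("need at least 2 serotypes to define GSRCs")
    present_in: dict[str, set] = defaultdict(set)
    for serotype, links in links_by_serotype.items():
        for link in links:
            if link.action != "discard":
                present_in[link.gene_id].add(serotype)
    all_serotypes = set(links_by_serotype)
    gsrcs = sorted(g for g, s in present_in.items() if s == all_serotypes)
    return gsrcs, dict(present_in)


def interval_union_length(intervals) -> int:
    """Total bp covered by a union of half-open intervals."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    total = 0
    cur_s = cur_e = None
    for s, e in ivs:
        if cur_e is None or s > cur_e:
            if cur_e is not None:
                total += cur_e - cur_s
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    if cur_e is not None:
        total += cur_e - cur_s
    return total


def coverage_class(gene: GeneModel, srcs, cuts: tuple = COVERAGE_CUTS) -> tuple:
    """Percent of the gene body covered by SRCs, and its class.

    Class I: cov <= 46 %; class II: 46 % < cov <= 88 %; class III:
    cov > 88 % (fully covered genes — the stratum where phasing
    concentrates).
    """
    lo, hi = cuts
    clipped = [
        (max(s.start, gene.start), min(s.end, gene.end))
        for s in srcs
        if s.chrom == gene.chrom
    ]
    pct = 100.0 * interval_union_length(clipped) / gene.length
    if pct <= lo:
        cls = "I"
    elif pct <= hi:
        cls = "II"
    else:
        cls = "III"
    return pct, cls


def aggregate_srna_per_gene(links, quant: pd.DataFrame, value: str = "tpm") -> pd.DataFrame:
    """Per-gene sRNA accumulation matrix from gene–SRC links.

    A gene linked to multiple SRCs gets the *sum* of their accumulation; an
    SRC linked to multiple genes contributes its full accumulation to each.
    ``quant`` is long-format with columns src_id, sample_id and ``value``.
    Returns a gene x sample DataFrame.
    """
    pairs = {(l.gene_id, l.src_id) for l in links if l.action != "discard"}
    wide = quant.pivot_table(index="src_id", columns="sample_id", values=value, fill_value=0.0)
    rows = {}
    by_gene: dict[str, list] = defaultdict(list)
    for gene_id, src_id in pairs:
        by_gene[gene_id].append(src_id)
    for gene_id, src_ids in by_gene.items():
        present = [s for s in src_ids if s in wide.index]
        if present:
            rows[gene_id] = wide.loc[present].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "gene_id"
    return out.sort_index()


def correlate(
    srna_matrix: pd.DataFrame,
    mrna_matrix: pd.DataFrame,
    alpha: float = 0.05,
    scale: str = "natural",
) -> pd.DataFrame:
    """Per-gene Pearson correlation of sRNA accumulation with mRNA expression.

    Matrices are gene x sample TPM with shared sample columns (the study
    design pairs 4 serotypes x 3 replicates = 12 samples). Two-sided p-values
    come from the t-transform with n-2 df; BH correction runs across all
    tested genes; a gene gets sign 'positive'/'negative' only at
    ``q < alpha``, else 'ns'. ``scale='log2'`` correlates log2(x+1) values.
    Zero-variance vectors are reported with ``sign='ns'`` and
    ``zero_variance=True``.
    """
    if scale not in ("natural", "log2"):
        raise ValueError(f"unknown correlation scale {scale!r}")
    samples = [c for c in srna_matrix.columns if c in set(mrna_matrix.columns)]
    if len(samples) < 3:
        raise ValueError("need >= 3 shared samples to correlate")
    genes = srna_matrix.index.intersection(mrna_matrix.index)
    rows = []
    for gene in genes:
        x = srna_matrix.loc[gene, samples].to_numpy(dtype=float)
        y = mrna_matrix.loc[gene, samples].to_numpy(dtype=float)
        if scale == "log2":
            x, y = np.log2(x + 1.0), np.log2(y + 1.0)
        zero_var = np.ptp(x) == 0 or np.ptp(y) == 0
        if zero_var:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x, y)
        rows.append(
            {
                "gene_id": gene,
                "r": r,
                "p_value": p,
                "n_samples": len(samples),
                "zero_variance": zero_var,
            }
        )
    res = pd.DataFrame(rows)
    if res.empty:
        return res.assign(q_value=[], sign=[])
    q = np.full(len(res), np.nan)
    valid = res["p_value"].notna().to_numpy()
    if valid.any():
        q[valid] = multipletests(res.loc[valid, "p_value"], method="fdr_bh")[1]
    res["q_value"] = q
    sign = np.where(
        (res["q_value"] < alpha) & (res["r"] > 0),
        "positive",
        np.where((res["q_value"] < alpha) & (res["r"] < 0), "negative", "ns"),
    )
    res["sign"] = np.where(res["zero_variance"], "ns", sign)
    return res


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (DESeq-style).

    Uses rows with all-positive counts for the geometric-mean reference;
    falls back to total-count ratios if no such row exists.
    """
    mat = counts.to_numpy(dtype=float)
    positive = (mat > 0).all(axis=1)
    if positive.any():
        logs = np.log(mat[positive])
        ref = logs.mean(axis=1, keepdims=True)
        sf = np.exp(np.median(logs - ref, axis=0))
    else:
        totals = mat.sum(axis=0)
        sf = totals / np.exp(np.mean(np.log(np.where(totals > 0, totals, 1.0))))
    return pd.Series(sf, index=counts.columns)


def mutant_contrast(
    counts: pd.DataFrame,
    wt_samples: list,
    mutant_samples: list,
    phased_flags: pd.Series,
    pseudocount: float = 1.0,
) -> tuple:
    """Per-locus log2 fold change (mutant/WT) plus phased-vs-unphased test.

    Counts are size-factor normalised (median-of-ratios over all samples),
    then per locus ``log2((mean_mut + c) / (mean_wt + c))`` with pseudocount
    ``c``. Loci with zero counts in both conditions are excluded and
    flagged. The phased and unphased fold-change distributions are compared
    with a two-sided Wilcoxon rank-sum test.

    Returns ``(per_locus_table, group_test_dict)``.
    """
    if len(wt_samples) < 2 or len(mutant_samples) < 2:
        raise ValueError("need >= 2 replicates per condition")
    sf = size_factors(counts[wt_samples + mutant_samples])
    norm = counts[wt_samples + mutant_samples].div(sf, axis=1)
    wt_mean = norm[wt_samples].mean(axis=1)
    mut_mean = norm[mutant_samples].mean(axis=1)
    all_zero = (wt_mean == 0) & (mut_mean == 0)
    lfc = np.log2((mut_mean + pseudocount) / (wt_mean + pseudocount))
    table = pd.DataFrame(
        {
            "log2fc": lfc,
            "wt_mean": wt_mean,
            "mutant_mean": mut_mean,
            "phased": phased_flags.reindex(counts.index).fillna(False).astype(bool),
            "all_zero": all_zero,
        }
    )
    usable = table[~table["all_zero"]]
    grp_p = usable.loc[usable["phased"], "log2fc"]
    grp_u = usable.loc[~usable["phased"], "log2fc"]
    if len(grp_p) and len(grp_u):
        stat, p = stats.ranksums(grp_p, grp_u)
    else:
        stat, p = np.nan, np.nan
    test = {
        "statistic": float(stat),
        "p_value": float(p),
        "median_phased": float(grp_p.median()) if len(grp_p) else np.nan,
        "median_unphased": float(grp_u.median()) if len(grp_u) else np.nan,
        "n_phased": int(len(grp_p)),
        "n_unphased": int(len(grp_u)),
    }
    return table, test


def intersections(membership: dict) -> dict:
    """UpSet-style exact intersection counts.

    ``membership`` maps item -> set of conditions; every item is counted
    once, under its full membership combination (a frozenset key). Counts
    sum to the number of items.
    """
    counts: Counter = Counter()
    for item, conds in membership.items():
        counts[frozenset(conds)] += 1
    return dict(counts)


def tag_de_groups(de_tables: dict, alpha: float = 0.05) -> pd.Series:
    """Name loci after their differential-expression membership across mutants.

    ``de_tables`` maps a mutant label ('1', '2', ...) to a DataFrame indexed
    by locus id with columns ``log2FC`` and ``padj`` (e.g. imported from an
    external differential-expression run). A locus significant at
    ``padj < alpha`` contributes ``D<label>`` (down) or ``U<label>`` (up);
    the group name concatenates its sorted memberships (``D1D2``, ``U1``,
    ...), empty for loci significant nowhere.
    """
    tags: defaultdict = defaultdict(list)
    for label in sorted(de_tables):
        table = de_tables[label]
        sig = table[table["padj"] < alpha]
        for locus, row in sig.iterrows():
            tags[locus].append(("D" if row["log2FC"] < 0 else "U") + str(label))
    all_loci = sorted({l for t in de_tables.values() for l in t.index})
    return pd.Series({l: "".join(sorted(tags.get(l, []))) for l in all_loci})


def enrichment(n_total: int, n_group: int, n_marked: int, n_marked_in_group: int) -> float:
    """One-sided hypergeometric upper-tail p for over-representation.

    Of ``n_total`` items, ``n_group`` are in the focal group (e.g. class III
    GSRCs) and ``n_marked`` carry the mark (e.g. phased); the p-value is the
    probability of drawing at least ``n_marked_in_group`` marked items when
    sampling ``n_group`` without replacement.
    """
    if not (0 <= n_group <= n_total and 0 <= n_marked <= n_total):
        raise ValueError("group/marked counts exceed total")
    if n_marked_in_group > min(n_group, n_marked) or n_marked_in_group < 0:
        raise ValueError("subset count exceeds its supersets")
    return float(stats.hypergeom.sf(n_marked_in_group - 1, n_total, n_marked, n_group))
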