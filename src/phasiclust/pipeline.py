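"""End-to-end orchestration: config validation, staged run, manifest.

The stage order is load -> filter -> merge replicates per serotype ->
downsample -> call clusters -> unify -> boundary-adjust -> quantify ->
phase -> integrate. All randomness flows from the single config seed through
per-stage derived seeds; a rerun with the same config and inputs is
bit-identical (the manifest carries no wall-clock information).
"""
from __future__ import annotations

import hashlib
import json
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .clusters import adjust_boundaries, call_clusters, unify_clusters
from .integrate import (
    aggregate_srna_per_gene,
    correlate,
    coverage_class,
    define_gsrcs,
    enrichment,
    intersections,
    mutant_contrast,
)
from .io_alignments import downsample, filter_reads, load_alignments, load_annotation
from .phasing import detect_phased
from .quantify import normalize_tpm, quantify_clusters, serotype_specific
from .records import SampleLibrary

_PHASE_DEFAULTS = {
    "min_score": 10.0,
    "min_bins": 3,
    "min_reads": 20,
    "merge": 100,
    "cycle": 23,
    "minus_offset": 2,
}
_PARAM_DEFAULTS = {
    "min_len": 21,
    "max_len": 25,
    "max_mismatch": 0,
    "max_placements": 100,
    "mincov": 20,
    "pad": 100,
    "tpm_threshold": 1.0,
    "flank": 18,
    "coverage_cuts": [46.0, 88.0],
    "alpha": 0.05,
}
_MODE_DEFAULTS = {
    "counting": "weighted",
    "tpm_variant": "length_normalized",
    "correlation_scale": "natural",
}
_TOP_KEYS = {"paths", "params", "modes", "seed", "out_dir"}
_PATH_KEYS = {"alignments", "gff3", "fasta", "mrna"}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (all parameter defaults built in)."""

    alignments: list
    gff3: str
    out_dir: str
    fasta: str | None = None
    mrna: str | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)
    phase: dict = field(default_factory=dict)
    modes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.params = {**_PARAM_DEFAULTS, **self.params}
        self.phase = {**_PHASE_DEFAULTS, **self.phase}
        self.modes = {**_MODE_DEFAULTS, **self.modes}

    @classmethod
    def from_dict(cls, cfg: dict) -> "PipelineConfig":
        errors = validate_config(cfg)
        if errors:
            raise ValueError("invalid config:\n  " + "\n  ".join(errors))
        paths = cfg["paths"]
        params = dict(cfg.get("params", {}))
        phase = params.pop("phase", {})
        return cls(
            alignments=paths["alignments"],
            gff3=paths["gff3"],
            fasta=paths.get("fasta"),
            mrna=paths.get("mrna"),
            out_dir=cfg["out_dir"],
            seed=cfg.get("seed", 0),
            params=params,
            phase=phase,
            modes=dict(cfg.get("modes", {})),
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        params = dict(self.params)
        params["phase"] = dict(self.phase)
        return {
            "paths": {
                "alignments": self.alignments,
                "gff3": self.gff3,
                "fasta": self.fasta,
                "mrna": self.mrna,
            },
            "params": params,
            "modes": dict(self.modes),
            "seed": self.seed,
            "out_dir": self.out_dir,
        }


def validate_config(cfg: dict) -> list:
    """Type/range checks for a raw config dict; returns an error list."""
    errors = []
    if not isinstance(cfg, dict):
        return ["config must be a mapping"]
    for key in cfg:
        if key not in _TOP_KEYS:
            errors.append(f"unknown top-level key {key!r}")
    paths = cfg.get("paths")
    if not isinstance(paths, dict):
        errors.append("paths section missing")
        paths = {}
    for key in paths:
        if key not in _PATH_KEYS:
            errors.append(f"unknown paths key {key!r}")
    aligns = paths.get("alignments")
    if not aligns or not isinstance(aligns, list):
        errors.append("paths.alignments must be a non-empty list")
    else:
        for i, a in enumerate(aligns):
            if not isinstance(a, dict) or "path" not in a:
                errors.append(f"paths.alignments[{i}] needs a 'path'")
    if "gff3" not in paths:
        errors.append("paths.gff3 is required")
    if "out_dir" not in cfg:
        errors.append("out_dir is required")
    seed = cfg.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append("seed must be a non-negative integer")
    params = dict(cfg.get("params", {}))
    phase = params.pop("phase", {})
    for key, val in params.items():
        if key not in _PARAM_DEFAULTS:
            errors.append(f"unknown params key {key!r}")
        elif key == "coverage_cuts":
            if not (isinstance(val, (list, tuple)) and len(val) == 2 and val[0] < val[1]):
                errors.append("coverage_cuts must be an increasing pair")
        elif not isinstance(val, (int, float)) or val < 0:
            errors.append(f"params.{key} must be a non-negative number")
    if params.get("min_len", 21) > params.get("max_len", 25):
        errors.append("min_len exceeds max_len")
    if params.get("mincov", 20) < 1:
        errors.append("mincov must be >= 1")
    for key, val in dict(phase).items():
        if key not in _PHASE_DEFAULTS:
            errors.append(f"unknown params.phase key {key!r}")
        elif not isinstance(val, (int, float)) or val < 0:
            errors.append(f"params.phase.{key} must be a non-negative number")
    if dict(phase).get("cycle", 23) < 2:
        errors.append("phase.cycle must be >= 2")
    modes = cfg.get("modes", {})
    allowed = {
        "counting": ("weighted", "unweighted"),
        "tpm_variant": ("length_normalized", "scaled"),
        "correlation_scale": ("natural", "log2"),
    }
    for key, val in dict(modes).items():
        if key not in allowed:
            errors.append(f"unknown modes key {key!r}")
        elif val not in allowed[key]:
            errors.append(f"modes.{key} must be one of {allowed[key]}")
    return errors


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: PipelineConfig) -> dict:
    """Execute the whole pipeline and write all outputs.

    Raises before any compute if an input path is missing; aborts with the
    stage name on stage failure. Returns the in-memory result bundle.
    """
    # --- validation ----------------------------------------------------
    missing = [p for p in [config.gff3, config.mrna, config.fasta] if p and not Path(p).exists()]
    missing += [a["path"] for a in config.alignments if not Path(a["path"]).exists()]
    if missing:
        raise FileNotFoundError(f"missing input files: {missing}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.params
    ph = config.phase
    weighted = config.modes["counting"] == "weighted"

    results: dict = {}
    stage = "load"
    try:
        genes = load_annotation(config.gff3)
        libs = [
            filter_reads(
                load_alignments(
                    a["path"],
                    sample_id=a.get("sample_id"),
                    serotype=a.get("serotype", ""),
                    genotype=a.get("genotype", "WT"),
                    replicate=a.get("replicate", 1),
                ),
                min_len=p["min_len"],
                max_len=p["max_len"],
                max_mismatch=p["max_mismatch"],
                max_placements=p["max_placements"],
            )
            for a in config.alignments
        ]

        # --- cluster definition on WT serotypes ------------------------
        stage = "callclusters"
        wt_by_serotype: dict[str, list] = defaultdict(list)
        for lib in libs:
            if lib.genotype == "WT":
                wt_by_serotype[lib.serotype].append(lib)
        serotype_libs = [
            SampleLibrary(
                sample_id=st,
                reads=[r for lib in ls for r in lib.reads],
                serotype=st,
            )
            for st, ls in sorted(wt_by_serotype.items())
        ]
        serotype_libs = downsample(serotype_libs, seed=config.seed + 11)
        per_serotype_clusters = {
            lib.serotype: call_clusters(lib, mincov=p["mincov"], pad=p["pad"])
            for lib in serotype_libs
        }

        stage = "unify"
        srcs = unify_clusters(list(per_serotype_clusters.values()))
        results["srcs"] = srcs

        stage = "adjust"
        adjusted, links = adjust_boundaries(srcs, genes)
        results["adjusted_srcs"] = adjusted
        results["links"] = links

        # --- quantification --------------------------------------------
        stage = "quantify"
        quant = pd.concat(
            [quantify_clusters(lib, srcs, weighted=weighted) for lib in libs],
            ignore_index=True,
        )
        results["quant"] = quant
        # serotype-aggregated WT quantification (replicates summed)
        sero_quant = []
        for lib in serotype_libs:
            q = quantify_clusters(lib, srcs, weighted=weighted)
            sero_quant.append(q)
        sero_quant = pd.concat(sero_quant, ignore_index=True)
        results["serotype_quant"] = sero_quant
        value_col = "tpm" if config.modes["tpm_variant"] == "length_normalized" else "scaled_count"
        specific = {
            st: set(
                serotype_specific(
                    grp.set_index("src_id")[value_col], threshold_tpm=p["tpm_threshold"]
                )
            )
            for st, grp in sero_quant.groupby("sample_id")
        }
        results["serotype_specific"] = specific

        # --- phasing ----------------------------------------------------
        stage = "phase"
        phased_regions = {}
        for lib in serotype_libs:
            phased_regions[lib.serotype] = detect_phased(
                lib,
                min_score=ph["min_score"],
                min_bins_per_strand=ph["min_bins"],
                min_reads=ph["min_reads"],
                merge_dist=ph["merge"],
                minus_offset=ph["minus_offset"],
                cycle=ph["cycle"],
                srcs=srcs,
            )
        results["phased_regions"] = phased_regions
        phased_src_by_serotype = {
            st: {sid for reg in regs for sid in reg.src_ids}
            for st, regs in phased_regions.items()
        }
        phased_src_ids = set().union(*phased_src_by_serotype.values()) if phased_src_by_serotype else set()
        results["phased_src_ids"] = phased_src_ids

        # --- integration -------------------------------------------------
        stage = "integrate"
        links_by_serotype = {
            st: [
                l
                for l in links
                if l.action != "discard" and l.src_id in specific.get(st, set())
            ]
            for st in specific
        }
        gsrc_ids, present_in = define_gsrcs(links_by_serotype)
        gene_by_id = {g.gene_id: g for g in genes}
        src_by_id = {s.src_id: s for s in srcs}
        kept_links = [l for l in links if l.action != "discard"]
        srcs_of_gene: dict[str, list] = defaultdict(list)
        for l in kept_links:
            srcs_of_gene[l.gene_id].append(src_by_id[l.src_id])
        gsrc_rows = []
        for gid in gsrc_ids:
            pct, cls = coverage_class(
                gene_by_id[gid], srcs_of_gene[gid], cuts=tuple(p["coverage_cuts"])
            )
            phased = any(s.src_id in phased_src_ids for s in srcs_of_gene[gid])
            gsrc_rows.append(
                {
                    "gene_id": gid,
                    "coverage_pct": pct,
                    "coverage_class": cls,
                    "phased": phased,
                    "n_srcs": len(srcs_of_gene[gid]),
                }
            )
        gsrc_table = pd.DataFrame(gsrc_rows)
        results["gsrc_table"] = gsrc_table
        results["present_in"] = present_in
        results["gsrc_intersections"] = intersections(present_in)

        if len(gsrc_table):
            n_total = len(gsrc_table)
            n_iii = int((gsrc_table["coverage_class"] == "III").sum())
            n_ph = int(gsrc_table["phased"].sum())
            n_ph_iii = int(
                ((gsrc_table["coverage_class"] == "III") & gsrc_table["phased"]).sum()
            )
            results["class3_enrichment_p"] = enrichment(n_total, n_iii, n_ph, n_ph_iii)

        wt_samples = sorted(l.sample_id for l in libs if l.genotype == "WT")
        if config.mrna:
            mrna = pd.read_csv(config.mrna, sep="\t", index_col=0)
            gene_srna = aggregate_srna_per_gene(kept_links, quant, value=value_col)
            shared = [c for c in wt_samples if c in mrna.columns]
            if len(shared) >= 3:
                corr = correlate(
                    gene_srna[[c for c in shared if c in gene_srna.columns]],
                    mrna[shared],
                    alpha=p["alpha"],
                    scale=config.modes["correlation_scale"],
                )
                results["correlations"] = corr

        counts_wide = quant.pivot_table(
            index="src_id", columns="sample_id", values="raw_count", fill_value=0.0
        )
        phased_flags = pd.Series(
            {sid: sid in phased_src_ids for sid in counts_wide.index}
        )
        contrasts = {}
        for mut in ("rdr1", "rdr2"):
            mut_samples = sorted(l.sample_id for l in libs if l.genotype == mut)
            wt_match = sorted(
                l.sample_id
                for l in libs
                if l.genotype == "WT"
                and l.serotype in {x.serotype for x in libs if x.genotype == mut}
            )
            if len(mut_samples) >= 2 and len(wt_match) >= 2:
                contrasts[mut] = mutant_contrast(
                    counts_wide, wt_match, mut_samples, phased_flags
                )
        results["contrasts"] = contrasts
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    _write_outputs(config, results, out)
    return results


def _write_outputs(config: PipelineConfig, results: dict, out: Path) -> None:
    def bed(srcs, path):
        with open(path, "w") as fh:
            for s in srcs:
                fh.write(f"{s.chrom}\t{s.start}\t{s.end}\t{s.src_id}\t{s.n_alignments}\t.\n")

    bed(results["srcs"], out / "srcs.bed")
    bed(results["adjusted_srcs"], out / "srcs_adjusted.bed")
    pd.DataFrame(
        [
            {
                "gene_id": l.gene_id,
                "src_id": l.src_id,
                "overlap_bp": l.overlap_bp,
                "gene_frac": round(l.gene_frac, 6),
                "src_frac": round(l.src_frac, 6),
                "action": l.action,
            }
            for l in results["links"]
        ]
    ).to_csv(out / "gene_src_links.tsv", sep="\t", index=False)
    results["quant"].round(6).to_csv(out / "quant.tsv", sep="\t", index=False)
    results["serotype_quant"].round(6).to_csv(out / "quant_serotype.tsv", sep="\t", index=False)

    with open(out / "phased_regions.tsv", "w") as fh:
        fh.write("serotype\tchrom\tstart\tend\tbest_p_score\tn_windows\tsrc_ids\n")
        for st in sorted(results["phased_regions"]):
            for r in results["phased_regions"][st]:
                fh.write(
                    f"{st}\t{r.chrom}\t{r.start}\t{r.end}\t{r.best_p_score:.4f}\t"
                    f"{r.n_windows}\t{','.join(r.src_ids)}\n"
                )
    with open(out / "phased_regions.bed", "w") as fh:
        for st in sorted(results["phased_regions"]):
            for r in results["phased_regions"][st]:
                score = min(int(round(r.best_p_score * 10)), 1000)
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{st}\t{score}\t.\n")

    results["gsrc_table"].round(4).to_csv(out / "gsrc.tsv", sep="\t", index=False)
    if "correlations" in results:
        results["correlations"].round(6).to_csv(out / "correlations.tsv", sep="\t", index=False)
    for mut, (table, test) in results.get("contrasts", {}).items():
        table.round(6).to_csv(out / f"contrast_srna_{mut}.tsv", sep="\t")

    summary = {
        "n_srcs": len(results["srcs"]),
        "n_adjusted_srcs": len(results["adjusted_srcs"]),
        "n_gsrcs": len(results["gsrc_table"]),
        "n_phased_srcs": len(results["phased_src_ids"]),
        "serotype_specific_counts": {
            st: len(v) for st, v in sorted(results["serotype_specific"].items())
        },
        "class_sizes": results["gsrc_table"]["coverage_class"].value_counts().to_dict()
        if len(results["gsrc_table"])
        else {},
        "class3_enrichment_p": results.get("class3_enrichment_p"),
        "contrast_tests": {m: t for m, (_, t) in results.get("contrasts", {}).items()},
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")

    cfg_dict = config.to_dict()
    cfg_blob = json.dumps(cfg_dict, sort_keys=True).encode()
    manifest = {
        "phasiclust_version": __version__,
        "seed": config.seed,
        "parameter_hash": hashlib.sha256(cfg_blob).hexdigest(),
        "inputs": {
            str(a["path"]): _sha256(a["path"]) for a in config.alignments
        }
        | {str(config.gff3): _sha256(config.gff3)}
        | ({str(config.mrna): _sha256(config.mrna)} if config.mrna else {}),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg_dict, fh, sort_keys=True)
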