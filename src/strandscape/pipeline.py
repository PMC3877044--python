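"""End-to-end orchestration: config validation, stage execution, reports.

All reports are tidy TSV plus one JSON run manifest, with fixed float
formatting and sorted keys, so reruns on identical inputs are
byte-identical and diffable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import pandas as pd
import yaml

from . import __version__
from .annotation import (
    PartitionIndex,
    build_partition,
    load_gene_models,
    load_repeats,
    read_chrom_sizes,
)
from .assignment import (
    CoverageTracker,
    RegionCounts,
    assign_read,
    count_by_region,
    filter_reads,
    read_alignment_tsv,
)
from .junctions import (
    extract_junctions,
    filter_junctions,
    junction_table,
    match_known,
    pool_observations,
    category_percentages,
    venn_partition,
)
from .landscape import (
    comparison_table,
    profile_sample,
    replicate_correlation,
)
from .repeats import family_profile, family_proportion_test, intron_concordance
from .transfrags import (
    classify_transfrags,
    length_summary,
    read_bed12,
    read_gtf_transfrags,
    transfrag_expression,
)

logger = logging.getLogger("strandscape")

_FLOAT_FMT = "%.6g"

DEFAULT_PARAMS = {
    "alpha": 0.05,
    "flank": 1000,
    "min_reads": 2,
    "min_overhang": 15,
    "transfrag_share": 0.8,
    "read_length": 50,
    "mapq_min": 10,
    "log_offset": 1.0,
}

_KNOWN_KEYS = {
    "annotation", "repeats", "chrom_sizes", "transfrags", "samples",
    "outdir", "seed", "family_map",
} | set(DEFAULT_PARAMS)


@dataclass
class RunConfig:
    annotation: str
    chrom_sizes: str
    samples: Dict[str, Dict[str, str]]  # id -> {path, condition, replicate}
    outdir: str
    repeats: Optional[str] = None
    transfrags: Optional[str] = None
    family_map: Optional[Dict[str, str]] = None
    seed: int = 0
    alpha: float = 0.05
    flank: int = 1000
    min_reads: int = 2
    min_overhang: int = 15
    transfrag_share: float = 0.8
    read_length: int = 50
    mapq_min: int = 10
    log_offset: float = 1.0

    @property
    def design(self) -> Dict[str, Tuple[str, str]]:
        return {sid: (s["condition"], s["replicate"]) for sid, s in self.samples.items()}

    @property
    def conditions(self) -> Tuple[str, str]:
        conds = sorted({s["condition"] for s in self.samples.values()})
        return tuple(conds)  # validated to be exactly two


def validate_config(source) -> Tuple[Optional[RunConfig], List[str]]:
    """Normalise a YAML path/dict into a RunConfig, listing every violation.

    All problems are collected rather than failing on the first; defaults
    are filled for absent parameters.  Unknown keys are rejected by name.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    errors: List[str] = []
    if not isinstance(raw, dict):
        return None, ["config must be a mapping"]
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        errors.append(f"unknown config keys: {', '.join(sorted(unknown))}")
    for key in ("annotation", "chrom_sizes", "samples", "outdir"):
        if key not in raw:
            errors.append(f"missing required key: {key}")
    params = dict(DEFAULT_PARAMS)
    for key in DEFAULT_PARAMS:
        if key in raw:
            params[key] = raw[key]
    if params["flank"] < 0:
        errors.append("flank must be >= 0")
    if not 0 < params["alpha"] < 1:
        errors.append("alpha must be in (0, 1)")
    if params["min_reads"] < 1:
        errors.append("min_reads must be >= 1")
    if params["min_overhang"] < 1:
        errors.append("min_overhang must be >= 1")
    if not 0 < params["transfrag_share"] < 1:
        errors.append("transfrag_share must be in (0, 1)")
    if params["read_length"] <= 0:
        errors.append("read_length must be positive")
    samples = raw.get("samples") or {}
    conds: Dict[str, int] = {}
    for sid, s in samples.items():
        if not isinstance(s, dict):
            errors.append(f"sample {sid}: must be a mapping")
            continue
        for key in ("path", "condition", "replicate"):
            if key not in s:
                errors.append(f"sample {sid}: missing {key}")
        if "condition" in s:
            conds[s["condition"]] = conds.get(s["condition"], 0) + 1
    if samples and len(conds) != 2:
        errors.append(f"exactly 2 conditions required, found {len(conds)}")
    if conds and any(n < 1 for n in conds.values()):
        errors.append("each condition needs at least one replicate")
    if errors:
        return None, errors
    cfg = RunConfig(
        annotation=raw["annotation"],
        chrom_sizes=raw["chrom_sizes"],
        samples=samples,
        outdir=raw["outdir"],
        repeats=raw.get("repeats"),
        transfrags=raw.get("transfrags"),
        family_map=raw.get("family_map"),
        seed=int(raw.get("seed", 0)),
        **params,
    )
    return cfg, []


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _load_reads(path: str):
    if path.endswith((".sam", ".bam")):
        return path  # filter_reads streams SAM/BAM itself
    return read_alignment_tsv(path)


def run_landscape(config: RunConfig) -> Dict:
    """Execute every stage in order and write the report bundle.

    Stages: partition dump, per-sample counts, distribution profiles,
    condition comparisons, repeat profiles, junction tables + Venn,
    transfrag classification, replicate correlations, run manifest.  A
    missing repeats file skips the repeat stages with an explicit notice;
    any stage failure aborts with a stage-named error.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "parameters": {k: getattr(config, k) for k in DEFAULT_PARAMS},
        "seed": config.seed,
        "notices": [],
        "filter_tallies": {},
        "stages": [],
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        stage("partition")
        genes, rrna = load_gene_models(config.annotation)
        sizes = read_chrom_sizes(config.chrom_sizes)
        index = build_partition(genes, rrna, sizes, flank=config.flank)
        if config.repeats and Path(config.repeats).exists():
            load_repeats(config.repeats, index, family_map=config.family_map)
        else:
            manifest["notices"].append("repeats file absent: repeat stages skipped")
        index.to_bed(str(out / "partition.bed"))
    except Exception as exc:
        raise RuntimeError(f"stage partition failed: {exc}") from exc

    counts_by_sample: Dict[str, RegionCounts] = {}
    reads_by_sample = {}
    profiles = []
    gene_counts: Dict[str, Dict[str, int]] = {}
    try:
        stage("count")
        for sid in sorted(config.samples):
            src = _load_reads(config.samples[sid]["path"])
            retained, tallies = filter_reads(src, index, mapq_min=config.mapq_min)
            manifest["filter_tallies"][sid] = tallies.as_dict()
            assignments = [assign_read(r, index) for r in retained]
            rc = count_by_region(assignments, sid, tallies)
            assert rc.check_conservation()
            counts_by_sample[sid] = rc
            reads_by_sample[sid] = retained
            cov = CoverageTracker(index.chrom_sizes)
            for r in retained:
                cov.add(r)
            profiles.append(profile_sample(rc, index, cov, config.read_length).to_frame())
            gvec: Dict[str, int] = {}
            for a in assignments:
                if a.gene_id is not None and a.orientation == "sense":
                    gvec[a.gene_id] = gvec.get(a.gene_id, 0) + 1
            gene_counts[sid] = gvec
        _write(pd.concat([rc.to_frame() for rc in counts_by_sample.values()]),
               out / "region_counts.tsv")
        _write(pd.concat(profiles), out / "profiles.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage count failed: {exc}") from exc

    design = config.design
    conditions = config.conditions
    try:
        stage("compare")
        by_key = {design[sid]: rc for sid, rc in counts_by_sample.items()}
        cmp = comparison_table(by_key, alpha=config.alpha, conditions=conditions)
        _write(cmp, out / "comparisons.tsv")
    except Exception as exc:
        raise RuntimeError(f"stage compare failed: {exc}") from exc

    if index.repeats is not None and index.repeats.entries:
        try:
            stage("repeats")
            prof = family_profile(counts_by_sample, design, conditions=conditions)
            _write(prof, out / "repeat_profile.tsv", index=True)
            conc = intron_concordance(index.repeats)
            _write(conc, out / "repeat_concordance.tsv", index=True)
            tests = family_proportion_test(
                counts_by_sample, design, alpha=config.alpha, conditions=conditions
            )
            rows = []
            for fam, res in sorted(tests.items()):
                rows.append({
                    "family": fam,
                    "p_reported": res.p_reported,
                    "significant": res.significant,
                    "fc_merged": res.fold_change_merged,
                })
            _write(pd.DataFrame(rows), out / "repeat_tests.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage repeats failed: {exc}") from exc

    try:
        stage("junctions")
        per_sample_raw = {
            sid: extract_junctions(reads) for sid, reads in reads_by_sample.items()
        }
        pooled = pool_observations(per_sample_raw, design)
        accepted = {
            cond: filter_junctions(raw, config.min_reads, config.min_overhang)
            for cond, raw in pooled.items()
        }
        table = junction_table(pooled, accepted, genes, index)
        _write(table, out / "junctions.tsv")
        venn_all = venn_partition(accepted)
        novel_accepted = {}
        for cond, keys in accepted.items():
            status, _ = match_known(keys, genes)
            novel_accepted[cond] = {k for k in keys if status[k] == "novel"}
        venn_novel = venn_partition(novel_accepted)
        venn_rows = [
            {"set": "all", **venn_all.counts()},
            {"set": "novel", **venn_novel.counts()},
        ]
        _write(pd.DataFrame(venn_rows), out / "junction_venn.tsv")
        pct = {}
        for cond, keys in sorted(venn_novel.exclusive.items()):
            pct[cond] = category_percentages(keys, index)
        _write(pd.DataFrame(pct).fillna(0.0).rename_axis("region_pair"),
               out / "junction_categories.tsv", index=True)
        status_all, confirmed_frac = match_known(
            set().union(*accepted.values()) if accepted else set(), genes
        )
        manifest["junctions"] = {
            "confirmed_annotated_fraction": confirmed_frac,
            **{f"venn_all_{k}": v for k, v in venn_all.counts().items()},
            **{f"venn_novel_{k}": v for k, v in venn_novel.counts().items()},
        }
    except Exception as exc:
        raise RuntimeError(f"stage junctions failed: {exc}") from exc

    if config.transfrags and Path(config.transfrags).exists():
        try:
            stage("transfrags")
            if config.transfrags.endswith((".bed", ".bed12")):
                tfs = read_bed12(config.transfrags)
            else:
                tfs = read_gtf_transfrags(config.transfrags)
            classified = classify_transfrags(tfs, index, config.transfrag_share)
            _write(classified, out / "transfrag_class.tsv")
            _write(length_summary(classified), out / "transfrag_summary.tsv")
            expr = transfrag_expression(tfs, reads_by_sample)
            _write(expr, out / "transfrag_expression.tsv")
        except Exception as exc:
            raise RuntimeError(f"stage transfrags failed: {exc}") from exc
    elif config.transfrags:
        manifest["notices"].append("transfrags file absent: transfrag stage skipped")

    try:
        stage("correlation")
        all_genes = sorted({g for vec in gene_counts.values() for g in vec})
        mat = pd.DataFrame(
            {sid: [gene_counts[sid].get(g, 0) for g in all_genes]
             for sid in sorted(gene_counts)},
            index=all_genes,
        )
        corr = replicate_correlation(mat, log_offset=config.log_offset)
        _write(corr.rename_axis("sample"), out / "replicate_correlation.tsv", index=True)
    except Exception as exc:
        raise RuntimeError(f"stage correlation failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
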