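"""Orchestration: simulate → analyse → score recovery against the truth ledger.

Each stage is a plain function over files so it can be driven from the CLI,
from the numbered analysis scripts, or directly from tests.  ``run_pipeline``
executes the selected stages in dependency order and writes a JSON manifest
(parameters, seeds, input checksums, outputs); ``evaluate_recovery`` scores
each detection stage against the planted truth.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import atac as atac_mod
from . import ribo as ribo_mod
from .io import (
    read_counts_tsv,
    read_design,
    read_fasta,
    read_fragments_bed,
    read_gwas_table,
    read_loci_bed,
    read_peptide_report,
    read_truth,
)
from .simulate import SimConfig, simulate_dataset
from .subscan import ScanParams, scan_peptide_report
from .usage import compute_usage, phe_abundance_correlation, usage_enrichment

logger = logging.getLogger("misphe")

STAGES = ["simulate", "subscan", "usage", "ribo", "atac", "gwaswin"]

DEFAULT_TOLERANCES = {
    "substitution_sensitivity_min": 0.9,
    "decoy_removal_min": 1.0,
    "canonical_false_positives_max": 0,
    "pause_ratio_range": (2.0, 4.5),
    "control_codon_ratio_max": 1.3,
    "accessibility_lfc_tolerance": 0.5,
    "accessibility_padj_max": 0.05,
    "accessibility_off_target_max": 0,
    "usage_rho_sign": -1,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class ConfigError(ValueError):
    """Raised when a run configuration does not validate."""


def _sim_config_from_dict(block: dict, seed: int | None) -> SimConfig:
    known = {f.name for f in fields(SimConfig)}
    unknown = set(block) - known
    if unknown:
        raise ConfigError(f"unknown simulate keys: {sorted(unknown)}")
    block = dict(block)
    for key in (
        "protein_length_range", "cds_length_codons", "pause_codons",
        "gwas_hit_distances", "gwas_hit_pvalues", "gwas_categories",
    ):
        if key in block and isinstance(block[key], list):
            block[key] = tuple(block[key])
    if "fragment_length_mixture" in block:
        block["fragment_length_mixture"] = [
            tuple(c) for c in block["fragment_length_mixture"]
        ]
    if seed is not None:
        block["seed"] = seed
    return SimConfig(**block)


# ---------------------------------------------------------------------------
# Stage runners (file-level)
# ---------------------------------------------------------------------------


def stage_simulate(config: SimConfig, outdir: Path) -> dict[str, Path]:
    logger.info("stage=simulate seed=%s outdir=%s", config.seed, outdir)
    return simulate_dataset(config, outdir)


def stage_subscan(
    proteome_path: Path,
    report_path: Path,
    design_path: Path,
    outdir: Path,
    params: ScanParams | None = None,
) -> dict[str, Path]:
    params = params or ScanParams()
    proteome = read_fasta(proteome_path)
    report = read_peptide_report(report_path)
    design = read_design(design_path)
    result = scan_peptide_report(proteome, report, design, params)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "substitution_report.tsv": outdir / "substitution_report.tsv",
        "removed_candidates.tsv": outdir / "removed_candidates.tsv",
        "unexplained_peptides.tsv": outdir / "unexplained_peptides.tsv",
    }
    result.report.to_csv(paths["substitution_report.tsv"], sep="\t", index=False)
    removed_cols = [
        c for c in (
            "peptide_sequence", "protein_id", "position", "substituted",
            "canonical_peptide", "isobaric_reason",
        ) if c in result.removed.columns
    ]
    result.removed[removed_cols].to_csv(
        paths["removed_candidates.tsv"], sep="\t", index=False
    )
    result.unexplained.to_csv(paths["unexplained_peptides.tsv"], sep="\t", index=False)
    meta = {
        "n_variants": result.n_variants,
        "n_canonical_peptides": result.n_canonical_peptides,
        "n_candidates_kept": int(len(result.report)),
        "n_candidates_removed": int(len(result.removed)),
        "isobaric_tolerance_da": params.isobaric_tolerance_da,
        "missed_cleavages": params.missed_cleavages,
        "length_range": list(params.length_range),
    }
    meta_path = outdir / "subscan_meta.json"
    meta_path.write_text(json.dumps(meta, indent=2) + "\n")
    paths["subscan_meta.json"] = meta_path
    logger.info(
        "stage=subscan kept=%d removed=%d", len(result.report), len(result.removed)
    )
    return paths


def stage_usage(
    proteome_path: Path, changes_path: Path, outdir: Path
) -> dict[str, Path]:
    proteome = read_fasta(proteome_path)
    changes = pd.read_csv(changes_path, sep="\t")
    usage = compute_usage(proteome)
    rho, p = phe_abundance_correlation(usage, changes)
    up = list(changes.loc[changes["direction"] == "up", "protein_id"])
    down = list(changes.loc[changes["direction"] == "down", "protein_id"])
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "usage_matrix.tsv": outdir / "usage_matrix.tsv",
        "usage_scatter.tsv": outdir / "usage_scatter.tsv",
        "usage_correlation.json": outdir / "usage_correlation.json",
    }
    usage.to_csv(paths["usage_matrix.tsv"], sep="\t")
    scatter = changes.merge(
        usage[["percent_phe"]], left_on="protein_id", right_index=True
    )[["protein_id", "percent_phe", "log2_ratio"]]
    scatter.to_csv(paths["usage_scatter.tsv"], sep="\t", index=False)
    paths["usage_correlation.json"].write_text(
        json.dumps({"spearman_rho": rho, "p_value": p}, indent=2) + "\n"
    )
    if up and down:
        enrichment = usage_enrichment(up, down, usage)
        enr_path = outdir / "usage_enrichment.tsv"
        enrichment.to_csv(enr_path, sep="\t", index=False)
        paths["usage_enrichment.tsv"] = enr_path
    logger.info("stage=usage rho=%.3f p=%.3g", rho, p)
    return paths


def stage_ribo(
    cds_path: Path,
    counts_path: Path,
    design_path: Path,
    outdir: Path,
    codons: tuple[str, ...] = ("UUU", "UUC", "AUC"),
    threshold: float = 1.5,
) -> dict[str, Path]:
    cds = read_fasta(cds_path)
    counts = read_counts_tsv(counts_path)
    design = read_design(design_path)
    outdir.mkdir(parents=True, exist_ok=True)
    profile_rows = []
    call_rows = []
    for codon in codons:
        mg = ribo_mod.metagene(cds, counts, design, codon)
        for group, profile in mg.profiles.items():
            for off, val in zip(mg.offsets, profile):
                profile_rows.append(
                    {"codon": mg.codon, "group": group, "offset": int(off),
                     "mean_normalized_count": float(val)}
                )
        call = ribo_mod.call_pauses(mg, threshold=threshold)
        for off, ratio in call.ratios.items():
            call_rows.append(
                {
                    "codon": call.codon,
                    "offset": off,
                    "site": ribo_mod.DEFAULT_SITE_OFFSETS.get(off, ""),
                    "ko_ctrl_ratio": ratio,
                    "flagged": off in call.flagged,
                    "score": call.score,
                }
            )
    paths = {
        "metagene_profiles.tsv": outdir / "metagene_profiles.tsv",
        "pause_calls.tsv": outdir / "pause_calls.tsv",
    }
    pd.DataFrame(profile_rows).to_csv(paths["metagene_profiles.tsv"], sep="\t", index=False)
    pd.DataFrame(call_rows).to_csv(paths["pause_calls.tsv"], sep="\t", index=False)
    logger.info("stage=ribo codons=%s", ",".join(codons))
    return paths


def stage_atac(
    fragments_path: Path,
    loci_path: Path,
    design_path: Path,
    outdir: Path,
) -> dict[str, Path]:
    fragments = read_fragments_bed(fragments_path)
    loci = read_loci_bed(loci_path)
    design = read_design(design_path)
    seg = atac_mod.estimate_segmentation(fragments)
    classified = atac_mod.classify_fragments(fragments, seg)
    windows = atac_mod.make_locus_windows(loci)
    counts = atac_mod.count_cut_sites(classified, windows, samples=list(design["sample"]))
    results, sf = atac_mod.differential_accessibility(counts, design)
    family = {locus: "tRNA-Phe" for locus in loci["locus_id"]}
    fam_results, _ = atac_mod.family_sum(counts, family, design)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cut_site_counts.tsv": outdir / "cut_site_counts.tsv",
        "differential_accessibility.tsv": outdir / "differential_accessibility.tsv",
        "family_accessibility.tsv": outdir / "family_accessibility.tsv",
        "segmentation.json": outdir / "segmentation.json",
    }
    counts.to_csv(paths["cut_site_counts.tsv"], sep="\t", index=False)
    for state in atac_mod.STATE_NAMES:
        bg = outdir / f"coverage_{state}.bedGraph"
        atac_mod.state_coverage_bedgraph(classified, bg, state)
        paths[f"coverage_{state}.bedGraph"] = bg
    results.to_csv(paths["differential_accessibility.tsv"], sep="\t", index=False)
    fam_results.to_csv(paths["family_accessibility.tsv"], sep="\t", index=False)
    paths["segmentation.json"].write_text(
        json.dumps(
            {
                "period": None if math.isnan(seg.period) else seg.period,
                "boundaries": [list(b) for b in seg.boundaries],
                "resolved": seg.resolved,
                "size_factors": {k: float(v) for k, v in sf.items()},
            },
            indent=2,
        )
        + "\n"
    )
    logger.info("stage=atac period=%s resolved=%s", seg.period, seg.resolved)
    return paths


def stage_gwaswin(
    gwas_path: Path,
    loci_path: Path,
    outdir: Path,
    windows: tuple[int, ...] = (50, 100, 250, 500, 1000),
    p_threshold: float = 0.05,
    exclude: tuple[str, ...] = (),
) -> dict[str, Path]:
    hits = read_gwas_table(gwas_path)
    loci = read_loci_bed(loci_path)
    table = atac_mod.gwas_window_counts(
        hits, loci, windows=windows, p_threshold=p_threshold, exclude=exclude
    )
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "gwas_window_counts.tsv"
    table.to_csv(path, sep="\t", index=False)
    logger.info("stage=gwaswin windows=%s", windows)
    return {"gwas_window_counts.tsv": path}


# ---------------------------------------------------------------------------
# Pipeline driver
# ---------------------------------------------------------------------------


def run_pipeline(config: dict) -> dict:
    """Run the selected stages from a single configuration mapping.

    Recognised keys: ``seed``, ``outdir``, ``stages`` (subset of
    ``simulate subscan usage ribo atac gwaswin``) and one optional block per
    stage.  Analysis stages read the simulated dataset under
    ``<outdir>/dataset`` unless explicit input paths are given in their
    block.  Returns the manifest (also written to ``<outdir>/manifest.json``).
    """
    known = {"seed", "outdir", "stages"} | set(STAGES)
    unknown = set(config) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    stages = config.get("stages", STAGES)
    bad = [s for s in stages if s not in STAGES]
    if bad:
        raise ConfigError(f"unknown stages: {bad}")
    if "outdir" not in config:
        raise ConfigError("config must set 'outdir'")
    outdir = Path(config["outdir"])
    seed = config.get("seed")
    dataset_dir = outdir / "dataset"
    results_dir = outdir / "results"

    manifest: dict = {"stages": {}, "seed": seed, "outdir": str(outdir)}

    def record(stage: str, params: dict, paths: dict[str, Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "outputs": {name: str(p) for name, p in paths.items()},
            "checksums": {name: _sha256(p) for name, p in paths.items()},
        }

    def dataset_path(stage_block: dict, key: str, default_name: str) -> Path:
        path = Path(stage_block.get(key, dataset_dir / default_name))
        if not path.exists():
            raise ConfigError(f"input path does not exist: {path}")
        return path

    # validate analysis inputs up front so nothing runs on a broken config
    for stage in stages:
        block = config.get(stage, {}) or {}
        if stage != "simulate" and "simulate" not in stages:
            defaults = {
                "subscan": ["proteome.fasta", "peptide_report.tsv", "dia_design.tsv"],
                "usage": ["proteome.fasta", "abundance_changes.tsv"],
                "ribo": ["cds.fasta", "ribo_counts.tsv", "ribo_design.tsv"],
                "atac": ["fragments.bed", "trna_loci.bed", "atac_design.tsv"],
                "gwaswin": ["gwas_hits.tsv", "trna_loci.bed"],
            }[stage]
            for name in defaults:
                candidate = Path(block.get(name.split(".")[0], dataset_dir / name))
                if not candidate.exists():
                    raise ConfigError(
                        f"stage {stage!r}: input {candidate} missing "
                        "(run the simulate stage or point to existing inputs)"
                    )

    try:
        if "simulate" in stages:
            sim_cfg = _sim_config_from_dict(config.get("simulate", {}) or {}, seed)
            paths = stage_simulate(sim_cfg, dataset_dir)
            record("simulate", asdict(sim_cfg) | {
                "fragment_length_mixture": [
                    list(c) for c in sim_cfg.fragment_length_mixture
                ]
            }, paths)
        if "subscan" in stages:
            block = config.get("subscan", {}) or {}
            params = ScanParams(
                target_residue=block.get("target_residue", "F"),
                missed_cleavages=int(block.get("missed_cleavages", 2)),
                isobaric_tolerance_da=float(block.get("isobaric_tolerance_da", 0.04)),
                welch=bool(block.get("welch", False)),
            )
            paths = stage_subscan(
                dataset_path(block, "proteome", "proteome.fasta"),
                dataset_path(block, "report", "peptide_report.tsv"),
                dataset_path(block, "design", "dia_design.tsv"),
                results_dir / "subscan",
                params,
            )
            record("subscan", {
                "target_residue": params.target_residue,
                "missed_cleavages": params.missed_cleavages,
                "isobaric_tolerance_da": params.isobaric_tolerance_da,
                "welch": params.welch,
            }, paths)
        if "usage" in stages:
            block = config.get("usage", {}) or {}
            paths = stage_usage(
                dataset_path(block, "proteome", "proteome.fasta"),
                dataset_path(block, "changes", "abundance_changes.tsv"),
                results_dir / "usage",
            )
            record("usage", {}, paths)
        if "ribo" in stages:
            block = config.get("ribo", {}) or {}
            codons = tuple(block.get("codons", ["UUU", "UUC", "AUC"]))
            paths = stage_ribo(
                dataset_path(block, "cds", "cds.fasta"),
                dataset_path(block, "counts", "ribo_counts.tsv"),
                dataset_path(block, "design", "ribo_design.tsv"),
                results_dir / "ribo",
                codons=codons,
                threshold=float(block.get("threshold", 1.5)),
            )
            record("ribo", {"codons": list(codons)}, paths)
        if "atac" in stages:
            block = config.get("atac", {}) or {}
            paths = stage_atac(
                dataset_path(block, "fragments", "fragments.bed"),
                dataset_path(block, "loci", "trna_loci.bed"),
                dataset_path(block, "design", "atac_design.tsv"),
                results_dir / "atac",
            )
            record("atac", {}, paths)
        if "gwaswin" in stages:
            block = config.get("gwaswin", {}) or {}
            paths = stage_gwaswin(
                dataset_path(block, "hits", "gwas_hits.tsv"),
                dataset_path(block, "loci", "trna_loci.bed"),
                results_dir / "gwaswin",
                windows=tuple(block.get("windows", [50, 100, 250, 500, 1000])),
                p_threshold=float(block.get("p_threshold", 0.05)),
                exclude=tuple(block.get("exclude", [])),
            )
            record("gwaswin", {}, paths)
    except Exception:
        (outdir / ".partial").touch()
        raise
    (outdir / ".partial").unlink(missing_ok=True)

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def evaluate_recovery(
    outdir: str | Path, tolerances: dict | None = None
) -> dict:
    """Score pipeline outputs against the dataset's truth ledger.

    ``outdir`` is a directory produced by :func:`run_pipeline` (containing
    ``dataset/truth.json`` and ``results/``).  Stages without outputs are
    skipped.  Returns a report with per-stage metrics and pass/fail flags;
    also written to ``<outdir>/recovery_report.json``.
    """
    outdir = Path(outdir)
    tol = DEFAULT_TOLERANCES | (tolerances or {})
    truth_path = outdir / "dataset" / "truth.json"
    if not truth_path.exists():
        raise FileNotFoundError(f"no truth ledger at {truth_path}")
    truth = read_truth(truth_path)
    report: dict = {"stages": {}, "passed": True}

    def add(stage: str, metrics: dict, passed: bool | None) -> None:
        clean = {
            k: (float(v) if isinstance(v, (np.floating, float)) else
                int(v) if isinstance(v, np.integer) else v)
            for k, v in metrics.items()
        }
        passed = None if passed is None else bool(passed)
        report["stages"][stage] = {"metrics": clean, "passed": passed}
        if passed is False:
            report["passed"] = False

    sub_path = outdir / "results" / "subscan" / "substitution_report.tsv"
    if sub_path.exists():
        kept = pd.read_csv(sub_path, sep="\t")
        removed = pd.read_csv(
            outdir / "results" / "subscan" / "removed_candidates.tsv", sep="\t"
        )
        planted = {e["peptide"] for e in truth.get("planted_substitutions", [])}
        decoys = {e["peptide"] for e in truth.get("planted_isobaric_decoys", [])}
        kept_seqs = set(kept.get("peptide_sequence", pd.Series(dtype=str)))
        removed_seqs = set(removed.get("peptide_sequence", pd.Series(dtype=str)))
        metrics = {
            "n_planted": len(planted),
            "sensitivity": (
                len(planted & kept_seqs) / len(planted) if planted else None
            ),
            "decoy_removal_rate": (
                len(decoys & removed_seqs) / len(decoys) if decoys else None
            ),
            "false_positives": int(len(kept_seqs - planted)),
        }
        passed = None
        if planted:
            passed = (
                metrics["sensitivity"] >= tol["substitution_sensitivity_min"]
                and (metrics["decoy_removal_rate"] or 0) >= tol["decoy_removal_min"]
                and metrics["false_positives"] <= tol["canonical_false_positives_max"]
            )
        add("subscan", metrics, passed)

    usage_path = outdir / "results" / "usage" / "usage_correlation.json"
    if usage_path.exists():
        corr = json.loads(usage_path.read_text())
        slope = truth.get("planted_usage_effect", {}).get("slope", 0.0)
        metrics = {"spearman_rho": corr["spearman_rho"], "planted_slope": slope}
        passed = None
        if slope != 0:
            passed = np.sign(corr["spearman_rho"]) == np.sign(slope)
        add("usage", metrics, passed)

    pause_path = outdir / "results" / "ribo" / "pause_calls.tsv"
    if pause_path.exists():
        calls = pd.read_csv(pause_path, sep="\t")
        pause_codons = set(truth.get("pause_codons", []))
        offset = truth.get("pause_offset")
        metrics: dict = {}
        passed = None
        if pause_codons and offset is not None:
            lo, hi = tol["pause_ratio_range"]
            ok = True
            for codon in sorted(pause_codons):
                at = calls[(calls["codon"] == codon) & (calls["offset"] == offset)]
                ratio = float(at["ko_ctrl_ratio"].iloc[0]) if len(at) else float("nan")
                metrics[f"{codon}_ratio_at_{offset}"] = ratio
                ok &= lo <= ratio <= hi and bool(at["flagged"].iloc[0])
            others = calls[~calls["codon"].isin(pause_codons)]
            max_other = float(others["ko_ctrl_ratio"].max()) if len(others) else 1.0
            metrics["max_control_codon_ratio"] = max_other
            ok &= max_other < tol["control_codon_ratio_max"]
            passed = ok
        add("ribo", metrics, passed)

    da_path = outdir / "results" / "atac" / "differential_accessibility.tsv"
    if da_path.exists():
        da = pd.read_csv(da_path, sep="\t")
        planted = truth.get("planted_accessibility_changes", [])
        metrics = {}
        passed = None
        if planted:
            ok = True
            planted_keys = {(e["locus_id"], e["state"]) for e in planted}
            for ev in planted:
                row = da[
                    (da["locus_id"] == ev["locus_id"]) & (da["state"] == ev["state"])
                ]
                est = float(row["log2_fold_change"].iloc[0]) if len(row) else float("nan")
                padj = float(row["p_adjusted"].iloc[0]) if len(row) else float("nan")
                metrics[f"{ev['locus_id']}:{ev['state']}_log2fc"] = est
                metrics[f"{ev['locus_id']}:{ev['state']}_padj"] = padj
                ok &= (
                    abs(est - ev["log2_fold_change"])
                    <= tol["accessibility_lfc_tolerance"]
                    and padj < tol["accessibility_padj_max"]
                )
            testable = da[da["p_adjusted"].notna()]
            others = testable[
                ~testable.apply(
                    lambda r: (r["locus_id"], r["state"]) in planted_keys, axis=1
                )
            ]
            n_fp = int((others["p_adjusted"] < 0.05).sum())
            metrics["off_target_significant"] = n_fp
            ok &= n_fp <= tol["accessibility_off_target_max"]
            passed = ok
        add("atac", metrics, passed)

    with open(outdir / "recovery_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
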