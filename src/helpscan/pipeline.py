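"""End-to-end orchestration: simulate -> normalize -> qc -> scan -> annotate -> power -> concord.

A run is driven by one YAML config with a section per stage and a
mandatory global seed; per-stage seeds derive deterministically from the
global seed and the stage name, so one number reproduces the whole run.
Every stage writes plain-text artifacts (TSV / BED / Newick / JSON) into
the run directory plus a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import concordance as conc
from . import diffscan, power, preprocess, synthetic
from .io_model import (
    MethylationMatrix,
    read_gene_models,
    read_intervals,
    read_ratio_matrix,
    read_sample_table,
    write_gene_models,
    write_intervals,
    write_ratio_matrix,
    write_sample_table,
)

__all__ = ["run_pipeline", "stage_seed", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("simulate", "normalize", "qc", "scan", "annotate", "power", "concord")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the global seed and stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' requires missing upstream artifact: {path.name}"
        )
    return path


def run_pipeline(config: str | Path | dict, out_dir: str | Path) -> dict:
    """Execute the requested stages in order and write all artifacts.

    ``config`` is a YAML path or an equivalent dict with a top-level
    ``seed`` and one optional section per stage in ``STAGES``; only the
    stages with a section present (value may be ``{}``) are run.  Returns
    the provenance record (also written as ``provenance.json``).
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            cfg = yaml.safe_load(fh)
        cfg_text = Path(config).read_text()
    else:
        cfg = dict(config)
        cfg_text = yaml.safe_dump(cfg, sort_keys=True)
    if "seed" not in cfg:
        raise ValueError("config must set a global 'seed'")
    seed = int(cfg["seed"])
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("helpscan")
    root.addHandler(handler)

    requested = [s for s in STAGES if s in cfg]
    provenance: dict = {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "global_seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in requested},
        "stages_run": requested,
        "helpscan_version": __version__,
        "artifacts": {},
    }

    try:
        for stage in requested:
            log.info("stage %s: start", stage)
            section = cfg.get(stage) or {}
            artifacts = _RUNNERS[stage](section, out, stage_seed(seed, stage))
            provenance["artifacts"][stage] = sorted(artifacts)
            log.info("stage %s: wrote %s", stage, ", ".join(sorted(artifacts)))
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    return provenance


# ---------------------------------------------------------------------------
# stage runners: each takes (section config, out dir, stage seed) and returns
# the artifact file names it wrote
# ---------------------------------------------------------------------------

def _run_simulate(section: dict, out: Path, seed: int) -> list[str]:
    params = {k: v for k, v in section.items() if k != "seed"}
    for key in ("baseline_means", "baseline_sds"):
        if key in params:
            params[key] = tuple(params[key])
    config = synthetic.SimulationConfig(seed=int(section.get("seed", seed)), **params)
    matrix, samples, truth = synthetic.simulate_cohort(config)
    write_ratio_matrix(matrix, out / "matrix.tsv")
    write_sample_table(samples, out / "samples.tsv")
    truth.to_tsv(out / "truth.tsv")
    written = ["matrix.tsv", "samples.tsv", "truth.tsv"]
    tracks, genes, _ = synthetic.simulate_annotation_tracks(config, truth)
    for track in tracks:
        name = f"{track.feature_kind}.bed"
        write_intervals(track, out / name)
        written.append(name)
    write_gene_models(genes, out / "genes.tsv")
    written.append("genes.tsv")
    bis = synthetic.simulate_bisulphite(matrix, seed=stage_seed(seed, "bisulphite"))
    bis.to_csv(out / "bisulphite.tsv", sep="\t", index_label="locus", lineterminator="\n")
    written.append("bisulphite.tsv")
    return written


def _run_normalize(section: dict, out: Path, seed: int) -> list[str]:
    src = Path(section.get("matrix", out / "matrix.tsv"))
    matrix = read_ratio_matrix(_require(src, "normalize"))
    complete, dropped = matrix.drop_incomplete_loci()
    if dropped:
        log.info("normalize: dropped %d loci with missing values", dropped)
    norm = preprocess.quantile_normalize(complete)
    if section.get("center", False):
        norm = preprocess.center_arrays(norm)
    write_ratio_matrix(norm, out / "normalized.tsv")
    return ["normalized.tsv"]


def _run_qc(section: dict, out: Path, seed: int) -> list[str]:
    src = Path(section.get("matrix", out / "normalized.tsv"))
    matrix = read_ratio_matrix(_require(src, "qc"))
    corr = preprocess.pairwise_pearson(matrix)
    corr.to_csv(out / "qc_pearson.tsv", sep="\t", lineterminator="\n")
    linkage = preprocess.ward_cluster(matrix)
    newick = preprocess.tree_to_newick(linkage, matrix.samples)
    (out / "qc_tree.nwk").write_text(newick + "\n")
    return ["qc_pearson.tsv", "qc_tree.nwk"]


def _run_scan(section: dict, out: Path, seed: int) -> list[str]:
    matrix = read_ratio_matrix(_require(Path(section.get("matrix", out / "normalized.tsv")), "scan"))
    samples = read_sample_table(_require(Path(section.get("samples", out / "samples.tsv")), "scan"))
    stats = diffscan.paired_t_scan(matrix, samples)
    stats["rank_score"] = diffscan.rank_scores(matrix, samples)
    null = diffscan.permutation_null(
        matrix,
        samples,
        n_perm=int(section.get("permutations", 255)),
        scheme=section.get("scheme", "within_pair_flip"),
        seed=seed,
        keep_pvectors=False,
    )
    alpha_star, perm_min = diffscan.significance_threshold(stats, null)
    moderate_alpha = float(section.get("moderate_alpha", min(10 * alpha_star, 0.999)))
    sel = diffscan.select_candidates(stats, alpha_star, moderate_alpha)
    stats.to_csv(out / "locus_stats.tsv", sep="\t", index_label="locus", lineterminator="\n")
    pd.DataFrame({"min_p": null.min_p}).to_csv(
        out / "null_summary.tsv", sep="\t", index_label="permutation", lineterminator="\n"
    )
    sel["histogram"].to_csv(out / "p_histogram.tsv", sep="\t", index=False, lineterminator="\n")
    sel["significant"].to_csv(out / "candidates_significant.tsv", sep="\t", index_label="locus", lineterminator="\n")
    sel["moderate"].to_csv(out / "candidates_moderate.tsv", sep="\t", index_label="locus", lineterminator="\n")
    with open(out / "threshold.json", "w") as fh:
        json.dump(
            {
                "alpha_star": alpha_star,
                "permutation_min_p": perm_min,
                "scheme": null.scheme,
                "n_perm": null.n_perm,
                "n_significant": int(len(sel["significant"])),
                "n_moderate": int(len(sel["moderate"])),
            },
            fh,
            indent=2,
        )
    return [
        "locus_stats.tsv", "null_summary.tsv", "p_histogram.tsv",
        "candidates_significant.tsv", "candidates_moderate.tsv", "threshold.json",
    ]


_TRACK_KINDS = {
    "CpG_island.bed": "CpG_island",
    "CG_cluster.bed": "CG_cluster",
    "conserved.bed": "conserved",
    "repeat_RT.bed": "repeat_RT",
}


def _run_annotate(section: dict, out: Path, seed: int) -> list[str]:
    cand_path = _require(Path(section.get("candidates", out / "candidates_significant.tsv")), "annotate")
    candidates = pd.read_csv(cand_path, sep="\t", index_col="locus")
    from .io_model import GenomicInterval

    loci = {k: GenomicInterval.from_key(k) for k in candidates.index}
    tracks = []
    track_paths = section.get("tracks")
    if track_paths:
        for item in track_paths:
            tracks.append(read_intervals(Path(item["path"]), item["kind"]))
    else:
        for name, kind in _TRACK_KINDS.items():
            p = out / name
            if p.exists():
                tracks.append(read_intervals(p, kind))
    genes_path = Path(section.get("genes", out / "genes.tsv"))
    genes = read_gene_models(genes_path) if genes_path.exists() else []
    flags = ann.overlap_flags(loci, tracks)
    assignments = ann.map_to_genes(loci, genes)
    report = ann.build_candidate_report(candidates, flags, assignments, loci)
    report.to_csv(out / "candidate_report.tsv", sep="\t", index=False, lineterminator="\n")
    return ["candidate_report.tsv"]


def _run_power(section: dict, out: Path, seed: int) -> list[str]:
    config = power.PowerConfig(
        delta=float(section.get("delta", 0.60)),
        sigma=float(section.get("sigma", 0.32)),
        ns=tuple(section.get("ns", power.DEFAULT_NS)),
        alphas=tuple(section.get("alphas", power.DEFAULT_ALPHAS)),
        reps=int(section.get("reps", 200_000)),
        seed=seed,
    )
    grid = power.power_grid(config, method="simulated")
    analytic = power.power_grid(config, method="analytic")
    grid = grid.merge(
        analytic[["n", "alpha", "power"]].rename(columns={"power": "power_analytic"}),
        on=["n", "alpha"],
    )
    grid.to_csv(out / "power_grid.tsv", sep="\t", index=False, lineterminator="\n")
    return ["power_grid.tsv"]


def _run_concord(section: dict, out: Path, seed: int) -> list[str]:
    matrix = read_ratio_matrix(_require(Path(section.get("ratios", out / "matrix.tsv")), "concord"))
    bis_path = _require(Path(section.get("bisulphite", out / "bisulphite.tsv")), "concord")
    bis = pd.read_csv(bis_path, sep="\t", index_col="locus")
    paired = pd.DataFrame(
        {
            "log_ratio": matrix.values.mean(axis=1),
            "percent": bis.mean(axis=1),
        }
    )
    result = conc.platform_concordance(paired)
    result["residuals"].to_csv(out / "concord_residuals.tsv", sep="\t", index_label="locus", lineterminator="\n")
    with open(out / "concordance.json", "w") as fh:
        json.dump({k: result[k] for k in ("r", "p", "slope", "intercept", "n")}, fh, indent=2)
    return ["concord_residuals.tsv", "concordance.json"]


_RUNNERS = {
    "simulate": _run_simulate,
    "normalize": _run_normalize,
    "qc": _run_qc,
    "scan": _run_scan,
    "annotate": _run_annotate,
    "power": _run_power,
    "concord": _run_concord,
}
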