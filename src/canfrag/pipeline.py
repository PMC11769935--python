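"""End-to-end orchestration: simulate/ingest -> distributions -> oscillation stats
-> feature selection -> classification bench -> CNA consensus, with one master
seed deriving every stage seed so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cna as cna_mod
from .classify import BenchConfig, kfold_cv, repeated_holdout
from .features import FeatureSpec, build_feature_matrix, svm_rfe_select
from .fragdist import (cohort_summary, normalize, plot_cohorts, proportion_below,
                       read_manifest, summary_to_frame)
from .fragio import read_histogram_tsv
from .oscillation import DetectionParams, detect_oscillations, profile_to_rows
from .synth import (SyntheticCNAConfig, SyntheticCohortConfig, generate_cna_cohort,
                    generate_cohort)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Stage toggles plus all module configurations for one reproducible run.

    Either ``manifest_path`` (existing cohort) or ``cohort_config`` (simulate)
    must be provided.  Stage seeds are derived deterministically from ``seed``.
    """

    outdir: str = "run_output"
    seed: int = 0
    manifest_path: str | None = None
    cohort_config: SyntheticCohortConfig | None = None
    cna_config: SyntheticCNAConfig | None = None
    detection: DetectionParams = field(default_factory=DetectionParams)
    bench: BenchConfig = field(default_factory=BenchConfig)
    selection_iterations: int = 100
    selection_cutoff: float = 0.5
    run_selection: bool = True
    run_classification: bool = True
    run_cna: bool = True
    make_plots: bool = True


def _stage_seed(master: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _json_ready(obj):
    if isinstance(obj, dict):
        return {k: _json_ready(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_ready(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_json_ready(v) for v in obj.tolist()]
    return obj


def run(config: RunConfig) -> dict:
    """Execute enabled stages in order and write a machine-readable report.

    Returns the report dict; also written as ``report.json`` in ``outdir``
    along with per-stage TSV outputs. Identical (config, seed) pairs produce
    byte-identical reports.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed}

    # --- cohort: simulate or ingest -------------------------------------
    if config.manifest_path is not None:
        manifest = read_manifest(config.manifest_path)
        hists = [read_histogram_tsv(r.histogram_path, r.sample_id)
                 for r in manifest.itertuples(index=False)]
    elif config.cohort_config is not None:
        from dataclasses import replace
        cc = replace(config.cohort_config, seed=_stage_seed(config.seed, "cohort"))
        cohort = generate_cohort(cc)
        cohort.write(outdir / "cohort")
        manifest = cohort.manifest
        hists = cohort.histograms
    else:
        raise ValueError("RunConfig needs manifest_path or cohort_config")
    if manifest.empty:
        raise ValueError("empty cohort manifest")

    dists = [normalize(h) for h in hists]
    by_group: dict[str, list] = {}
    for dist, group in zip(dists, manifest["group"]):
        by_group.setdefault(group, []).append(dist)
    report["cohort_sizes"] = {g: len(v) for g, v in sorted(by_group.items())}
    logger.info("cohort: %s", report["cohort_sizes"])

    # --- distributions + oscillation statistics --------------------------
    summaries = [cohort_summary(v, g) for g, v in sorted(by_group.items())]
    summary_to_frame(summaries).to_csv(outdir / "cohort_summary.tsv", sep="\t",
                                       index=False, lineterminator="\n")
    osc_rows = []
    report["oscillation"] = {}
    for s in summaries:
        profile = detect_oscillations(s.mean_distribution(), config.detection)
        osc_rows.extend(profile_to_rows(profile, s.group_label))
        report["oscillation"][s.group_label] = {
            "main_peak_bp": profile.main_peak_bp,
            "n_cycles": profile.n_cycles,
            "peak_positions": profile.peak_positions.tolist(),
            "peak_densities": [round(float(x), 6) for x in profile.peak_densities],
            "valley_densities": [round(float(x), 6) for x in profile.valley_densities],
            "diffs": [round(float(x), 6) for x in profile.diffs],
            "proportion_below_174": round(
                proportion_below(s.mean_distribution(), 174), 6),
        }
    pd.DataFrame(osc_rows).to_csv(outdir / "oscillation.tsv", sep="\t",
                                  index=False, lineterminator="\n")
    if config.make_plots:
        plot_cohorts(summaries, outdir / "fragment_sizes.png")

    labels = list(manifest["group"])

    # --- SVM-RFE feature selection ---------------------------------------
    if config.run_selection:
        fm = build_feature_matrix(dists, labels, FeatureSpec("full_grid"))
        sel = svm_rfe_select(fm, n_iterations=config.selection_iterations,
                             frequency_cutoff=config.selection_cutoff,
                             seed=_stage_seed(config.seed, "selection"))
        pd.DataFrame({"position_bp": sel.positions,
                      "frequency": sel.selection_frequency}).to_csv(
            outdir / "selection_frequency.tsv", sep="\t", index=False,
            lineterminator="\n")
        with open(outdir / "selected_regions.bed", "w") as fh:
            for lo, hi in sel.selected_regions:
                fh.write(f"sizegrid\t{lo}\t{hi + 1}\tselected\n")
        report["selection"] = {"regions": [[int(a), int(b)] for a, b in
                                           sel.selected_regions]}

    # --- classification bench --------------------------------------------
    if config.run_classification:
        from dataclasses import replace
        bench = replace(config.bench, seed=_stage_seed(config.seed, "bench"))
        fm = build_feature_matrix(dists, labels, FeatureSpec("full_grid"))
        hold = repeated_holdout(fm, bench)
        cv = kfold_cv(fm, bench)
        hold.table.to_csv(outdir / "classification_holdout.tsv", sep="\t",
                          index=False, lineterminator="\n")
        cv.table.to_csv(outdir / "classification_kfold.tsv", sep="\t",
                        index=False, lineterminator="\n")
        report["classification"] = {
            "holdout": {r["algorithm"]: round(r["auc"], 4)
                        for _, r in hold.table.iterrows()},
            "kfold": {r["algorithm"]: round(r["auc"], 4)
                      for _, r in cv.table.iterrows()},
        }

    # --- CNA consensus -----------------------------------------------------
    if config.run_cna:
        from dataclasses import replace
        cna_cfg = config.cna_config or SyntheticCNAConfig()
        cna_cfg = replace(cna_cfg, seed=_stage_seed(config.seed, "cna"))
        cohort = generate_cna_cohort(cna_cfg)
        panel = cna_mod.PanelOfNormals.build(
            [cohort.bins[s] for s in cohort.normal_ids])
        consensus = []
        for sid in cohort.tumor_ids:
            corrected = cna_mod.correct_bias(cohort.bins[sid], panel, sid)
            a = cna_mod.call_states(corrected, cna_mod.CALLER_A)
            b = cna_mod.call_states(corrected, cna_mod.CALLER_B)
            consensus.append(cna_mod.intersect_callsets(a, b))
        grid = next(iter(cohort.bins.values()))
        recur = cna_mod.recurrence_filter(
            consensus, grid,
            cna_mod.ConsensusConfig(n_samples=len(cohort.tumor_ids)))
        recur.regions.to_csv(outdir / "recurrent_cna.tsv", sep="\t", index=False,
                             lineterminator="\n")
        cna_mod.write_calls_bed(recur.regions, outdir / "recurrent_cna.bed")
        report["cna"] = {"gain_chromosomes": recur.chromosomes["gain"],
                         "loss_chromosomes": recur.chromosomes["loss"]}

    report_json = json.dumps(_json_ready(report), indent=1, sort_keys=True)
    (outdir / "report.json").write_text(report_json + "\n")
    return report
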