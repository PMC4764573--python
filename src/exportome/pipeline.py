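"""End-to-end orchestration: simulate, quantify/partition, classify, report.

Each stage reads and writes plain TSV artifacts in a working directory and
records a JSON run manifest, so a run can be audited and reproduced
bit-for-bit for its deterministic outputs.  These functions are the
library-level equivalent of pipeline subcommands; ``full_run`` chains all
stages on a synthetic dataset.
"""

from __future__ import annotations

import dataclasses
import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, quantify, summary
from .cargo import classify_experiment
from .config import RunConfig
from .simulate import (
    SimulationParams,
    generate_ground_truth,
    make_spike_standard,
    proteoform_map_from_truth,
    simulate_affinity_experiment,
    simulate_fraction_intensities,
)

__version__ = "0.1.0"


def _write_manifest(outdir: Path, stage: str, seed: int | None, inputs: dict) -> None:
    manifest = {
        "stage": stage,
        "tool_version": __version__,
        "seed": seed,
        "inputs": inputs,
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    with open(outdir / f"manifest_{stage}.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


def run_simulate(
    outdir,
    params: SimulationParams,
    n_proteins: int = 2000,
    n_replicates: int = 3,
    keep_fraction: float = 0.035,
) -> dict[str, Path]:
    """Generate a full synthetic dataset on disk: truth table, fraction and
    affinity intensity tables (with manifests), spike table, proteoform map,
    and contaminant flag/keep lists (a ``keep_fraction`` of flagged proteins
    is manually 'kept', mirroring the curation step)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    truth = generate_ground_truth(n_proteins, params)
    spike = make_spike_standard(6, 8, 0.5, 10.0)
    fraction = simulate_fraction_intensities(truth, spike, params, n_replicates)
    affinity = simulate_affinity_experiment(truth, params)
    pmap = proteoform_map_from_truth(truth)

    flags = set(truth.loc[truth["is_contaminant"], "protein_id"])
    rng = np.random.default_rng([params.seed, 3])
    flagged_sorted = sorted(flags)
    keep = set(
        np.array(flagged_sorted)[
            rng.random(len(flagged_sorted)) < keep_fraction
        ]
    ) if flagged_sorted else set()

    paths = {
        "truth": outdir / "truth.tsv",
        "spike": outdir / "spike.tsv",
        "fraction": outdir / "fraction_intensities.tsv",
        "fraction_manifest": outdir / "fraction_intensities.manifest.tsv",
        "affinity": outdir / "affinity_intensities.tsv",
        "affinity_manifest": outdir / "affinity_intensities.manifest.tsv",
        "proteoform_map": outdir / "proteoform_map.tsv",
        "flags": outdir / "contaminant_flags.txt",
        "keep": outdir / "contaminant_keep.txt",
    }
    io.write_truth_table(truth, paths["truth"])
    io.write_spike_table(spike, paths["spike"])
    io.write_intensity_table(fraction, paths["fraction"], paths["fraction_manifest"])
    io.write_intensity_table(affinity, paths["affinity"], paths["affinity_manifest"])
    pmap.to_csv(paths["proteoform_map"], sep="\t", index=False)
    io.write_list(flags, paths["flags"])
    io.write_list(keep, paths["keep"])
    _write_manifest(
        outdir,
        "simulate",
        params.seed,
        {"n_proteins": n_proteins, "n_replicates": n_replicates,
         "params": dataclasses.asdict(params) | {"volumes": dict(params.volumes)}},
    )
    return paths


def run_partition(workdir, config: RunConfig) -> dict[str, Path]:
    """Quantify the fractionation experiment: filter, merge proteoforms,
    calibrate against the spike-in standard, estimate concentrations, apply
    contaminant flags and write the partition report."""
    workdir = Path(workdir)
    spike = io.read_spike_table(workdir / "spike.tsv")
    manifest = io.read_manifest(workdir / "fraction_intensities.manifest.tsv")
    table = io.read_intensity_table(workdir / "fraction_intensities.tsv", manifest)
    pmap = io.read_proteoform_map(workdir / "proteoform_map.tsv")

    filtered, filter_log = quantify.filter_records(table, config, mode="partition")
    merged = quantify.merge_proteoforms(filtered, pmap)
    curves = quantify.fit_all_calibrations(spike, merged)
    standards = set(spike["standard_id"])
    proteins = merged[~merged["protein_id"].isin(standards)]
    concentrations = quantify.estimate_concentrations(proteins, curves, config)
    records = quantify.compute_partition(concentrations, config)

    flags = io.read_lists(workdir / "contaminant_flags.txt") \
        if (workdir / "contaminant_flags.txt").exists() else set()
    keep = io.read_lists(workdir / "contaminant_keep.txt") \
        if (workdir / "contaminant_keep.txt").exists() else set()
    records, flag_counts = quantify.apply_contaminant_flags(records, flags, keep)

    calib = pd.DataFrame(
        [dataclasses.asdict(c) for c in curves.values()]
    ).sort_values("replicate_id")

    paths = {
        "partition_report": io.write_reports(records, None, workdir)["partition"],
        "partition_filter_log": workdir / "filter_log.tsv",
        "calibration": workdir / "calibration.tsv",
        "flag_counts": workdir / "flag_counts.json",
    }
    io.write_filter_log(filter_log, paths["partition_filter_log"])
    calib.to_csv(paths["calibration"], sep="\t", index=False)
    with open(paths["flag_counts"], "w", encoding="utf-8") as fh:
        json.dump(flag_counts, fh, indent=2, sort_keys=True)
    _write_manifest(workdir, "partition", config.seed, {"config": str(config)})
    return paths


def run_classify(workdir, config: RunConfig, machinery=None) -> dict[str, Path]:
    """Score and categorise the affinity experiment; writes the cargo report
    and the category census."""
    workdir = Path(workdir)
    manifest = io.read_manifest(workdir / "affinity_intensities.manifest.tsv")
    table = io.read_intensity_table(workdir / "affinity_intensities.tsv", manifest)
    pmap = io.read_proteoform_map(workdir / "proteoform_map.tsv")
    if machinery is None and (workdir / "machinery.tsv").exists():
        machinery = io.read_machinery(workdir / "machinery.tsv")

    filtered, filter_log = quantify.filter_records(table, config, mode="cargo")
    merged = quantify.merge_proteoforms(filtered, pmap)
    scores, census = classify_experiment(merged, config, machinery)

    paths = {
        "cargo_report": io.write_reports(None, scores, workdir)["cargo"],
        "census": workdir / "category_census.tsv",
        "cargo_filter_log": workdir / "cargo_filter_log.tsv",
    }
    census.to_csv(paths["census"], sep="\t", index=False)
    io.write_filter_log(filter_log, paths["cargo_filter_log"])
    _write_manifest(workdir, "classify", config.seed, {"config": str(config)})
    return paths


def run_report(workdir, config: RunConfig, bandwidth: float | None = None) -> dict[str, Path]:
    """Summaries over the partition report: Venn bookkeeping and, when a
    ``groups.tsv`` file is present, per-functional-group density curves."""
    workdir = Path(workdir)
    records = io.read_partition_report(workdir / "partition_report.tsv")
    counts = summary.venn_counts(records)
    paths = {"venn": workdir / "venn.tsv"}
    pd.DataFrame([counts]).to_csv(paths["venn"], sep="\t", index=False)

    groups_path = workdir / "groups.tsv"
    if groups_path.exists():
        groups = summary.read_groups(groups_path)
        curves = summary.group_densities(records, groups, bandwidth=bandwidth)
        for p in summary.write_densities(curves, workdir / "densities"):
            paths[p.stem] = p
    _write_manifest(workdir, "report", config.seed, {"config": str(config)})
    return paths


def full_run(
    outdir,
    params: SimulationParams | None = None,
    config: RunConfig | None = None,
    n_proteins: int = 2000,
    n_replicates: int = 3,
) -> dict[str, Path]:
    """Simulate a dataset and push it through every downstream stage."""
    params = params or SimulationParams()
    config = config or RunConfig(seed=params.seed)
    paths = run_simulate(outdir, params, n_proteins, n_replicates)
    paths |= run_partition(outdir, config)
    paths |= run_classify(outdir, config)
    paths |= run_report(outdir, config)
    return paths
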