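"""End-to-end orchestration: simulate -> select -> connect -> cluster ->
netcorr -> hubs, with a reproducible run directory.

Every stage writes its outputs into its own subdirectory; a manifest records
the configuration snapshot, the seed, and a SHA-256 digest of every output
file, so a run can be replayed and verified bit for bit.  All randomness
flows from the single cohort seed (the generator derives independent
per-stage streams from it).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import WardNetworkClusterer
from .config import PipelineConfig, log_stage
from .connectivity import (
    correlation_to_dissimilarity,
    fisher_group_average,
    stack_from_timeseries,
    write_matrix_tsv,
)
from .hubs import HubDetector
from .netstats import InterNetworkSignTest
from .selection import ConjunctionSelector
from .simulate import CohortConfig, planted_truth, simulate_contrasts, simulate_rest_timeseries

__all__ = ["PipelineResult", "run_pipeline", "replay"]

STAGES = ("simulate", "select", "connect", "cluster", "netcorr", "hubs")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


@dataclass
class PipelineResult:
    """In-memory artifacts of a full run."""

    run_dir: Path
    selection: object
    group_correlation: np.ndarray
    dissimilarity: np.ndarray
    cluster_labels: dict
    optimal_k: int
    network_members: dict
    netcorr: pd.DataFrame
    hub_detector: HubDetector
    truth: object


def run_pipeline(
    cohort_cfg: CohortConfig,
    pipe_cfg: PipelineConfig | None = None,
    out_dir: str | Path = "alans_run",
    persist_timeseries: bool = True,
) -> PipelineResult:
    """Run every stage on a synthetic cohort and persist a run directory.

    Stage outputs are plain TSV/JSON so each stage can also be re-run
    independently from the persisted intermediates (see the CLI).
    """
    pipe_cfg = pipe_cfg or PipelineConfig(rng_seed=cohort_cfg.rng_seed)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    digests: dict[str, dict[str, str]] = {}

    def record(stage: str, *paths: Path) -> None:
        digests.setdefault(stage, {})
        for p in paths:
            digests[stage][str(p.relative_to(out))] = _sha256(p)

    # --- simulate -----------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    contrasts = simulate_contrasts(cohort_cfg)
    panel = simulate_rest_timeseries(cohort_cfg)
    truth = planted_truth(cohort_cfg)
    log_stage("simulate", participants=cohort_cfg.n_participants,
              pairs=contrasts.n_pairs, regions=len(panel.region_ids),
              timepoints=cohort_cfg.n_timepoints)
    contrasts.to_tsv(sim_dir / "contrasts.tsv")
    (sim_dir / "truth.json").write_text(json.dumps(_jsonable({
        "selected_regions": sorted(truth.selected_regions),
        "module_labels": truth.module_labels,
        "hub_regions": sorted(truth.hub_regions),
    }), indent=2))
    record("simulate", sim_dir / "contrasts.tsv", sim_dir / "truth.json")
    if persist_timeseries:
        panel.to_dir(sim_dir / "timeseries")
        record("simulate", *sorted((sim_dir / "timeseries").glob("*.tsv")))

    # --- select -------------------------------------------------------------
    sel_dir = out / "select"
    sel_dir.mkdir(exist_ok=True)
    selector = ConjunctionSelector(
        alpha_family=pipe_cfg.alpha_family, n_pairs=pipe_cfg.n_pairs
    ).fit(contrasts)
    result = selector.result_
    log_stage("select", selected=selector.n_selected_,
              per_test_alpha=f"{result.per_test_alpha:.3e}")
    result.to_tsv(sel_dir / "selection.tsv")
    (sel_dir / "meta.json").write_text(json.dumps({
        "per_test_alpha": result.per_test_alpha,
        "conjunction_alpha": result.conjunction_alpha,
        "alpha_family": result.alpha_family,
        "n_pairs_corrected": result.n_pairs_corrected,
    }, indent=2))
    record("select", sel_dir / "selection.tsv", sel_dir / "meta.json")

    # --- connect ------------------------------------------------------------
    con_dir = out / "connect"
    con_dir.mkdir(exist_ok=True)
    selected_ids = [pair for pair, _ in result.selected_regions]
    with_series = [r for r in selected_ids if r in panel.region_ids]
    if not with_series:
        raise RuntimeError("stage connect failed: no selected region has a "
                           "rest time series")
    idx = [panel.region_ids.index(r) for r in with_series]
    stack = stack_from_timeseries(panel.data[:, idx, :], with_series,
                                  panel.participant_ids)
    group = fisher_group_average(stack)
    dissim = correlation_to_dissimilarity(group, rule=pipe_cfg.dissimilarity_rule)
    log_stage("connect", regions=len(with_series))
    write_matrix_tsv(group, with_series, con_dir / "group_correlation.tsv")
    write_matrix_tsv(dissim, with_series, con_dir / "dissimilarity.tsv")
    record("connect", con_dir / "group_correlation.tsv", con_dir / "dissimilarity.tsv")

    # --- cluster ------------------------------------------------------------
    clu_dir = out / "cluster"
    clu_dir.mkdir(exist_ok=True)
    clusterer = WardNetworkClusterer(k_range=pipe_cfg.k_range).fit(dissim)
    labels = dict(zip(with_series, (int(x) for x in clusterer.labels_)))
    members: dict[str, list[str]] = {}
    for region, lab in labels.items():
        members.setdefault(f"N{lab + 1}", []).append(region)
    log_stage("cluster", k=clusterer.n_clusters_)
    pd.DataFrame({"region": list(labels), "cluster": list(labels.values())}).to_csv(
        clu_dir / "labels.tsv", sep="\t", index=False
    )
    clusterer.index_votes_.to_csv(clu_dir / "index_votes.tsv", sep="\t", index=False)
    clusterer.solution(with_series).merge_table().to_csv(
        clu_dir / "merge_tree.tsv", sep="\t", index=False
    )
    record("cluster", clu_dir / "labels.tsv", clu_dir / "index_votes.tsv",
           clu_dir / "merge_tree.tsv")

    # --- netcorr ------------------------------------------------------------
    net_dir = out / "netcorr"
    net_dir.mkdir(exist_ok=True)
    tester = InterNetworkSignTest(alpha_family=pipe_cfg.alpha_family).fit(
        stack, members
    )
    log_stage("netcorr", pairs=len(tester.results_),
              adjusted_alpha=tester.adjusted_alpha_)
    tester.results_.to_csv(net_dir / "network_pairs.tsv", sep="\t", index=False)
    record("netcorr", net_dir / "network_pairs.tsv")

    # --- hubs ---------------------------------------------------------------
    hub_dir = out / "hubs"
    hub_dir.mkdir(exist_ok=True)
    detector = HubDetector(
        edge_length_rule=pipe_cfg.edge_length_rule,
        bc_normalized=pipe_cfg.bc_normalized,
        ci_level=pipe_cfg.ci_level,
    ).fit(stack, members)
    log_stage("hubs", hubs=sum(len(h) for h in detector.hubs_.values()))
    detector.region_table().to_csv(hub_dir / "regions.tsv", sep="\t", index=False)
    detector.network_table().to_csv(hub_dir / "networks.tsv", sep="\t", index=False)
    record("hubs", hub_dir / "regions.tsv", hub_dir / "networks.tsv")

    manifest = {
        "tool_version": __version__,
        "seed": cohort_cfg.rng_seed,
        "pipeline_config": _jsonable(dataclasses.asdict(pipe_cfg)),
        "cohort_config": _jsonable(dataclasses.asdict(cohort_cfg)),
        "stages": [{"name": s, "outputs": digests.get(s, {})} for s in STAGES],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    return PipelineResult(
        run_dir=out,
        selection=result,
        group_correlation=group,
        dissimilarity=dissim,
        cluster_labels=labels,
        optimal_k=clusterer.n_clusters_,
        network_members=members,
        netcorr=tester.results_,
        hub_detector=detector,
        truth=truth,
    )


def replay(run_dir: str | Path) -> dict:
    """Verify a run directory against its manifest digests.

    Returns ``{"ok": bool, "stages": {stage: {file: matches}}, "first_divergent_stage": ...}``.
    Missing files raise a structured error naming the file.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"missing manifest: {manifest_path}")
    manifest = json.loads(manifest_path.read_text())
    report: dict = {"ok": True, "stages": {}, "first_divergent_stage": None}
    for stage in manifest["stages"]:
        name = stage["name"]
        report["stages"][name] = {}
        for rel, digest in stage["outputs"].items():
            path = run_dir / rel
            if not path.exists():
                raise FileNotFoundError(f"stage {name!r}: missing output file {path}")
            try:
                ok = _sha256(path) == digest
            except OSError as exc:
                raise OSError(f"stage {name!r}: unreadable output file {path}") from exc
            report["stages"][name][rel] = ok
            if not ok:
                report["ok"] = False
                if report["first_divergent_stage"] is None:
                    report["first_divergent_stage"] = name
    return report
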