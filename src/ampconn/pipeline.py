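"""End-to-end orchestration of the amplitude-connectivity analysis.

``run_pipeline`` drives the whole flow — synthetic cohort (or user data) ->
stage connectivity -> thresholded graphs -> island continuum -> node metrics
-> coupling statistics -> node classification -> exports — and records every
output with a checksum in a JSON manifest, so that a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from ampconn import io as aio
from ampconn.couplingstats import (
    CouplingResult,
    amplitude_group_ttest,
    coupling_frame,
    coupling_profile,
    partial_correlation,
    permutation_group_difference,
)
from ampconn.netbuild import (
    DEFAULT_THRESHOLD,
    IslandHierarchy,
    build_graph,
    default_m_values,
)
from ampconn.netmetrics import METRIC_COLUMNS, island_metrics
from ampconn.nodeclass import (
    aggregate_to_original,
    classification_table,
    export_four_color_network,
)
from ampconn.phaseconn import subject_stage_analysis
from ampconn.synthcohort import (
    GROUPS,
    STAGE_WINDOWS,
    EpochSet,
    RoiAtlas,
    SynthConfig,
    generate_cohort,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "coupling_experiment"]

MEASURES = [c for c in METRIC_COLUMNS if c != "amplitude"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``synth`` holds the cohort generator parameters; ``epoch_paths`` and
    ``atlas_path`` may instead point at user data (epoch .npy/.json prefixes
    and an atlas TSV).  Statistical defaults mirror the study design: edge
    threshold 1.96, 1000 permutations, island minimum size 3.
    """

    synth: SynthConfig = field(default_factory=SynthConfig)
    epoch_paths: Optional[List[str]] = None
    atlas_path: Optional[str] = None
    stages: Optional[List[str]] = None  # None -> all six naming stages
    m_values: Optional[List[int]] = None  # None -> 50..750 step 50 + n/2 + n
    threshold: float = DEFAULT_THRESHOLD
    n_perm: int = 1000
    n_boot: int = 200
    boot_stride: int = 1
    measures: List[str] = field(default_factory=lambda: list(MEASURES))
    perm_measures: List[str] = field(default_factory=lambda: ["DEG", "EIG"])
    stats_seed: int = 1234
    outdir: str = "ampconn_out"

    def resolved_stages(self) -> List[str]:
        return self.stages or [label for label, *_ in STAGE_WINDOWS]

    def resolved_m_values(self, n_roi: int) -> List[int]:
        if self.m_values:
            return list(self.m_values)
        return [m for m in default_m_values(n_roi) if m <= n_roi] or [n_roi]

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["synth"] = dataclasses.asdict(self.synth)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        synth = payload.pop("synth", {})
        if isinstance(synth.get("coupling_rho"), list):
            synth["coupling_rho"] = dict(zip(GROUPS, synth["coupling_rho"]))
        for key in ("epoch_window", "band", "kappa_range", "amp_range"):
            if key in synth and isinstance(synth[key], list):
                synth[key] = tuple(synth[key])
        return cls(synth=SynthConfig(**synth), **payload)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _load_inputs(config: RunConfig) -> Tuple[List[EpochSet], RoiAtlas, object]:
    if config.epoch_paths:
        if not config.atlas_path:
            raise ValueError("atlas_path is required when epoch_paths are given")
        epochs = [aio.load_epochs(p) for p in config.epoch_paths]
        atlas = RoiAtlas.from_tsv(config.atlas_path)
        return epochs, atlas, None
    epochs, atlas, truth = generate_cohort(config.synth)
    return epochs, atlas, truth


def run_pipeline(config: RunConfig) -> Dict:
    """Run the full analysis; returns the manifest (also written to disk).

    On partial failure the manifest records the completed stages before the
    exception propagates.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "config": yaml.safe_load(_config_yaml(config)),
        "completed": [],
        "outputs": {},
    }
    manifest_path = outdir / "manifest.json"

    def checkpoint(step: str, files: Mapping[str, Path] | None = None) -> None:
        manifest["completed"].append(step)
        for key, p in (files or {}).items():
            manifest["outputs"][key] = {"path": str(p), "sha256": _sha256(Path(p))}
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    try:
        epochs, atlas, _truth = _load_inputs(config)
        atlas_path = outdir / "atlas.tsv"
        atlas.to_tsv(atlas_path)
        checkpoint("inputs", {"atlas": atlas_path})

        stages = config.resolved_stages()
        labels = atlas.refined_ids
        partition = atlas.module_of()
        band = config.synth.band
        n_roi = len(labels)
        m_values = config.resolved_m_values(n_roi)

        # stage connectivity and amplitudes per subject
        conn_files: Dict[str, Path] = {}
        subject_conn: Dict[str, Dict] = {}
        subject_amp: Dict[str, Dict] = {}
        for i, ep in enumerate(epochs):
            conn, amp = subject_stage_analysis(
                ep,
                stages=stages,
                band=band,
                n_boot=config.n_boot,
                seed=config.stats_seed + 1000 * i,
                sample_stride=config.boot_stride,
            )
            subject_conn[ep.subject_id] = conn
            subject_amp[ep.subject_id] = amp
            for stage, sc in conn.items():
                p = outdir / "connectivity" / f"{ep.subject_id}_{stage}_z.tsv"
                p.parent.mkdir(parents=True, exist_ok=True)
                aio.write_matrix_tsv(sc.z, labels, p)
                conn_files[f"z_{ep.subject_id}_{stage}"] = p
        checkpoint("connectivity", conn_files)

        # per-subject metrics across the island continuum
        rows = []
        for ep in epochs:
            for stage in stages:
                sc = subject_conn[ep.subject_id][stage]
                g = build_graph(sc, config.threshold, labels=labels, partition=partition)
                hierarchy = IslandHierarchy(g)
                amps = dict(zip(labels, subject_amp[ep.subject_id][stage].amplitude))
                for m in m_values:
                    islands = hierarchy.islands(max_size=m)
                    tbl = island_metrics(g, islands, amps, partition)
                    if tbl.empty:
                        continue
                    tbl = tbl.reset_index()
                    tbl.insert(0, "group", ep.group)
                    tbl.insert(1, "subject", ep.subject_id)
                    tbl.insert(2, "stage", stage)
                    tbl.insert(3, "m", m)
                    rows.append(tbl)
        metrics_long = (
            pd.concat(rows, ignore_index=True)
            if rows
            else pd.DataFrame(
                columns=["group", "subject", "stage", "m", "node", *METRIC_COLUMNS]
            )
        )
        metrics_path = outdir / "node_metrics.tsv"
        metrics_long.to_csv(metrics_path, sep="\t", index=False)
        checkpoint("metrics", {"node_metrics": metrics_path})

        # coupling statistics
        coupling_results: List[CouplingResult] = []
        for measure in config.measures:
            coupling_results.extend(coupling_profile(metrics_long, measure, m_values, stages))
        coupling_path = outdir / "coupling.tsv"
        coupling_frame(coupling_results).to_csv(coupling_path, sep="\t", index=False)

        perm_rows = []
        m_top = max(m_values)
        groups_of = {ep.subject_id: ep.group for ep in epochs}
        if len(set(groups_of.values())) == 2:
            for stage in stages:
                for measure in config.perm_measures:
                    cell = metrics_long[
                        (metrics_long["stage"] == stage) & (metrics_long["m"] == m_top)
                    ].dropna(subset=["amplitude", measure])
                    data = {
                        s: (
                            sub["amplitude"].to_numpy(),
                            sub[measure].to_numpy(),
                        )
                        for s, sub in cell.groupby("subject")
                    }
                    if len(data) < 4:
                        continue
                    res = permutation_group_difference(
                        data,
                        {s: groups_of[s] for s in data},
                        n_perm=config.n_perm,
                        seed=config.stats_seed,
                    )
                    perm_rows.append(
                        {
                            "stage": stage,
                            "m": m_top,
                            "measure": measure,
                            "observed_diff": res.observed_diff,
                            "perm_ci_low": res.perm_ci_low,
                            "perm_ci_high": res.perm_ci_high,
                            "significant": res.significant,
                            **{f"r_{g}": r for g, r in res.r_by_group.items()},
                        }
                    )
        perm_path = outdir / "group_permutation.tsv"
        pd.DataFrame(perm_rows).to_csv(perm_path, sep="\t", index=False)
        checkpoint("coupling", {"coupling": coupling_path, "group_permutation": perm_path})

        # group-averaged networks: classification and exports
        class_files: Dict[str, Path] = {}
        class_frames = []
        original_of = atlas.original_of()
        for group in sorted(set(groups_of.values())):
            members = [ep.subject_id for ep in epochs if ep.group == group]
            for stage in stages:
                z_mean = np.mean([subject_conn[s][stage].z for s in members], axis=0)
                amp_z = np.mean([subject_amp[s][stage].z for s in members], axis=0)
                g = build_graph(z_mean, config.threshold, labels=labels, partition=partition)
                islands = IslandHierarchy(g).islands(max_size=n_roi)
                island_nodes = sorted(islands.nodes, key=str)
                if len(island_nodes) < 2:
                    continue
                sub = g.subgraph(island_nodes).copy()
                tbl = classification_table(
                    sub, dict(zip(labels, amp_z)), stage=stage, group=group
                )
                class_frames.append(tbl.reset_index())
                hothubs = aggregate_to_original(tbl, atlas)
                hot_path = outdir / "classification" / f"{group}_{stage}_hothubs.tsv"
                hot_path.parent.mkdir(parents=True, exist_ok=True)
                hothubs.to_csv(hot_path, sep="\t", index=False)
                class_files[f"hothubs_{group}_{stage}"] = hot_path
                exports = export_four_color_network(
                    sub, tbl, outdir / "networks" / f"{group}_{stage}"
                )
                for kind, p in exports.items():
                    class_files[f"net_{group}_{stage}_{kind}"] = p
        class_path = outdir / "classification.tsv"
        (
            pd.concat(class_frames, ignore_index=True)
            if class_frames
            else pd.DataFrame()
        ).to_csv(class_path, sep="\t", index=False)
        class_files["classification"] = class_path
        checkpoint("classification", class_files)

        # amplitude permutation t-tests at the original-scout level
        if len(set(groups_of.values())) == 2:
            ttest_files = {}
            for stage in stages:
                rows_z = {}
                for ep in epochs:
                    z = pd.Series(subject_amp[ep.subject_id][stage].z, index=labels)
                    rows_z[ep.subject_id] = z.groupby(
                        z.index.map(original_of)
                    ).mean()
                z_table = pd.DataFrame(rows_z).T
                res = amplitude_group_ttest(
                    z_table,
                    groups_of,
                    n_perm=config.n_perm,
                    seed=config.stats_seed,
                )
                p = outdir / "amplitude_tests" / f"{stage}_ttest.tsv"
                p.parent.mkdir(parents=True, exist_ok=True)
                res.to_csv(p, sep="\t")
                ttest_files[f"amplitude_ttest_{stage}"] = p
            checkpoint("amplitude_tests", ttest_files)

        checkpoint("done")
    except Exception:
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    return manifest


def _config_yaml(config: RunConfig) -> str:
    payload = dataclasses.asdict(config)
    payload["synth"] = dataclasses.asdict(config.synth)
    return yaml.safe_dump(payload, sort_keys=False)


def validate_inputs(paths: Mapping[str, object]) -> List[str]:
    """Validate user inputs; returns a list of human-readable problems.

    ``paths`` may carry ``connectivity`` (list of square matrix TSVs),
    ``atlas`` (atlas TSV) and ``epochs`` (list of epoch path prefixes).  An
    empty report means all checks passed.
    """
    report: List[str] = []
    atlas = None
    if paths.get("atlas"):
        try:
            atlas = RoiAtlas.from_tsv(paths["atlas"])
        except Exception as exc:
            report.append(f"atlas {paths['atlas']}: unreadable ({exc})")
    for mp in paths.get("connectivity", []) or []:
        try:
            mat, labels = aio.read_matrix_tsv(mp)
        except Exception as exc:
            report.append(f"connectivity {mp}: unreadable ({exc})")
            continue
        if mat.shape[0] != mat.shape[1]:
            report.append(f"connectivity {mp}: matrix is not square {mat.shape}")
            continue
        asym = np.abs(mat - mat.T)
        if asym.max() > 1e-9:
            i, j = np.unravel_index(np.argmax(asym), asym.shape)
            report.append(
                f"connectivity {mp}: not symmetric at ({labels[i]}, {labels[j]})"
            )
        if atlas is not None:
            known = set(atlas.refined_ids)
            missing = [l for l in labels if l not in known]
            if missing:
                report.append(
                    f"connectivity {mp}: atlas misses nodes {missing[:5]}"
                )
    for prefix in paths.get("epochs", []) or []:
        try:
            ep = aio.load_epochs(prefix)
        except Exception as exc:
            report.append(f"epochs {prefix}: unreadable ({exc})")
            continue
        if ep.n_trials < 2:
            report.append(f"epochs {prefix}: fewer than 2 trials")
        if atlas is not None:
            known = set(atlas.refined_ids)
            missing = [l for l in ep.roi_labels if l not in known]
            if missing:
                report.append(f"epochs {prefix}: atlas misses ROIs {missing[:5]}")
    return report


# ---------------------------------------------------------------------------
# compact experiment driver (simulation studies and acceptance checks)
# ---------------------------------------------------------------------------


def coupling_experiment(
    config: SynthConfig,
    stage: str = "t4",
    measure: str = "DEG",
    threshold: float = DEFAULT_THRESHOLD,
    n_boot: int = 30,
    boot_stride: int = 4,
    n_perm: int = 1000,
    stats_seed: int | None = None,
    single_precision: bool = True,
) -> Dict:
    """One cohort -> single-stage coupling analysis, compactly.

    Generates a cohort, computes the stage connectivity of every subject,
    thresholds, decomposes into whole-graph islands, computes the requested
    measure, and returns per-group subject-adjusted coupling coefficients
    plus the group-difference permutation test.
    """
    epochs, atlas, truth = generate_cohort(config)
    labels = atlas.refined_ids
    partition = atlas.module_of()
    n_roi = len(labels)
    data: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    groups_of: Dict[str, str] = {}
    per_group: Dict[str, Dict[str, list]] = {}
    for i, ep in enumerate(epochs):
        conn, amp = subject_stage_analysis(
            ep,
            stages=[stage],
            band=config.band,
            n_boot=n_boot,
            seed=(stats_seed or 0) + 7919 * i,
            sample_stride=boot_stride,
            single_precision=single_precision,
        )
        g = build_graph(conn[stage], threshold, labels=labels, partition=partition)
        islands = IslandHierarchy(g).islands(max_size=n_roi)
        amps = dict(zip(labels, amp[stage].amplitude))
        tbl = island_metrics(g, islands, amps, partition)
        if tbl.empty:
            continue
        x = tbl["amplitude"].to_numpy()
        y = tbl[measure].to_numpy()
        data[ep.subject_id] = (x, y)
        groups_of[ep.subject_id] = ep.group
        bucket = per_group.setdefault(ep.group, {"x": [], "y": [], "subject": []})
        bucket["x"].extend(x)
        bucket["y"].extend(y)
        bucket["subject"].extend([ep.subject_id] * len(x))

    group_results = {}
    for group, bucket in per_group.items():
        r, ci, p = partial_correlation(bucket["x"], bucket["y"], bucket["subject"])
        group_results[group] = {"r": r, "ci": ci, "p": p, "n_obs": len(bucket["x"])}
    perm = None
    if len(per_group) == 2 and all(
        sum(1 for s in groups_of if groups_of[s] == g) >= 2 for g in per_group
    ):
        perm = permutation_group_difference(
            data,
            groups_of,
            n_perm=n_perm,
            # keep the permutation stream disjoint from the bootstrap streams
            seed=None if stats_seed is None else stats_seed + 999331,
        )
    return {"groups": group_results, "permutation": perm, "truth": truth}
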