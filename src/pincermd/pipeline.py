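"""End-to-end comparative study over multiple proteins and replicates.

``run_study`` composes the whole analysis: per-protein structural metrics
(RMSD per domain, RMSF, radius of gyration, SASA, interdomain COM distances),
the cross-replicate EWMA + Kolmogorov-Smirnov verdict grid over all protein
pairs, Frechet matrices on RMSF curves for named selections, jaw-distance
time-lag synchronization, clustering with medoid extraction, open/closed
state representatives, 2-D medoid projection, weak-interaction catalogues and
conserved-segment detection, plus a run manifest that reproduces every number
in the bundle.  Stage outputs are pure functions of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import itertools
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import catalog_to_table, unique_contact_catalog
from .metrics import (MetricSeries, interdomain_distances, radius_of_gyration,
                      rmsd_series, rmsf, sasa_series)
from .states import (ClusterConfig, EmbedConfig, cluster_frames,
                     extract_medoids, map_residues, select_state_representatives,
                     smooth_normalize, stack_and_project, time_lag)
from .stats import (EwmaSpec, VerdictRule, ewma, frechet_distance, ks_compare,
                    replicate_verdict)
from .segments import longest_common_segments
from .trajio import (DomainMap, Selection, Trajectory, read_domain_map,
                     read_fasta, read_topology, read_trajectory,
                     write_json, write_table, write_topology_pdb)

logger = logging.getLogger("pincermd")

__all__ = ["ProteinInput", "StudyConfig", "StageError", "run_study",
           "load_study_config"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ProteinInput:
    """One protein's trajectories (in memory or by path) plus annotations."""

    name: str
    replicates: list[Trajectory] = field(default_factory=list)
    domain_map: DomainMap | None = None
    selections: dict[str, Selection] = field(default_factory=dict)
    sequence: str | None = None
    # path-based loading (CLI route)
    topology_path: str | None = None
    trajectory_paths: list[str] = field(default_factory=list)
    domain_map_path: str | None = None

    def load(self, stride_ps: float = 10.0) -> None:
        if not self.replicates and self.topology_path:
            top = read_topology(self.topology_path)
            self.replicates = [read_trajectory(p, top, stride_ps=stride_ps)
                               for p in self.trajectory_paths]
        if self.domain_map is None and self.domain_map_path:
            self.domain_map, sels = read_domain_map(self.domain_map_path)
            for name, sel in sels.items():
                self.selections.setdefault(name, sel)
        if self.domain_map is None:
            raise ValueError(f"protein {self.name}: no domain map")
        if not self.replicates:
            raise ValueError(f"protein {self.name}: no trajectories")


@dataclass
class StudyConfig:
    proteins: list[ProteinInput]
    out_dir: str | Path = "study_out"
    seed: int = 0
    metrics_span_fraction: float = 0.10     # EWMA span for metric comparisons
    interdomain_span: int = 1000            # EWMA span for interdomain distances
    verdict_rule: VerdictRule = field(default_factory=VerdictRule)
    cluster: ClusterConfig = field(default_factory=ClusterConfig)
    embed: EmbedConfig = field(default_factory=EmbedConfig)
    jaw_pair: tuple[str, str] = ("PAZ", "MID")
    max_lag_fraction: float = 0.25          # of series length
    sasa_max_frames: int = 50               # SASA frames are subsampled to this
    contact_types: tuple[str, ...] = ("hbbb", "hbsb", "hbss", "sb", "pc", "ps", "ts")
    fasta_path: str | None = None

    def validate(self) -> None:
        if not self.proteins:
            raise ValueError("no proteins configured")
        counts = {len(p.replicates) or len(p.trajectory_paths)
                  for p in self.proteins}
        if len(counts) != 1:
            raise ValueError(f"unequal replicate counts across proteins: {counts}")


def load_study_config(path: str | Path) -> StudyConfig:
    """Load a YAML/JSON study config (the CLI entry route).

    Schema::

        seed: 0
        out_dir: study_out
        jaw_pair: [PAZ, MID]
        fasta: sequences.fasta        # optional
        proteins:
          - name: A
            topology: a_top.pdb
            trajectories: [a_r1.csv, a_r2.csv, a_r3.csv]
            domain_map: a_domains.json
    """
    path = Path(path)
    with open(path) as handle:
        cfg = yaml.safe_load(handle)
    base = path.parent

    def _resolve(p):
        p = Path(p)
        return str(p if p.is_absolute() else base / p)

    proteins = []
    for entry in cfg.get("proteins", []):
        proteins.append(ProteinInput(
            name=entry["name"],
            topology_path=_resolve(entry["topology"]),
            trajectory_paths=[_resolve(t) for t in entry["trajectories"]],
            domain_map_path=_resolve(entry["domain_map"]),
        ))
    sc = StudyConfig(
        proteins=proteins,
        out_dir=cfg.get("out_dir", "study_out"),
        seed=int(cfg.get("seed", 0)),
        jaw_pair=tuple(cfg.get("jaw_pair", ("PAZ", "MID"))),
        fasta_path=_resolve(cfg["fasta"]) if cfg.get("fasta") else None,
    )
    if "cluster" in cfg:
        sc.cluster = ClusterConfig(
            k_range=tuple(cfg["cluster"].get("k_range", (2, 20))),
            seed=int(cfg.get("seed", 0)))
    if "embed" in cfg:
        sc.embed = EmbedConfig(method=cfg["embed"].get("method", "pca"),
                               seed=int(cfg.get("seed", 0)))
    for prot in proteins:
        for required in [prot.topology_path, prot.domain_map_path,
                         *prot.trajectory_paths]:
            if required and not Path(required).exists():
                raise FileNotFoundError(f"{prot.name}: missing input {required}")
    return sc


# ---------------------------------------------------------------------------

def run_study(config: StudyConfig) -> dict:
    """Run the full comparative study; returns a manifest-like result dict.

    On stage failure, completed outputs are preserved under
    ``<out_dir>/partial`` and a StageError naming the stage is raised.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result: dict = {"proteins": [p.name for p in config.proteins],
                    "seed": config.seed, "stages": []}
    stage = "load"
    try:
        for p in config.proteins:
            p.load()
        _log_stage(result, stage)

        stage = "metrics"
        metric_store = _stage_metrics(config, out)
        _log_stage(result, stage)

        stage = "compare"
        _stage_compare(config, metric_store, out)
        _log_stage(result, stage)

        stage = "states"
        lag_rows = _stage_time_lags(config, metric_store, out)
        _log_stage(result, stage)

        stage = "cluster"
        cluster_store = _stage_cluster(config, metric_store, out)
        _log_stage(result, stage)

        stage = "contacts"
        _stage_contacts(config, cluster_store, out)
        _log_stage(result, stage)

        stage = "segments"
        _stage_segments(config, out)
        _log_stage(result, stage)

        stage = "manifest"
        manifest = _manifest(config, result)
        write_json(manifest, out / "manifest.json")
        _log_stage(result, stage)
    except Exception as exc:
        partial = out / "partial"
        partial.mkdir(exist_ok=True)
        for item in list(out.iterdir()):
            if item.name != "partial":
                shutil.move(str(item), str(partial / item.name))
        raise StageError(stage, exc) from exc
    return result


def _log_stage(result: dict, stage: str) -> None:
    logger.info("stage complete: %s", stage)
    result["stages"].append(stage)


def _stage_metrics(config: StudyConfig, out: Path) -> dict:
    """Per protein x replicate: RMSD (whole + per domain), RMSF, Rg, SASA,
    interdomain distances."""
    store: dict = {}
    for prot in config.proteins:
        dmap = prot.domain_map
        pstore = store[prot.name] = {"rmsd": [], "rmsf": [], "rg": [],
                                     "sasa": [], "interdomain": [],
                                     "protein": prot}
        for r, traj in enumerate(prot.replicates):
            ca = traj.topology.alpha_carbons()
            rmsd_cols = {"whole": rmsd_series(traj).values}
            for dom in dmap.domain_names:
                idx = traj.topology.atom_indices_for_residues(
                    dmap.residues_of(dom))
                rmsd_cols[dom] = rmsd_series(traj, selection=idx).values
            pstore["rmsd"].append(rmsd_cols)
            pstore["rmsf"].append(rmsf(traj))
            pstore["rg"].append(radius_of_gyration(traj))
            step = max(1, traj.n_frames // config.sasa_max_frames)
            sub = Trajectory(topology=traj.topology,
                             coords=traj.coords[::step],
                             stride_ps=traj.stride_ps * step)
            pstore["sasa"].append(sasa_series(sub))
            pstore["interdomain"].append(interdomain_distances(traj, dmap))

            df = pd.DataFrame({f"{k}_A": v for k, v in rmsd_cols.items()})
            df.insert(0, "frame", np.arange(len(df)))
            write_table(df, out / f"{prot.name}_R{r + 1}_rmsd.csv")
            write_table(pstore["rmsf"][-1].to_frame(),
                        out / f"{prot.name}_R{r + 1}_rmsf.csv")
            write_table(pstore["rg"][-1].to_frame(),
                        out / f"{prot.name}_R{r + 1}_rg.csv")
            write_table(pstore["sasa"][-1].to_frame(),
                        out / f"{prot.name}_R{r + 1}_sasa.csv")
            write_table(pstore["interdomain"][-1].summary(),
                        out / f"{prot.name}_R{r + 1}_interdomain_summary.csv")
    return store


def _stage_compare(config: StudyConfig, store: dict, out: Path) -> None:
    """Verdict grid: per-domain RMSD EWMA KS comparisons across protein pairs,
    aggregated over matched replicate indices; Frechet matrices on RMSF."""
    verdicts = []
    names = [p.name for p in config.proteins]
    for a, b in itertools.combinations(names, 2):
        domains = [d for d in ("whole", *store[a]["protein"].domain_map.domain_names)
                   if d in store[a]["rmsd"][0] and d in store[b]["rmsd"][0]]
        for dom in domains:
            records = []
            for ra, rb in zip(store[a]["rmsd"], store[b]["rmsd"]):
                xa, xb = ra[dom], rb[dom]
                sa = ewma(xa, EwmaSpec.fraction_of(len(xa),
                                                   config.metrics_span_fraction))
                sb = ewma(xb, EwmaSpec.fraction_of(len(xb),
                                                   config.metrics_span_fraction))
                records.append(ks_compare(sa, sb))
            verdict = replicate_verdict(records, config.verdict_rule)
            verdicts.append({"comparison": f"{a}-vs-{b}", "metric": "RMSD",
                             "selection": dom, **verdict.to_dict()})
    write_json(verdicts, out / "verdicts_rmsd.json")

    # Frechet on RMSF curves per named selection (mapped residues)
    frechet_rows = []
    for a, b in itertools.combinations(names, 2):
        pa, pb = store[a]["protein"], store[b]["protein"]
        mapping = None
        if pa.sequence and pb.sequence:
            mapping = map_residues(pa.sequence, pb.sequence).as_dict()
        common_selections = set(pa.selections) & set(pb.selections)
        for sel_name in sorted(common_selections | {"whole"}):
            dists = []
            for fa, fb in zip(store[a]["rmsf"], store[b]["rmsf"]):
                ca_curve, cb_curve = _matched_rmsf(fa, fb, pa, pb,
                                                   sel_name, mapping)
                if ca_curve.size == 0:
                    continue
                dists.append(frechet_distance(ca_curve, cb_curve))
            if dists:
                frechet_rows.append({
                    "comparison": f"{a}-vs-{b}", "selection": sel_name,
                    "mean_frechet_A": float(np.mean(dists)),
                    "n_replicates": len(dists)})
    write_table(pd.DataFrame(frechet_rows), out / "frechet_rmsf.csv")


def _matched_rmsf(fa: MetricSeries, fb: MetricSeries, pa: ProteinInput,
                  pb: ProteinInput, sel_name: str,
                  mapping: dict[int, int] | None) -> tuple[np.ndarray, np.ndarray]:
    index_a = {int(r): i for i, r in enumerate(fa.index)}
    index_b = {int(r): i for i, r in enumerate(fb.index)}
    if sel_name == "whole":
        residues_a = sorted(index_a)
    else:
        residues_a = sorted(pa.selections[sel_name].residues)
    pairs = []
    for ra in residues_a:
        rb = mapping.get(ra) if mapping is not None else ra
        if rb is None:
            continue
        if ra in index_a and rb in index_b:
            pairs.append((index_a[ra], index_b[rb]))
    if not pairs:
        return np.array([]), np.array([])
    ia, ib = zip(*pairs)
    return fa.values[list(ia)], fb.values[list(ib)]


def _stage_time_lags(config: StudyConfig, store: dict, out: Path) -> list[dict]:
    """Jaw-distance synchronization between protein pairs, per replicate."""
    rows = []
    names = [p.name for p in config.proteins]
    jaw_a, jaw_b = config.jaw_pair
    series: dict[str, list[np.ndarray]] = {}
    for name in names:
        dmap = store[name]["protein"].domain_map
        if jaw_a not in dmap.domain_names or jaw_b not in dmap.domain_names:
            continue
        # paper-scale series use the configured absolute span (1000 at 100k
        # points); short desk-scale series fall back to 10% of length
        def _span(n: int) -> int | None:
            return config.interdomain_span if n >= 10 * config.interdomain_span \
                else None
        series[name] = [smooth_normalize(dm.get(jaw_a, jaw_b),
                                         span=_span(len(dm.get(jaw_a, jaw_b))))
                        for dm in store[name]["interdomain"]]
    for a, b in itertools.combinations(series, 2):
        for r, (sa, sb) in enumerate(zip(series[a], series[b])):
            max_lag = max(1, int(config.max_lag_fraction * sa.size))
            lag, corr = time_lag(sa, sb, max_lag)
            rows.append({"pair": f"{a}-vs-{b}", "replicate": r + 1,
                         "lag_frames": lag, "peak_correlation": corr})
    write_table(pd.DataFrame(rows), out / "time_lags.csv")
    return rows


def _stage_cluster(config: StudyConfig, store: dict, out: Path) -> dict:
    """Cluster each replicate, extract medoids, pick open/closed states,
    project stacked medoids."""
    cluster_store: dict = {}
    jaw_a, jaw_b = config.jaw_pair
    for prot in config.proteins:
        entries = []
        for r, traj in enumerate(prot.replicates):
            res = cluster_frames(traj, dataclasses.replace(
                config.cluster, seed=config.seed))
            medoids = extract_medoids(res, traj)
            entries.append({"result": res, "medoids": medoids, "traj": traj,
                            "replicate": r})
            write_table(res.to_frame(),
                        out / f"{prot.name}_R{r + 1}_clusters.csv")
        cluster_store[prot.name] = entries

        dmap = prot.domain_map
        if jaw_a in dmap.domain_names and jaw_b in dmap.domain_names:
            all_medoids, jaw_d = [], []
            for entry in entries:
                dm = store[prot.name]["interdomain"][entry["replicate"]]
                jaw_series = dm.get(jaw_a, jaw_b).values
                for m, frame_idx in enumerate(entry["result"].medoid_indices):
                    all_medoids.append(entry["medoids"][m])
                    jaw_d.append(float(jaw_series[frame_idx]))
            open_i, closed_i = select_state_representatives(all_medoids, jaw_d)
            top = prot.replicates[0].topology
            for tag, idx in (("open", open_i), ("closed", closed_i)):
                t = Trajectory(topology=top,
                               coords=all_medoids[idx][None, :, :],
                               stride_ps=prot.replicates[0].stride_ps)
                write_topology_pdb(t, out / f"{prot.name}_state_{tag}.pdb")
            write_json({"open": {"index": open_i, "jaw_distance_A": jaw_d[open_i]},
                        "closed": {"index": closed_i,
                                   "jaw_distance_A": jaw_d[closed_i]}},
                       out / f"{prot.name}_states.json")

    # stacked medoid projection across proteins
    reference = config.proteins[0].name
    medoid_sets = {}
    ca_indices = {}
    for prot in config.proteins:
        medoids = [m for e in cluster_store[prot.name] for m in e["medoids"]]
        medoid_sets[prot.name] = medoids
        ca_indices[prot.name] = prot.replicates[0].topology.alpha_carbons()
    mappings = None
    ref_seq = config.proteins[0].sequence
    if ref_seq and all(p.sequence for p in config.proteins):
        mappings = {p.name: map_residues(ref_seq, p.sequence)
                    for p in config.proteins if p.name != reference}
    projection = stack_and_project(medoid_sets, ca_indices, mappings,
                                   reference, config.embed)
    df = projection.to_frame()
    write_table(df, out / "medoid_projection.csv")
    write_json(projection.config.to_dict(), out / "medoid_projection_config.json")
    return cluster_store


def _stage_contacts(config: StudyConfig, cluster_store: dict, out: Path) -> None:
    for prot in config.proteins:
        medoids = [m for e in cluster_store[prot.name] for m in e["medoids"]]
        catalog = unique_contact_catalog(
            medoids, prot.replicates[0].topology, prot.domain_map,
            types=config.contact_types)
        write_table(catalog_to_table(catalog),
                    out / f"{prot.name}_contact_catalog.csv")


def _stage_segments(config: StudyConfig, out: Path) -> None:
    sequences = [(p.name, p.sequence) for p in config.proteins if p.sequence]
    if config.fasta_path:
        sequences = read_fasta(config.fasta_path)
        by_id = dict(sequences)
        for p in config.proteins:
            if p.sequence is None and p.name in by_id:
                p.sequence = by_id[p.name]
    if len(sequences) < 2:
        return
    hits = longest_common_segments(sequences)
    write_table(pd.DataFrame([h.to_dict() for h in hits]),
                out / "common_segments.csv")


def _manifest(config: StudyConfig, result: dict) -> dict:
    return {
        "package": "pincermd",
        "version": __version__,
        "seed": config.seed,
        "proteins": [
            {"name": p.name,
             "n_replicates": len(p.replicates),
             "n_frames": [t.n_frames for t in p.replicates],
             "topology_path": p.topology_path,
             "trajectory_paths": p.trajectory_paths}
            for p in config.proteins],
        "verdict_rule": config.verdict_rule.to_dict(),
        "cluster": {"k_range": list(config.cluster.k_range),
                    "msd_preference": config.cluster.msd_preference,
                    "seed": config.seed},
        "embed": config.embed.to_dict(),
        "jaw_pair": list(config.jaw_pair),
        "metrics_span_fraction": config.metrics_span_fraction,
        "interdomain_span": config.interdomain_span,
        "stages": result["stages"],
        "note": "raw per-comparison verdicts; no multiple-testing correction",
    }
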