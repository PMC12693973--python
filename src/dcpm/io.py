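"""Readers, writers, run manifests, configuration and the pipeline driver.

All interchange formats are plain text: node time series as delimited
matrices (nodes x samples), trial tables as delimited text with a header,
atlas partitions as two-column label tables, predictive networks as edge
lists.  Synchrony tensors, which are large and intermediate, go into .npz
containers that carry an edge-order checksum; any operation combining two
saved artifacts verifies the checksum and a mismatch is fatal.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import simulate as sim
from .connectivity import (
    DEFAULT_BAND, DEFAULT_SHIFT_S, DEFAULT_WINDOW_S, EdgeSynchronyTensor,
    NodeTimeSeries, compute_synchrony, edge_pairs, trial_average,
)
from .cpm import (
    DEFAULT_ALPHA, DEFAULT_N_PERM, CPMResult, PredictiveNetwork,
    consensus_network, generalize, loto_cv,
)
from .dynamics import (
    engagement, internetwork_cofluctuation, remove_shared_edges,
    summarize_by_condition,
)
from .netstats import AtlasPartition, composition_matrix

logger = logging.getLogger("dcpm")

TRIAL_COLUMNS = ["subject", "session", "run", "onset_sample", "memory", "arousal"]


def setup_logging(log_file: str | Path | None = None,
                  level: int = logging.INFO) -> None:
    """Route package logs to stderr and optionally a run log file."""
    logger.setLevel(level)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    h = logging.StreamHandler(sys.stderr)
    h.setFormatter(fmt)
    logger.addHandler(h)
    if log_file is not None:
        fh = logging.FileHandler(log_file)
        fh.setFormatter(fmt)
        logger.addHandler(fh)


# ---------------------------------------------------------------------------
# Edge-order manifest
# ---------------------------------------------------------------------------

def edge_order_checksum(n_nodes: int) -> str:
    """Checksum of the canonical upper-triangle edge order for n_nodes."""
    h = hashlib.sha1()
    h.update(f"upper-triangle-row-major:{n_nodes}:".encode())
    h.update(np.ascontiguousarray(edge_pairs(n_nodes), dtype=np.int64).tobytes())
    return h.hexdigest()


def check_edge_order(checksum_a: str, checksum_b: str) -> None:
    if checksum_a != checksum_b:
        raise ValueError(
            "edge-order manifest mismatch between combined artifacts: "
            f"{checksum_a} != {checksum_b}"
        )


# ---------------------------------------------------------------------------
# Delimited-text readers / writers
# ---------------------------------------------------------------------------

def load_timeseries(path: str | Path, subject: str = "", session: str = "",
                    run: str = "", sampling_interval: float = 1.0,
                    delimiter: str | None = None) -> NodeTimeSeries:
    """Read a nodes x samples delimited matrix, validating every cell.

    Ragged rows, non-numeric cells and non-finite values are rejected with
    their (row, column) location.  A single leading non-numeric line is
    treated as a header and skipped.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        lines = [ln for ln in (l.strip() for l in fh) if ln]
    start = 0
    if lines:
        try:
            [float(v) for v in lines[0].replace(",", " ").split()]
        except ValueError:
            start = 1  # header line
    width = None
    for rnum, line in enumerate(lines[start:], start=start + 1):
        cells = line.replace(",", " ").split() if delimiter is None \
            else line.split(delimiter)
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise ValueError(
                f"{path}: ragged row {rnum}: {len(cells)} cells, expected {width}"
            )
        vals = []
        for cnum, cell in enumerate(cells, start=1):
            try:
                v = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell at row {rnum}, column {cnum}: "
                    f"{cell!r}"
                ) from None
            if not np.isfinite(v):
                raise ValueError(
                    f"{path}: non-finite value at row {rnum}, column {cnum}"
                )
            vals.append(v)
        rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: empty time-series file")
    return NodeTimeSeries(subject=subject, session=session, run=run,
                          values=np.array(rows),
                          sampling_interval=sampling_interval)


def save_timeseries(ts: NodeTimeSeries, path: str | Path) -> None:
    np.savetxt(path, ts.values, delimiter="\t", fmt="%.17g")


def load_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table; missing behavior entries stay missing.

    Required columns: subject, session, run, onset_sample, memory, arousal.
    memory outside {0, 1} or arousal outside 1..4 is rejected naming the
    offending row; exclusion of missing-behavior trials happens downstream,
    per construct.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    missing_cols = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required column(s): {missing_cols}")
    df = df[TRIAL_COLUMNS + [c for c in df.columns if c not in TRIAL_COLUMNS]]
    for col, ok in (("memory", {0.0, 1.0}), ("arousal", {1.0, 2.0, 3.0, 4.0})):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_numeric = df[col].notna() & vals.isna()
        if bad_numeric.any():
            raise ValueError(
                f"{path}: non-numeric {col} at row {int(np.flatnonzero(bad_numeric)[0]) + 1}"
            )
        bad = vals.notna() & ~vals.isin(list(ok))
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 1
            raise ValueError(
                f"{path}: {col} value {vals[bad].iloc[0]} out of range at row {row}"
            )
        df[col] = vals
    for sub_run, grp in df.groupby(["subject", "session", "run"]):
        onsets = grp["onset_sample"].to_numpy()
        if not np.all(np.diff(onsets) > 0):
            raise ValueError(
                f"{path}: onsets not strictly increasing for {sub_run}"
            )
    return df


def save_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def load_atlas(path: str | Path) -> AtlasPartition:
    """Read a node_index -> network_label table (delimited text)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if not {"node_index", "network_label"} <= set(df.columns):
        raise ValueError(f"{path}: need columns node_index, network_label")
    df = df.sort_values("node_index")
    idx = df["node_index"].to_numpy()
    if not np.array_equal(idx, np.arange(len(idx))):
        raise ValueError(f"{path}: node_index must be 0..n-1, each exactly once")
    return AtlasPartition(labels=df["network_label"].astype(str).to_numpy())


def save_atlas(partition: AtlasPartition, path: str | Path) -> None:
    pd.DataFrame({
        "node_index": np.arange(partition.n_nodes),
        "network_label": partition.labels,
    }).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Tensor container and network edge lists
# ---------------------------------------------------------------------------

def save_tensor(tensor: EdgeSynchronyTensor, path: str | Path) -> None:
    """Write a synchrony tensor with its edge-order manifest."""
    np.savez_compressed(
        path, synchrony=tensor.synchrony, n_nodes=tensor.n_nodes,
        sampling_interval=tensor.sampling_interval,
        low_confidence=tensor.low_confidence,
        subject=tensor.subject, session=tensor.session, run=tensor.run,
        edge_checksum=edge_order_checksum(tensor.n_nodes),
    )


def load_tensor(path: str | Path) -> EdgeSynchronyTensor:
    with np.load(path, allow_pickle=False) as z:
        n_nodes = int(z["n_nodes"])
        check_edge_order(str(z["edge_checksum"]), edge_order_checksum(n_nodes))
        return EdgeSynchronyTensor(
            n_nodes=n_nodes, synchrony=z["synchrony"],
            sampling_interval=float(z["sampling_interval"]),
            subject=str(z["subject"]), session=str(z["session"]),
            run=str(z["run"]), low_confidence=z["low_confidence"],
        )


def save_network(net: PredictiveNetwork, path: str | Path) -> None:
    """Edge-list text file: one edge per line (node_i, node_j, subnetwork)."""
    with open(path, "w") as fh:
        fh.write(f"# construct: {net.construct}\n")
        cond = f"{net.condition[0]}/{net.condition[1]}" if net.condition else ""
        fh.write(f"# condition: {cond}\n")
        fh.write(f"# n_nodes: {net.n_nodes}\n")
        fh.write(f"# edge_checksum: {edge_order_checksum(net.n_nodes)}\n")
        fh.write("node_i\tnode_j\tsubnetwork\n")
        for i, j in sorted(net.positive_edges):
            fh.write(f"{i}\t{j}\tpositive\n")
        for i, j in sorted(net.negative_edges):
            fh.write(f"{i}\t{j}\tnegative\n")


def load_network(path: str | Path) -> PredictiveNetwork:
    meta: dict[str, str] = {}
    pos, neg = set(), set()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                key, _, val = line[1:].partition(":")
                meta[key.strip()] = val.strip()
            elif line and not line.startswith("node_i"):
                i, j, sub = line.split("\t")
                (pos if sub == "positive" else neg).add((int(i), int(j)))
    n_nodes = int(meta["n_nodes"])
    if "edge_checksum" in meta:
        check_edge_order(meta["edge_checksum"], edge_order_checksum(n_nodes))
    cond = None
    if meta.get("condition"):
        parts = meta["condition"].split("/")
        if len(parts) == 2:
            cond = (parts[0], parts[1])
    return PredictiveNetwork(
        construct=meta.get("construct", ""), positive_edges=frozenset(pos),
        negative_edges=frozenset(neg), n_nodes=n_nodes, condition=cond,
    )


# ---------------------------------------------------------------------------
# Manifest and dataset loading
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Locates a dataset on disk: per subject/session/run time-series files,
    a trial table, the sampling interval and optionally an atlas table."""

    root: Path
    timeseries: list[dict]  # {subject, session, run, path}
    trials_path: Path
    sampling_interval: float = 1.0
    atlas_path: Path | None = None

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        root = path.parent
        man = cls(
            root=root,
            timeseries=raw["timeseries"],
            trials_path=root / raw["trials"],
            sampling_interval=float(raw.get("sampling_interval", 1.0)),
            atlas_path=(root / raw["atlas"]) if raw.get("atlas") else None,
        )
        missing = [str(man.trials_path)] if not man.trials_path.exists() else []
        for entry in man.timeseries:
            p = root / entry["path"]
            if not p.exists():
                missing.append(str(p))
        if man.atlas_path and not man.atlas_path.exists():
            missing.append(str(man.atlas_path))
        if missing:
            raise FileNotFoundError(f"manifest references missing file(s): {missing}")
        return man

    def load_dataset(self) -> tuple[list[NodeTimeSeries], pd.DataFrame]:
        series = [
            load_timeseries(self.root / e["path"], subject=str(e["subject"]),
                            session=str(e["session"]), run=str(e["run"]),
                            sampling_interval=self.sampling_interval)
            for e in self.timeseries
        ]
        return series, load_trials(self.trials_path)


def write_dataset(series: list[NodeTimeSeries], trials: pd.DataFrame,
                  truth: sim.GroundTruth | None, out_dir: str | Path) -> Path:
    """Write a simulated dataset as delimited text plus a manifest (and a
    JSON ground-truth sidecar when available).  Returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for ts in series:
        name = f"ts_{ts.subject}_{ts.session}_{ts.run}.tsv"
        save_timeseries(ts, out / name)
        entries.append({"subject": ts.subject, "session": ts.session,
                        "run": ts.run, "path": name})
    save_trials(trials, out / "trials.tsv")
    manifest = {
        "timeseries": entries, "trials": "trials.tsv",
        "sampling_interval": series[0].sampling_interval,
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    if truth is not None:
        sidecar = {
            "planted_positive_edges": sorted(map(list, truth.planted_positive_edges)),
            "planted_negative_edges": sorted(map(list, truth.planted_negative_edges)),
            "secondary_positive_edges": sorted(map(list, truth.secondary_positive_edges)),
            "secondary_negative_edges": sorted(map(list, truth.secondary_negative_edges)),
        }
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
    return out / "manifest.yaml"


# ---------------------------------------------------------------------------
# Configuration and pipeline
# ---------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "dataset": {"preset": "desk", "seed": 0, "coupling_strength": 0.0},
    "analysis": {
        "alpha": DEFAULT_ALPHA,
        "band": list(DEFAULT_BAND),
        "shift": DEFAULT_SHIFT_S,
        "window": DEFAULT_WINDOW_S,
        "n_perm": DEFAULT_N_PERM,
        "seed": 0,
        "constructs": ["memory", "arousal"],
        "feature_mode": "two",
    },
    "stages": ["fit", "anatomy", "dynamics", "generalize"],
    "output_dir": "dcpm_out",
}


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    """Merge a YAML config file over the defaults (which reproduce the
    reference analysis settings: alpha 0.01, 5-s shift, 10-s window,
    0.008-0.12 Hz band, 1000 permutations)."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    layers = []
    if path is not None:
        with open(path) as fh:
            layers.append(yaml.safe_load(fh) or {})
    if overrides:
        layers.append(overrides)
    for layer in layers:
        for key, val in layer.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _dataset_from_config(cfg: dict) -> tuple[list[NodeTimeSeries], pd.DataFrame,
                                             sim.GroundTruth | None,
                                             AtlasPartition | None]:
    ds = cfg["dataset"]
    if "manifest" in ds:
        man = RunManifest.load(ds["manifest"])
        series, trials = man.load_dataset()
        atlas = load_atlas(man.atlas_path) if man.atlas_path else None
        return series, trials, None, atlas
    preset = ds.get("preset", "desk")
    seed = int(ds.get("seed", 0))
    if preset == "paper":
        spec = sim.design_preset_paper(seed=seed)
    elif preset == "desk":
        spec = sim.design_preset_desk(
            seed=seed, coupling_strength=float(ds.get("coupling_strength", 0.0)))
    elif preset == "strong":
        spec = sim.preset_strong_coupling(seed=seed)
    elif preset == "null_small":
        spec = sim.preset_null_small(seed=seed)
    else:
        raise ValueError(f"unknown preset {preset!r}")
    series, trials, truth = sim.simulate_dataset(spec)
    # fabricated, evenly sized partition so anatomy stages are exercisable
    n_networks = min(10, spec.n_nodes)
    labels = np.array([f"FN{k % n_networks:02d}" for k in range(spec.n_nodes)],
                      dtype=object)
    return series, trials, truth, AtlasPartition(labels=labels)


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: dict | str | Path | None = None,
                 overrides: dict | None = None) -> dict:
    """Execute synchrony -> dCPM -> consensus -> anatomy -> dynamics ->
    generalization per session/run condition and write all artifacts.

    Returns the results bundle (also written as results.json with a
    provenance block).  A failing stage is recorded and later stages that
    depend on it are skipped; artifacts of completed stages are preserved.
    """
    if isinstance(config, (str, Path)):
        cfg = load_config(config, overrides)
    else:
        cfg = load_config(None, {**(config or {}), **(overrides or {})})
    out_dir = Path(cfg["output_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir / "run.log")
    ana = cfg["analysis"]
    stages = cfg.get("stages", DEFAULT_CONFIG["stages"])
    t0 = time.time()

    cfg_hash = hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()
    results: dict = {"conditions": {}, "stage_errors": {}}

    series, trials, truth, atlas = _dataset_from_config(cfg)
    n_nodes = series[0].n_nodes
    low, high = ana["band"]

    logger.info("computing phase synchrony for %d series", len(series))
    tensors = [compute_synchrony(ts, low, high) for ts in series]

    conditions = sorted({(t.session, t.run) for t in tensors})
    networks: dict[tuple, dict[str, PredictiveNetwork]] = {}
    matrices: dict[tuple, dict[str, object]] = {}

    for cond in conditions:
        sess, run = cond
        cond_key = f"{sess}/{run}"
        cond_tensors = [t for t in tensors if (t.session, t.run) == cond]
        cond_trials = trials[(trials["session"] == sess) &
                             (trials["run"] == run)].reset_index(drop=True)
        cond_res: dict = {}
        networks[cond] = {}
        matrices[cond] = {}
        for construct in ana["constructs"]:
            try:
                if "fit" not in stages:
                    continue
                X = trial_average(cond_tensors, cond_trials,
                                  shift=ana["shift"], window=ana["window"],
                                  construct=construct)
                matrices[cond][construct] = X
                n_perm = int(ana["n_perm"])
                res = loto_cv(X, construct=construct, alpha=ana["alpha"],
                              feature_mode=ana["feature_mode"],
                              n_perm=n_perm, seed=int(ana["seed"]),
                              condition=cond)
                net = consensus_network(res)
                networks[cond][construct] = net
                save_network(net, out_dir / f"network_{sess}_{run}_{construct}.tsv")
                cond_res[construct] = {
                    "performance": res.performance,
                    "metric": "accuracy" if construct == "memory" else "pearson_r",
                    "p_value": res.p_value,
                    "coverage": res.coverage,
                    "n_trials": int(len(res.observed)),
                    "n_consensus_positive": len(net.positive_edges),
                    "n_consensus_negative": len(net.negative_edges),
                }
                if "anatomy" in stages and atlas is not None:
                    comp = composition_matrix(net, atlas)
                    comp.to_csv(out_dir /
                                f"composition_{sess}_{run}_{construct}.tsv",
                                sep="\t", index=False)
                    cond_res[construct]["n_significant_cells"] = int(
                        comp["significant"].sum())
            except Exception as exc:  # keep partial outputs, report stage
                logger.exception("stage 'fit' failed for %s %s", cond_key, construct)
                results["stage_errors"][f"fit:{cond_key}:{construct}"] = str(exc)
        results["conditions"][cond_key] = cond_res

    if "dynamics" in stages:
        try:
            eng_series = []
            cof_pairs = []
            for cond in conditions:
                nets = networks.get(cond, {})
                if {"memory", "arousal"} <= set(nets):
                    mem_net, aro_net = remove_shared_edges(nets["memory"],
                                                           nets["arousal"])
                else:
                    mem_net = aro_net = None
                for t in tensors:
                    if (t.session, t.run) != cond:
                        continue
                    for construct, net in nets.items():
                        if net.positive_edges or net.negative_edges:
                            eng_series.append(engagement(t, net))
                    if (mem_net is not None and
                            (mem_net.positive_edges or mem_net.negative_edges) and
                            (aro_net.positive_edges or aro_net.negative_edges)):
                        cof_pairs.append((
                            engagement(t, mem_net, shared_edges_removed=True),
                            engagement(t, aro_net, shared_edges_removed=True),
                        ))
            if eng_series:
                summary = summarize_by_condition(eng_series, cof_pairs or None)
                summary.to_csv(out_dir / "engagement_summary.tsv", sep="\t",
                               index=False)
                results["dynamics"] = {
                    "n_engagement_series": len(eng_series),
                    "n_cofluctuation_pairs": len(cof_pairs),
                    "mean_engagement": float(summary["mean_engagement"].mean()),
                }
        except Exception as exc:
            logger.exception("stage 'dynamics' failed")
            results["stage_errors"]["dynamics"] = str(exc)

    if "generalize" in stages and len(conditions) >= 2:
        try:
            gen: dict = {}
            sess0 = conditions[0][0]
            runs0 = [c for c in conditions if c[0] == sess0]
            if len(runs0) >= 2:
                a, b = runs0[0], runs0[1]
                for construct in ana["constructs"]:
                    Xa = matrices[a].get(construct)
                    Xb = matrices[b].get(construct)
                    if Xa is None or Xb is None:
                        continue
                    res = generalize(Xa, Xa.behavior(construct),
                                     Xb, Xb.behavior(construct),
                                     construct, construct,
                                     alpha=ana["alpha"],
                                     n_perm=int(ana["n_perm"]),
                                     seed=int(ana["seed"]))
                    gen[f"cross_run_{construct}"] = {
                        "performance": res.performance, "p_value": res.p_value,
                        "source": f"{a[0]}/{a[1]}", "target": f"{b[0]}/{b[1]}",
                    }
            results["generalization"] = gen
        except Exception as exc:
            logger.exception("stage 'generalize' failed")
            results["stage_errors"]["generalize"] = str(exc)

    logger.info("pipeline finished in %.2f s", time.time() - t0)
    # timings stay in the log so results.json is bit-stable across reruns
    results["provenance"] = {
        "config_hash": cfg_hash,
        "seed": int(ana["seed"]),
        "n_nodes": int(n_nodes),
    }
    with open(out_dir / "results.json", "w") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_json_default)
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return results
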