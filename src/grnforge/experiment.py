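"""End-to-end experiment plumbing: config parsing, artifacts, manifests.

An experiment is described by a flat INI-style config (sections of
``key = value`` pairs) and runs generate -> simulate -> screen ->
summaries, writing plain-text artifacts plus a JSON manifest with seeds,
parameter values, convergence flags and artifact checksums.  All
randomness flows from seeds recorded in the manifest, so re-running a
config reproduces the artifacts bit-identically.
"""

from __future__ import annotations

import configparser
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np

from . import netgen
from .exprmodel import SimConfig, sample_expression_params, save_params, simulate_to_steady_state
from .perturb import hub_counts, knockout_screen

__all__ = ["ExperimentManifest", "ConfigError", "run_experiment", "grid_runner"]

#: matrices with more columns than this go to MatrixMarket instead of TSV
TSV_MAX_COLS = 512


class ConfigError(ValueError):
    """Invalid or missing experiment configuration key."""


@dataclass
class ExperimentManifest:
    version: str
    config: dict
    seeds: dict
    artifacts: dict = field(default_factory=dict)  # name -> {path, sha256}
    convergence: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


_REQUIRED = {
    "network": ["n", "k", "w", "p", "delta_in", "delta_out", "seed"],
}
_KNOWN = {
    "network": {"n", "k", "w", "p", "delta_in", "delta_out", "seed"},
    "simulation": {"burn_in", "check_every", "t_max", "tol", "s", "dt", "seed"},
    "screen": {"enabled", "seed", "effect_thresh", "count_thresh"},
}


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 16), b""):
            h.update(block)
    return h.hexdigest()


def _parse_config(path) -> dict:
    cp = configparser.ConfigParser()
    if not cp.read(path):
        raise ConfigError(f"cannot read config file {path}")
    cfg: dict = {}
    for section in cp.sections():
        if section not in _KNOWN:
            raise ConfigError(f"unknown config section [{section}]")
        cfg[section] = {}
        for key, val in cp.items(section):
            if key not in _KNOWN[section]:
                raise ConfigError(f"unknown key '{key}' in section [{section}]")
            cfg[section][key] = val
    for section, keys in _REQUIRED.items():
        if section not in cfg:
            raise ConfigError(f"missing required section [{section}]")
        for key in keys:
            if key not in cfg[section]:
                raise ConfigError(f"missing required key '{key}' in [{section}]")
    return cfg


def run_experiment(config_path, out_dir) -> ExperimentManifest:
    """Execute the pipeline described by a config file; write artifacts."""
    from . import __version__

    cfg = _parse_config(config_path)
    os.makedirs(out_dir, exist_ok=True)

    net = cfg["network"]
    gp = netgen.GraphParams(
        n=int(net["n"]), k=int(net["k"]), w=float(net["w"]), p=float(net["p"]),
        delta_in=float(net["delta_in"]), delta_out=float(net["delta_out"]),
        seed=int(net["seed"]),
    )
    sim = cfg.get("simulation", {})
    config = SimConfig(
        burn_in=int(sim.get("burn_in", 5000)),
        check_every=int(sim.get("check_every", 1000)),
        t_max=int(sim.get("t_max", 20000)),
        tol=float(sim.get("tol", 1e-3)),
    )
    s = float(sim.get("s", 1e-4))
    dt = float(sim.get("dt", 0.01))
    sim_seed = int(sim.get("seed", gp.seed + 1))
    scr = cfg.get("screen", {})
    screen_enabled = scr.get("enabled", "true").lower() in ("1", "true", "yes")
    screen_seed = int(scr.get("seed", gp.seed + 2))

    manifest = ExperimentManifest(
        version=__version__,
        config={k: dict(v) for k, v in cfg.items()},
        seeds={"network": gp.seed, "simulation": sim_seed, "screen": screen_seed},
    )

    graph = netgen.generate_network(gp)
    edges_path = os.path.join(out_dir, "edges.tsv")
    groups_path = os.path.join(out_dir, "groups.tsv")
    netgen.write_edges_tsv(graph, edges_path, groups_path)

    params = sample_expression_params(graph, seed=sim_seed, s=s, dt=dt)
    params_path = os.path.join(out_dir, "expression_params.npz")
    save_params(params, params_path)

    baseline = simulate_to_steady_state(params, config=config, seed=sim_seed)
    ss_path = os.path.join(out_dir, "steady_state.tsv")
    with open(ss_path, "w") as fh:
        fh.write("gene\txbar\texpressed\n")
        for g, (xb, ex) in enumerate(zip(baseline.xbar, baseline.expressed_mask)):
            fh.write(f"{g}\t{xb:.10g}\t{int(ex)}\n")
    manifest.convergence["baseline"] = bool(baseline.converged)

    artifacts = {
        "edges": edges_path, "groups": groups_path,
        "expression_params": params_path, "steady_state": ss_path,
    }

    if screen_enabled:
        result = knockout_screen(params, baseline, config=config, seed=screen_seed)
        fc_path = os.path.join(out_dir, "log2fc")
        artifacts["log2fc"] = _write_matrix(result.log2fc, fc_path)
        hubs = hub_counts(
            result,
            effect_thresh=float(scr.get("effect_thresh", 0.1)),
            count_thresh=int(scr.get("count_thresh", 100)),
        )
        hub_path = os.path.join(out_dir, "hub_summary.json")
        with open(hub_path, "w") as fh:
            json.dump(asdict(hubs), fh, indent=2)
        artifacts["hub_summary"] = hub_path
        manifest.convergence["screen_all_converged"] = bool(result.converged_per_ko.all())

    for name, path in artifacts.items():
        manifest.artifacts[name] = {"path": os.path.basename(path), "sha256": _sha256(path)}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        fh.write(manifest.to_json())
    return manifest


def _write_matrix(mat: np.ndarray, stem: str) -> str:
    """Dense TSV for small matrices, MatrixMarket for large ones."""
    if mat.shape[1] <= TSV_MAX_COLS:
        path = stem + ".tsv"
        header = "\t".join(f"g{i}" for i in range(mat.shape[1]))
        np.savetxt(path, mat, delimiter="\t", header=header, comments="", fmt="%.8g")
    else:
        from scipy import io as spio
        import scipy.sparse as sp

        path = stem + ".mtx"
        spio.mmwrite(path, sp.coo_matrix(np.nan_to_num(mat)))
    return path


def grid_runner(
    grid,
    out_path,
    subsample: int | None = None,
    seed: int = 0,
    n_genes: int | None = None,
    config: SimConfig = SimConfig(),
    log=print,
):
    """Run screens over (a subsample of) a parameter grid; resumable.

    One TSV row per network with its parameters and hub summary; networks
    already present in ``out_path`` are skipped on resume.  Per-network
    failures are logged and do not stop the run.
    """
    cols = ["p", "k", "w", "delta_in", "delta_out", "net_seed",
            "n", "n_expressed", "n_hub_ko", "n_hub_target", "baseline_converged"]
    done = set()
    if os.path.exists(out_path):
        with open(out_path) as fh:
            header = fh.readline()
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                done.add(tuple(parts[:6]))
    else:
        with open(out_path, "w") as fh:
            fh.write("\t".join(cols) + "\n")

    rng = np.random.default_rng(seed)
    grid = list(grid)
    if subsample is not None and subsample < len(grid):
        idx = rng.choice(len(grid), size=subsample, replace=False)
        grid = [grid[i] for i in sorted(idx)]

    rows = []
    for gp in grid:
        if n_genes is not None and gp.n != n_genes:
            gp = netgen.GraphParams(n=n_genes, k=gp.k, w=gp.w, p=gp.p,
                                    delta_in=gp.delta_in, delta_out=gp.delta_out,
                                    seed=gp.seed)
        key = tuple(str(v) for v in
                    (gp.p, gp.k, gp.w, gp.delta_in, gp.delta_out, gp.seed))
        if key in done:
            continue
        try:
            graph = netgen.generate_network(gp)
            params = sample_expression_params(graph, seed=gp.seed + 1)
            baseline = simulate_to_steady_state(params, config=config, seed=gp.seed + 1)
            result = knockout_screen(params, baseline, config=config, seed=gp.seed + 2)
            hubs = hub_counts(result)
            row = [gp.p, gp.k, gp.w, gp.delta_in, gp.delta_out, gp.seed,
                   gp.n, hubs.n_expressed, hubs.n_hub_ko, hubs.n_hub_target,
                   int(baseline.converged)]
            with open(out_path, "a") as fh:
                fh.write("\t".join(str(v) for v in row) + "\n")
            rows.append(row)
        except Exception as exc:  # noqa: BLE001 - per-network failures logged
            log(f"network {key} failed: {exc!r}")
    return rows
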