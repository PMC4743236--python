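"""Batch sessions: validated configuration, stage chaining and exports.

A session is a reproducible batch computation described by one YAML (or
dict) configuration: generate or augment an ensemble, simulate attractors,
build the flip-induced attractor transition matrices, extract TES
differentiation trees, match against a target tree, run perturbation
screens and network statistics.  Every run writes its resolved
configuration and the tool version next to its outputs, and all writers use
canonical ordering, so a rerun with the same configuration is
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import attractor_statistics, find_attractors
from .generate import (
    AugmentationSpec,
    GenerationSpec,
    augment_ensemble,
    generate_ensemble,
)
from .model import NetworkError, RegulatoryNetwork
from .netio import read_network, read_tree, write_network, write_tree
from .noise import FlipSpec, build_atm
from .robustness import ko_tree_screen, network_measures, run_perturbation_experiments
from .tes import build_tree, match_ensemble, sweep_thresholds
from .fixtures import hematopoietic_tree, synthetic_core

__all__ = ["SessionConfig", "run_session"]

log = logging.getLogger(__name__)

_KNOWN_STAGES = ("networks", "simulate", "atm", "tree", "match", "perturb", "stats")

_GEN_KEYS = {
    "n_nodes", "topology", "k", "m_edges", "exponent", "ws_k", "ws_p",
    "self_loops", "function_scheme", "bias", "seed", "ensemble_size",
}
_AUG_KEYS = {
    "n_nodes", "m_edges", "topology", "exponent", "k", "function_scheme",
    "bias", "core_extension_policy", "protect_core_inputs", "seed",
}


class SessionConfig:
    """Validated session description.

    Expected top-level keys: ``stages`` (ordered subset of
    ``networks, simulate, atm, tree, match, perturb, stats``), ``seed``,
    ``count``, one of ``generate`` / ``augment`` (specs as nested dicts;
    ``augment`` additionally takes ``core: <path>|synthetic``), plus
    optional ``simulate`` (n_samples, max_steps), ``atm`` (flip_duration,
    flip_targets, flip_phases), ``tree`` (depth, samples), ``match``
    (target: <path>|hematopoietic, tolerance, budget, max_attractors),
    ``perturb`` (kind, targets, repetitions) and an output directory.
    """

    def __init__(self, raw: dict):
        if not isinstance(raw, dict):
            raise NetworkError("session config must be a mapping")
        self.raw = raw
        self.stages: list[str] = list(raw.get("stages", []))
        unknown = [s for s in self.stages if s not in _KNOWN_STAGES]
        if unknown:
            raise NetworkError(f"unknown stages {unknown}")
        self.seed = int(raw.get("seed", 0))
        self.count = int(raw.get("count", 1))
        if self.count < 1:
            raise NetworkError("count must be >= 1")
        self.mode = None
        if "generate" in raw and "augment" in raw:
            raise NetworkError("config must not define both generate and augment")
        if "generate" in raw:
            self.mode = "generate"
            bad = set(raw["generate"]) - _GEN_KEYS
            if bad:
                raise NetworkError(f"unknown generate keys {sorted(bad)}")
            self.generate_spec = GenerationSpec(**raw["generate"])
        if "augment" in raw:
            self.mode = "augment"
            body = dict(raw["augment"])
            self.core_source = body.pop("core", "synthetic")
            bad = set(body) - _AUG_KEYS
            if bad:
                raise NetworkError(f"unknown augment keys {sorted(bad)}")
            self.augment_spec = AugmentationSpec(**body)
        if "networks" in self.stages and self.mode is None:
            raise NetworkError("stage 'networks' requires a generate or augment block")
        self.simulate = dict(raw.get("simulate", {}))
        self.atm = dict(raw.get("atm", {}))
        self.tree = dict(raw.get("tree", {}))
        self.match = dict(raw.get("match", {}))
        self.perturb = dict(raw.get("perturb", {}))

    @classmethod
    def from_yaml(cls, path) -> "SessionConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def resolved(self) -> dict:
        out = dict(self.raw)
        out["stages"] = self.stages
        out["seed"] = self.seed
        out["count"] = self.count
        out["version"] = __version__
        return out


def _load_core(source: str) -> RegulatoryNetwork:
    if source == "synthetic":
        return synthetic_core()
    return read_network(source)


def _load_target(source: str):
    if source == "hematopoietic":
        return hematopoietic_tree()
    return read_tree(source)


def run_session(config: SessionConfig | dict, out_dir) -> Path:
    """Execute the configured stage chain, writing artifacts into
    ``out_dir``; a stage failure halts the chain with earlier artifacts
    intact.  Fully reproducible from the configuration and seeds."""
    if isinstance(config, dict):
        config = SessionConfig(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "session.yaml").write_text(
        yaml.safe_dump(config.resolved(), sort_keys=True)
    )

    master = np.random.SeedSequence(config.seed)
    stage_seeds = {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_KNOWN_STAGES, master.spawn(len(_KNOWN_STAGES)))
    }

    networks: list[RegulatoryNetwork] = []
    atlases = []
    atms = []

    for stage in config.stages:
        log.info("stage %s", stage)
        if stage == "networks":
            if config.mode == "generate":
                networks = generate_ensemble(
                    config.generate_spec, config.count, seed=stage_seeds["networks"]
                )
            else:
                core = _load_core(config.core_source)
                networks = augment_ensemble(
                    core, config.augment_spec, config.count,
                    seed=stage_seeds["networks"],
                )
            ndir = out / "networks"
            ndir.mkdir(exist_ok=True)
            for i, net in enumerate(networks):
                write_network(net, ndir / f"net{i:04d}.net")
            log.info("wrote %d networks", len(networks))

        elif stage == "simulate":
            if not networks:
                raise NetworkError("simulate stage requires networks")
            n_samples = int(config.simulate.get("n_samples", 500))
            max_steps = int(config.simulate.get("max_steps", 1000))
            seeds = np.random.SeedSequence(stage_seeds["simulate"]).spawn(len(networks))
            rows = []
            atlases = []
            for i, (net, child) in enumerate(zip(networks, seeds)):
                atlas = find_attractors(
                    net, mode="sampled", n_samples=n_samples, max_steps=max_steps,
                    seed=int(child.generate_state(1)[0] % 2**31),
                )
                atlases.append(atlas)
                if len(atlas) == 0:
                    # every trajectory hit the step cut-off
                    rows.append(
                        {
                            "network": i,
                            "n_attractors": 0,
                            "unresolved": atlas.unresolved_count,
                            "mean_frozen": "",
                            "lengths": "",
                        }
                    )
                    continue
                stats = attractor_statistics(atlas)
                rows.append(
                    {
                        "network": i,
                        "n_attractors": stats["n_attractors"],
                        "unresolved": atlas.unresolved_count,
                        "mean_frozen": round(stats["mean_frozen_proportion"], 6),
                        "lengths": ";".join(
                            f"{k}x{v}" for k, v in stats["length_histogram"].items()
                        ),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "attractors.csv", index=False)

        elif stage == "atm":
            if not atlases:
                raise NetworkError("atm stage requires simulated atlases")
            flip = FlipSpec(
                duration=int(config.atm.get("flip_duration", 1)),
                targets=tuple(config.atm["flip_targets"])
                if config.atm.get("flip_targets")
                else None,
                phases=config.atm.get("flip_phases"),
            )
            seeds = np.random.SeedSequence(stage_seeds["atm"]).spawn(len(networks))
            max_att = int(config.atm.get("max_attractors", 64))
            atms = []
            adir = out / "atm"
            adir.mkdir(exist_ok=True)
            for i, (net, atlas, child) in enumerate(zip(networks, atlases, seeds)):
                if len(atlas) == 0 or len(atlas) > max_att:
                    atms.append(None)
                    continue
                atm = build_atm(
                    net, atlas, flip=flip,
                    max_steps=atlas.max_steps,
                    seed=int(child.generate_state(1)[0] % 2**31),
                )
                atms.append(atm)
                lines = [
                    f"A{i_} A{j_} {p:.10g}" for i_, j_, p in atm.edge_list()
                ]
                (adir / f"atn{i:04d}.txt").write_text(
                    "\n".join(lines) + ("\n" if lines else "")
                )

        elif stage == "tree":
            if not atms:
                raise NetworkError("tree stage requires ATMs")
            tdir = out / "trees"
            tdir.mkdir(exist_ok=True)
            for i, atm in enumerate(atms):
                if atm is None:
                    continue
                tree = build_tree(sweep_thresholds(atm))
                write_tree(tree, tdir / f"tree{i:04d}.tsv")

        elif stage == "match":
            if not networks:
                raise NetworkError("match stage requires networks")
            target = _load_target(config.match.get("target", "hematopoietic"))
            results = match_ensemble(
                networks,
                target,
                tolerance=float(config.match.get("tolerance", 0)),
                budget=int(config.match.get("budget", 200)),
                n_samples=int(config.simulate.get("n_samples", 500)),
                max_steps=int(config.simulate.get("max_steps", 1000)),
                seed=stage_seeds["match"],
                max_attractors=int(config.match.get("max_attractors", 64)),
            )
            df = pd.DataFrame(
                [
                    {
                        "network": r.index,
                        "matched": r.matched,
                        "best_d_hat": "" if r.best_distance is None else r.best_distance,
                        "thresholds": ""
                        if r.best_thresholds is None
                        else ";".join(f"{t:.10g}" for t in r.best_thresholds),
                        "undetermined": r.undetermined,
                        "n_attractors": r.n_attractors,
                    }
                    for r in results
                ]
            )
            df.to_csv(out / "match_report.csv", index=False)
            log.info(
                "match: %d/%d matched, %d undetermined",
                int(df["matched"].sum()), len(df), int(df["undetermined"].sum()),
            )

        elif stage == "perturb":
            if not networks:
                raise NetworkError("perturb stage requires networks")
            kind = config.perturb.get("kind", "knockout")
            if kind == "ko-tree-screen":
                target = _load_target(config.perturb.get("target", "hematopoietic"))
                net = networks[int(config.perturb.get("network", 0))]
                genes = config.perturb.get("genes") or list(net.core_nodes)
                df = ko_tree_screen(
                    net, genes, target,
                    n_samples=int(config.simulate.get("n_samples", 500)),
                    max_steps=int(config.simulate.get("max_steps", 1000)),
                    budget=int(config.perturb.get("budget", 100)),
                    seed=stage_seeds["perturb"],
                )
                df.to_csv(out / "ko_tree_screen.csv", index=False)
            else:
                frames = []
                seeds = np.random.SeedSequence(stage_seeds["perturb"]).spawn(
                    len(networks)
                )
                for i, (net, child) in enumerate(zip(networks, seeds)):
                    df = run_perturbation_experiments(
                        net,
                        kind=kind,
                        targets=config.perturb.get("targets"),
                        repetitions=int(config.perturb.get("repetitions", 1)),
                        horizon=int(config.simulate.get("max_steps", 1000)),
                        seed=int(child.generate_state(1)[0] % 2**31),
                    )
                    df.insert(0, "network", i)
                    frames.append(df)
                pd.concat(frames, ignore_index=True).to_csv(
                    out / "perturbations.csv", index=False
                )

        elif stage == "stats":
            if not networks:
                raise NetworkError("stats stage requires networks")
            rows = []
            for i, net in enumerate(networks):
                m = network_measures(net)
                rows.append(
                    {
                        "network": i,
                        "n_nodes": m["n_nodes"],
                        "n_edges": m["n_edges"],
                        "clustering": round(m["clustering_coefficient"], 6),
                        "diameter": m["diameter"],
                        "avg_path_length": None
                        if m["average_path_length"] is None
                        else round(m["average_path_length"], 6),
                    }
                )
            pd.DataFrame(rows).to_csv(out / "network_measures.csv", index=False)

    return out
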