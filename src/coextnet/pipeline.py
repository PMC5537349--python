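"""End-to-end study runs: simulate, analyse, and write deterministic outputs.

``run_full_study`` drives the whole protocol from one sectioned YAML
config: obtain a community (synthetic preset or network + IPD files),
simulate the stochastic model for every requested scenario and variant
alongside the topological baseline, and write tidy CSV tables — per-plant
robustness, richness-decay curves per variant, per-scenario survival
surfaces, the keystone single-deletion scan with functional-group
summaries, and trait correlations — plus a JSON manifest with input
checksums and the config echo, so a run is reproducible bit-for-bit
from its manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .analytics import (
    functional_group_summary,
    keystone_scan,
    plant_robustness,
    robustness_table,
    trait_correlations,
)
from .errors import ConfigError
from .ipd import dependence_array, read_ipd, write_ipd
from .network import degree, eigenvector_centrality, interaction_evenness, read_network, write_network
from .scm import SimulationConfig, run_simulation
from .synthetic import generate_community, preset
from .tcm import run_tcm

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_full_study", "load_config"]

_FLOAT_FMT = "%.6g"


@dataclass
class RunManifest:
    """Record of one full study run: inputs, config, outputs, checksums."""

    version: str
    config: dict
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    stages_completed: list[str] = field(default_factory=list)
    failed_stage: str | None = None

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path) -> dict:
    """Load and minimally validate a sectioned YAML study config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "input" not in cfg:
        raise ConfigError("config must be a mapping with an 'input' section")
    return cfg


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    manifest.outputs[path.name] = _sha256(path)


def run_full_study(config, out_dir=None) -> tuple[Path, RunManifest]:
    """Execute the full simulation-and-analysis protocol.

    ``config`` is a dict or a YAML path with sections ``input``
    (``preset`` name or ``network``/``ipd`` paths), ``simulation``
    (``replicates``, ``scenarios``, ``variants``, ``seed``),
    ``keystone`` (``replicates``) and ``output`` (``dir``).
    Any stage failure aborts with the stage named; outputs written so
    far stay listed in the manifest with ``failed_stage`` set.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    out = Path(out_dir or config.get("output", {}).get("dir", "coextnet_out"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, config=config)
    stage = "input"
    try:
        inp = config["input"]
        sim_cfg = config.get("simulation", {})
        replicates = int(sim_cfg.get("replicates", 10_000))
        scenarios = list(sim_cfg.get("scenarios", ["random"]))
        variants = list(sim_cfg.get("variants", ["F"]))
        seed = int(sim_cfg.get("seed", 0))

        if "preset" in inp:
            spec = preset(inp["preset"], seed=int(inp.get("seed", seed)))
            network, dep = generate_community(spec)
            write_network(network, out / "network.csv")
            write_ipd(dep, out / "ipd.csv")
            manifest.inputs["preset"] = inp["preset"]
        else:
            network = read_network(inp["network"])
            dep = read_ipd(inp["ipd"])
            manifest.inputs["network"] = _sha256(Path(inp["network"]))
            manifest.inputs["ipd"] = _sha256(Path(inp["ipd"]))
        dependence_array(network, dep)
        manifest.outputs.update(
            {p.name: _sha256(p) for p in (out / "network.csv", out / "ipd.csv") if p.exists()}
        )
        manifest.stages_completed.append(stage)

        # -- simulations ------------------------------------------------
        stage = "simulate"
        surfaces = {}
        for scenario in scenarios:
            for variant in variants:
                cfg = SimulationConfig(
                    replicates=replicates, scenario=scenario, variant=variant,
                    seed=seed,
                )
                surfaces[("SCM", variant, scenario)] = run_simulation(
                    network, dep, cfg
                )
                logger.info("simulated SCM-%s under %s", variant, scenario)
            tcm_cfg = SimulationConfig(
                replicates=replicates, scenario=scenario, seed=seed
            )
            surfaces[("TCM", None, scenario)] = run_tcm(network, tcm_cfg)
        manifest.stages_completed.append(stage)

        # -- robustness table (Fig. 1-style comparison) -----------------
        stage = "robustness"
        rob = pd.concat(
            [robustness_table(s) for s in surfaces.values()], ignore_index=True
        )
        _write_csv(rob, out / "robustness.csv", manifest)
        manifest.stages_completed.append(stage)

        # -- richness decay per variant (Fig. 2-style) ------------------
        stage = "richness_decay"
        frames = []
        for (model, variant, scenario), surf in surfaces.items():
            df = surf.richness_frame()
            df["model"] = model if model == "TCM" else f"SCM-{variant}"
            df["scenario"] = scenario
            frames.append(df)
        _write_csv(pd.concat(frames, ignore_index=True),
                   out / "richness_decay.csv", manifest)
        manifest.stages_completed.append(stage)

        # -- survival surfaces (Fig. 3-style heatmap tables) ------------
        stage = "survival_surfaces"
        base_variant = "F" if "F" in variants else variants[0]
        for scenario in scenarios:
            surf = surfaces[("SCM", base_variant, scenario)]
            _write_csv(surf.to_frame(), out / f"survival_surface_{scenario}.csv",
                       manifest)
        manifest.stages_completed.append(stage)

        # -- keystone scan and guild summary (Figs 4/5-style) -----------
        stage = "keystone"
        key_reps = int(config.get("keystone", {}).get("replicates", replicates))
        keystone = keystone_scan(network, dep, replicates=key_reps, seed=seed)
        _write_csv(keystone, out / "keystone.csv", manifest)
        _write_csv(functional_group_summary(keystone),
                   out / "functional_groups.csv", manifest)
        manifest.stages_completed.append(stage)

        # -- trait correlations -----------------------------------------
        stage = "correlations"
        rows = []
        surf = surfaces[("SCM", base_variant, scenarios[0])]
        plant_surv = {p: plant_robustness(surf.trajectory(p)) for p in surf.plant_ids}
        centrality = eigenvector_centrality(network)
        plant_traits = {
            "ipd": {p: float(dep[p]) for p in network.plant_ids},
            "degree_norm": {
                p: degree(network, p, normalised=True) for p in network.plant_ids
            },
            "evenness": {
                p: interaction_evenness(network, p) for p in network.plant_ids
            },
            "centrality": {p: centrality[p] for p in network.plant_ids},
        }
        y = np.array([plant_surv[p] for p in network.plant_ids])
        for name, trait in plant_traits.items():
            x = np.array([trait[p] for p in network.plant_ids])
            try:
                rho, p_val = trait_correlations(x, y)
            except Exception:
                continue  # constant trait on a degenerate community
            rows.append({"side": "plant", "trait": name,
                         "outcome": "survival", "rho": rho, "p": p_val})
        for name in ("degree_norm", "evenness", "centrality", "strength"):
            try:
                rho, p_val = trait_correlations(
                    keystone[name].to_numpy(), keystone["mean_survivors"].to_numpy()
                )
            except Exception:
                continue
            rows.append({"side": "pollinator", "trait": name,
                         "outcome": "mean_survivors", "rho": rho, "p": p_val})
        _write_csv(pd.DataFrame(rows), out / "correlations.csv", manifest)
        manifest.stages_completed.append(stage)
    except Exception:
        manifest.failed_stage = stage
        manifest.write(out / "manifest.json")
        logger.error("study aborted during stage %r", stage)
        raise
    manifest.write(out / "manifest.json")
    return out, manifest
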