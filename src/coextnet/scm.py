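"""Hybrid stochastic coextinction model (SCM) for pollinator loss.

The model removes pollinators one at a time (the primary extinctions)
and lets extinction cascades settle after each removal:

* **Plants are stochastic.**  When pollinator ``j`` is removed, every
  extant plant partner ``i`` survives with probability
  ``P_ij = 1 - IPD_i * d_ij``, where ``IPD_i`` is the plant's intrinsic
  dependence on insect pollination and ``d_ij`` its relative dependence
  on ``j`` among the currently surviving partners (including ``j``
  itself).  Relative dependences are recalculated after every event, so
  surviving pollinators absorb the visitation share of lost ones;
  ``d_ij = 1`` when ``j`` is the plant's last surviving partner.

* **Pollinators are topological.**  A pollinator goes secondarily
  extinct exactly when it has lost all extant plant partners; such
  losses trigger no further plant draws (their plant partners are
  already gone), so every cascade settles in one step.

No rewiring: interactions lost to an extinction never reappear.

Four model variants control which empirical ingredients are kept:
``F`` (full: empirical IPD and weights), ``D`` (all plants fully
dependent, IPD = 1), ``H`` (homogeneous interaction strengths) and
``DH`` (both simplifications).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .errors import CascadeError, ConfigError, DependenceError
from .ipd import DependenceVector, dependence_array
from .network import CascadeState, InteractionNetwork
from .results import SurvivalSurface

__all__ = [
    "ModelVariant",
    "ScenarioKind",
    "SimulationConfig",
    "ReplicateOutcome",
    "survival_probability",
    "apply_variant",
    "scenario_order",
    "remove_pollinator",
    "run_replicate",
    "run_simulation",
]

ModelVariant = Literal["F", "D", "H", "DH"]
ScenarioKind = Literal["random", "generalist", "specialist"]

_VARIANTS = ("F", "D", "H", "DH")
_SCENARIOS = ("random", "generalist", "specialist")


@dataclass(frozen=True)
class SimulationConfig:
    """Fully determines a simulation run given a network and IPD vector."""

    replicates: int = 10_000
    scenario: ScenarioKind = "random"
    variant: ModelVariant = "F"
    seed: int = 0
    #: "static" fixes each replicate's removal order from initial degrees;
    #: "dynamic" re-ranks extant pollinators by current degree each event.
    order_mode: Literal["static", "dynamic"] = "static"
    engine: Literal["vectorized", "loop"] = "vectorized"

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ConfigError("replicates must be >= 1")
        if self.variant not in _VARIANTS:
            raise ConfigError(f"unknown variant {self.variant!r}")
        if self.scenario not in _SCENARIOS:
            raise ConfigError(f"unknown scenario {self.scenario!r}")
        if self.order_mode not in ("static", "dynamic"):
            raise ConfigError(f"unknown order mode {self.order_mode!r}")


@dataclass(frozen=True)
class ReplicateOutcome:
    """Extant-species trajectories of one replicate.

    ``plants_extant[k]`` / ``pollinators_extant[k]`` give the extant
    masks after event ``k`` settled (row 0 = initial state).
    """

    plants_extant: np.ndarray  # (n_events + 1, n_plants) bool
    pollinators_extant: np.ndarray  # (n_events + 1, n_pollinators) bool


def survival_probability(ipd_i: float, d_ij: float) -> float:
    """P_ij = 1 - IPD_i * d_ij, the plant's chance of surviving the loss."""
    if not 0.0 <= ipd_i <= 1.0:
        raise DependenceError(f"IPD outside [0, 1]: {ipd_i}")
    if not 0.0 <= d_ij <= 1.0:
        raise DependenceError(f"relative dependence outside [0, 1]: {d_ij}")
    return 1.0 - ipd_i * d_ij


def apply_variant(
    network: InteractionNetwork,
    dep: DependenceVector,
    variant: ModelVariant,
) -> tuple[InteractionNetwork, DependenceVector]:
    """Return the (network, dependence) pair a model variant simulates.

    ``D`` forces IPD = 1 for every plant; ``H`` replaces each plant's
    positive weights by equal values (so d_ij = 1/k_i), preserving the
    topology; ``DH`` composes both; ``F`` is the identity.  Inputs are
    never mutated.
    """
    if variant not in _VARIANTS:
        raise ConfigError(f"unknown variant {variant!r}")
    out_net = network
    out_dep = dict(dep)
    if "H" in variant:
        hom = (network.visits > 0).astype(float)
        out_net = InteractionNetwork(
            network.plant_ids, network.pollinator_ids, hom, dict(network.guild)
        )
    if "D" in variant:
        out_dep = {p: 1.0 for p in network.plant_ids}
    return out_net, out_dep


def scenario_order(
    network: InteractionNetwork,
    scenario: ScenarioKind,
    rng: np.random.Generator,
) -> list[str]:
    """One replicate's primary-removal order.

    Generalist removes from the most to the least connected pollinator
    (by initial degree), specialist the reverse, random uniformly; ties
    in degree are broken by a fresh uniform shuffle.
    """
    order = _scenario_orders(network, scenario, rng, 1)[0]
    return [network.pollinator_ids[j] for j in order]


def _scenario_orders(
    network: InteractionNetwork,
    scenario: ScenarioKind,
    rng: np.random.Generator,
    replicates: int,
) -> np.ndarray:
    """(replicates, n_pollinators) integer removal orders."""
    n_p = network.n_pollinators
    keys = rng.random((replicates, n_p))
    if scenario == "random":
        return np.argsort(keys, axis=1)
    deg = network.pollinator_degrees()
    rank = -deg if scenario == "generalist" else deg
    # shuffle first, then stable-sort by degree: uniform tie-breaking
    perm = np.argsort(keys, axis=1)
    idx = np.argsort(rank[perm], axis=1, kind="stable")
    return np.take_along_axis(perm, idx, axis=1)


# ----------------------------------------------------------------------
# Per-replicate reference path
# ----------------------------------------------------------------------


def remove_pollinator(
    state: CascadeState,
    pollinator: str,
    dep: DependenceVector,
    rng: np.random.Generator,
) -> tuple[CascadeState, list[dict]]:
    """Remove one extant pollinator and settle the resulting cascade.

    Every extant plant partner draws survival against
    ``P_ij = 1 - IPD_i * d_ij`` with ``d_ij`` computed over its extant
    partners *including* the pollinator being removed (pre-removal
    denominator); all draws are simultaneous and independent.  Plants
    that fail are removed, and pollinators left without extant plant
    partners follow topologically (no further plant draws — their
    partners are already extinct).  Returns the settled state and an
    extinction log.
    """
    net = state.network
    if pollinator not in state.extant_pollinators:
        raise CascadeError(f"pollinator {pollinator!r} is not extant")
    j = net.pollinator_index(pollinator)
    pol_mask = state.pollinator_mask()
    log: list[dict] = [{"species": pollinator, "role": "pollinator", "kind": "primary"}]

    dead_plants: set[str] = set()
    # iterate in network order: draw sequence must not depend on set hashing
    for i, plant in enumerate(net.plant_ids):
        if plant not in state.extant_plants:
            continue
        if net.visits[i, j] <= 0:
            continue  # no shared interaction, no draw
        denom = float(np.where(pol_mask, net.visits[i], 0.0).sum())
        d_ij = net.visits[i, j] / denom
        p_surv = survival_probability(float(dep[plant]), d_ij)
        if rng.random() >= p_surv:
            dead_plants.add(plant)
            log.append({"species": plant, "role": "plant", "kind": "secondary"})

    new_plants = state.extant_plants - dead_plants
    new_pols = state.extant_pollinators - {pollinator}
    # topological rule: prune pollinators with no extant plant partner
    plant_rows = [net.plant_index(p) for p in new_plants]
    for other in sorted(new_pols):
        jj = net.pollinator_index(other)
        if not plant_rows or not np.any(net.visits[plant_rows, jj] > 0):
            new_pols.discard(other)
            log.append({"species": other, "role": "pollinator", "kind": "secondary"})
    return CascadeState(net, new_plants, new_pols), log


def run_replicate(
    network: InteractionNetwork,
    dep: DependenceVector,
    order: list[str],
    rng: np.random.Generator,
) -> ReplicateOutcome:
    """Run one full removal sequence (reference, non-vectorised path).

    ``order`` must be a permutation of the pollinators.  A scheduled
    removal whose target already went secondarily extinct is skipped but
    still consumes an event index, so every replicate spans exactly
    ``n_pollinators`` events.
    """
    if sorted(order) != sorted(network.pollinator_ids):
        raise CascadeError("order must be a permutation of the pollinators")
    n_p = network.n_pollinators
    state = CascadeState.initial(network)
    plants = np.ones((n_p + 1, network.n_plants), dtype=bool)
    pols = np.ones((n_p + 1, n_p), dtype=bool)
    for k, target in enumerate(order, start=1):
        if target in state.extant_pollinators:
            state, _ = remove_pollinator(state, target, dep, rng)
        plants[k] = state.plant_mask()
        pols[k] = state.pollinator_mask()
    return ReplicateOutcome(plants, pols)


# ----------------------------------------------------------------------
# Vectorised engine
# ----------------------------------------------------------------------


def _simulate_vectorized(
    visits: np.ndarray,
    ipd: np.ndarray,
    config: SimulationConfig,
    orders: np.ndarray | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All replicates in parallel over one RNG stream.

    Returns (plant_survival (n_plants, n_p + 1), mean extant plants,
    mean extant pollinators) per event.
    """
    n_a, n_p = visits.shape
    r = config.replicates
    rows = np.arange(r)
    pos = visits > 0
    pos_f = pos.astype(float)
    extant_p = np.ones((r, n_a), dtype=bool)
    extant_a = np.ones((r, n_p), dtype=bool)
    live_sum = np.broadcast_to(visits.sum(axis=1), (r, n_a)).copy()

    plant_counts = np.zeros((n_p + 1, n_a))
    plant_counts[0] = r
    mean_plants = np.zeros(n_p + 1)
    mean_pols = np.zeros(n_p + 1)
    mean_plants[0], mean_pols[0] = n_a, n_p

    dynamic = config.order_mode == "dynamic"

    for k in range(1, n_p + 1):
        if dynamic:
            cur_deg = (extant_p.astype(float) @ pos_f) * extant_a
            if config.scenario == "random":
                score = rng.random((r, n_p))
            else:
                sign = 1.0 if config.scenario == "generalist" else -1.0
                score = sign * cur_deg + rng.random((r, n_p))
            score[~extant_a] = -np.inf
            j = np.argmax(score, axis=1)
            active = extant_a.any(axis=1)
        else:
            j = orders[:, k - 1]
            active = extant_a[rows, j]
        vj = visits.T[j]  # (r, n_a)
        partner = (vj > 0) & extant_p & active[:, None]
        d = np.zeros((r, n_a))
        np.divide(vj, live_sum, out=d, where=partner)
        u = rng.random((r, n_a))
        die = partner & (u < ipd[None, :] * d)
        extant_a[rows[active], j[active]] = False
        extant_p &= ~die
        # topological pruning of unsupported pollinators
        support = extant_p.astype(float) @ pos_f
        extant_a &= support > 0
        live_sum = extant_a.astype(float) @ visits.T
        plant_counts[k] = extant_p.sum(axis=0)
        mean_plants[k] = extant_p.sum(axis=1).mean()
        mean_pols[k] = extant_a.sum(axis=1).mean()
    return plant_counts / r, mean_plants, mean_pols


def _simulate_loop(
    network: InteractionNetwork,
    dep: DependenceVector,
    config: SimulationConfig,
    orders: np.ndarray,
    root: np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Replicate-at-a-time engine with per-replicate child seeds."""
    n_a, n_p = network.n_plants, network.n_pollinators
    plant_counts = np.zeros((n_p + 1, n_a))
    mean_plants = np.zeros(n_p + 1)
    mean_pols = np.zeros(n_p + 1)
    children = root.spawn(config.replicates)
    for rep in range(config.replicates):
        rng = np.random.default_rng(children[rep])
        order = [network.pollinator_ids[j] for j in orders[rep]]
        outcome = run_replicate(network, dep, order, rng)
        plant_counts += outcome.plants_extant
        mean_plants += outcome.plants_extant.sum(axis=1)
        mean_pols += outcome.pollinators_extant.sum(axis=1)
    r = config.replicates
    return plant_counts / r, mean_plants / r, mean_pols / r


def run_simulation(
    network: InteractionNetwork,
    dep: DependenceVector,
    config: SimulationConfig,
) -> SurvivalSurface:
    """Estimate the full survival surface under one scenario and variant.

    Runs ``config.replicates`` independent removal sequences and returns,
    for every plant and event index, the fraction of replicates in which
    the plant was extant after the event's cascade settled, together
    with community richness-decay curves.  Bit-reproducible from
    ``config.seed``.
    """
    dependence_array(network, dep)  # validates coverage and range
    net_v, dep_v = apply_variant(network, dep, config.variant)
    ipd = dependence_array(net_v, dep_v)
    ss = np.random.SeedSequence(config.seed)
    ss_orders, ss_draws = ss.spawn(2)
    order_rng = np.random.default_rng(ss_orders)
    orders = None
    if config.order_mode == "static":
        orders = _scenario_orders(net_v, config.scenario, order_rng, config.replicates)
    if config.engine == "vectorized":
        draw_rng = np.random.default_rng(ss_draws)
        surv_t, mean_plants, mean_pols = _simulate_vectorized(
            net_v.visits, ipd, config, orders, draw_rng
        )
    elif config.engine == "loop":
        if config.order_mode == "dynamic":
            raise ConfigError("dynamic ranking requires the vectorized engine")
        surv_t, mean_plants, mean_pols = _simulate_loop(
            net_v, dep_v, config, orders, ss_draws
        )
    else:
        raise ConfigError(f"unknown engine {config.engine!r}")

    n_a, n_p = network.n_plants, network.n_pollinators
    meta = {
        "model": "SCM",
        "variant": config.variant,
        "scenario": config.scenario,
        "order_mode": config.order_mode,
        "replicates": config.replicates,
        "seed": config.seed,
    }
    return SurvivalSurface(
        plant_ids=network.plant_ids,
        survival=surv_t.T,
        frac_plants=mean_plants / n_a,
        frac_pollinators=mean_pols / n_p,
        frac_species=(mean_plants + mean_pols) / (n_a + n_p),
        meta=meta,
    )


def variant_description(variant: ModelVariant) -> str:
    return {
        "F": "full model (empirical IPD, empirical interaction strengths)",
        "D": "all plants fully dependent (IPD = 1)",
        "H": "homogeneous interaction strengths",
        "DH": "IPD = 1 and homogeneous interaction strengths",
    }[variant]
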