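"""Topological coextinction model (TCM) baseline.

The classic static model: a plant goes extinct exactly when all of its
pollinator partners have been removed, regardless of interaction
strengths or of its intrinsic dependence on pollination.  Pollinator
loss is purely primary here — a plant only dies once its whole partner
set is gone, so a surviving pollinator can never be stranded by plant
deaths and no secondary pollinator extinctions occur.

Given a removal order the outcome is deterministic; randomness enters
only through random orders and degree-tie shuffles, exactly as in the
stochastic model, so the two models are compared on identically
distributed removal sequences.
"""

from __future__ import annotations

import numpy as np

from .network import InteractionNetwork
from .results import SurvivalSurface
from .scm import SimulationConfig, _scenario_orders

__all__ = ["run_tcm", "tcm_robustness"]


def run_tcm(network: InteractionNetwork, config: SimulationConfig) -> SurvivalSurface:
    """Survival surface under the purely topological model.

    ``config.variant`` is ignored (the TCM is blind to weights and IPD);
    scenario, replicates and seed are honoured so surfaces are directly
    comparable with :func:`coextnet.scm.run_simulation`.
    """
    n_a, n_p = network.n_plants, network.n_pollinators
    ss = np.random.SeedSequence(config.seed)
    ss_orders, _ = ss.spawn(2)
    rng = np.random.default_rng(ss_orders)
    orders = _scenario_orders(network, config.scenario, rng, config.replicates)
    # pos[r, j] = event index (1-based) at which pollinator j is removed
    pos = np.argsort(orders, axis=1) + 1
    partners = network.visits > 0  # (n_a, n_p)
    surv = np.zeros((n_a, n_p + 1))
    death_event = np.empty((config.replicates, n_a), dtype=np.int64)
    for i in range(n_a):
        death_event[:, i] = pos[:, partners[i]].max(axis=1)
    events = np.arange(n_p + 1)
    for i in range(n_a):
        # extant after event k iff the last partner falls after event k
        surv[i] = (death_event[:, i][:, None] > events[None, :]).mean(axis=0)
    mean_plants = surv.sum(axis=0)  # expected extant plants per event
    mean_pols = (n_p - events).astype(float)
    meta = {
        "model": "TCM",
        "variant": None,
        "scenario": config.scenario,
        "replicates": config.replicates,
        "seed": config.seed,
    }
    return SurvivalSurface(
        plant_ids=network.plant_ids,
        survival=surv,
        frac_plants=mean_plants / n_a,
        frac_pollinators=mean_pols / n_p,
        frac_species=(mean_plants + mean_pols) / (n_a + n_p),
        meta=meta,
    )


def tcm_robustness(surface: SurvivalSurface) -> dict[str, float]:
    """Per-plant robustness of a TCM surface (area under the decay curve)."""
    from .analytics import plant_robustness

    return {
        plant: plant_robustness(surface.trajectory(plant))
        for plant in surface.plant_ids
    }
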