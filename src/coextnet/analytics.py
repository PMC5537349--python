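"""Robustness, exact expectations, keystone scans and trait correlations.

Robustness R_i of a plant is the area under its survival-probability
curve plotted against the fraction of extinction events (x = k / N_P,
x in [0, 1]): R_i = 1 for a plant whose survival never drops, R_i near 0
for one that collapses at the first removal.

The module also carries two independent cross-checks on the simulator:
a first-step closed form (under a uniformly random first removal the
expected survival of plant i is 1 - IPD_i / N_P, because d_ij summed
over partners is 1 and 0 elsewhere) and a full enumeration oracle that
computes exact per-event survival probabilities on tiny networks by
walking every removal order and every Bernoulli branch.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DependenceError, NetworkValidationError, SizeError
from .ipd import DependenceVector, dependence_array
from .network import (
    InteractionNetwork,
    degree,
    eigenvector_centrality,
    interaction_evenness,
    species_strength,
)
from .results import SurvivalSurface

__all__ = [
    "plant_robustness",
    "robustness_table",
    "analytic_expected_survival_first_step",
    "exhaustive_expected_survival",
    "keystone_scan",
    "functional_group_summary",
    "trait_correlations",
]


def plant_robustness(trajectory: np.ndarray) -> float:
    """Area under one plant's survival curve over x = k / N_P.

    ``trajectory`` holds survival probabilities at events 0..N_P (the
    leading 1.0 included); it must start at 1, stay in [0, 1] and be
    non-increasing.
    """
    t = np.asarray(trajectory, dtype=float)
    if t.ndim != 1 or t.size < 2:
        raise NetworkValidationError("trajectory must cover events 0..N_P")
    if abs(t[0] - 1.0) > 1e-9:
        raise NetworkValidationError("survival at event 0 must be 1")
    if np.any((t < -1e-9) | (t > 1 + 1e-9)):
        raise NetworkValidationError("survival outside [0, 1]")
    if np.any(np.diff(t) > 1e-9):
        raise NetworkValidationError("survival must be non-increasing")
    x = np.linspace(0.0, 1.0, t.size)
    return float(np.trapezoid(t, x))


def robustness_table(surface: SurvivalSurface) -> pd.DataFrame:
    """Tidy per-plant robustness records for one survival surface."""
    meta = surface.meta
    model = meta.get("model", "SCM")
    if model == "SCM" and meta.get("variant"):
        model = f"SCM-{meta['variant']}"
    return pd.DataFrame(
        {
            "plant": surface.plant_ids,
            "robustness": [
                plant_robustness(surface.trajectory(p)) for p in surface.plant_ids
            ],
            "model": model,
            "scenario": meta.get("scenario"),
        }
    )


def analytic_expected_survival_first_step(
    network: InteractionNetwork, dep: DependenceVector, plant: str
) -> float:
    """Closed-form survival after one uniformly random removal: 1 - IPD_i/N_P."""
    i = network.plant_index(plant)
    ipd = dependence_array(network, dep)[i]
    return 1.0 - float(ipd) / network.n_pollinators


# ----------------------------------------------------------------------
# Enumeration oracle
# ----------------------------------------------------------------------


def exhaustive_expected_survival(
    network: InteractionNetwork,
    dep: DependenceVector,
    *,
    max_pollinators: int = 5,
) -> np.ndarray:
    """Exact per-plant, per-event survival under the random scenario.

    Enumerates all N_P! removal orders and, within each, every Bernoulli
    branch of the cascade, merging probabilistically identical states.
    Returns an ``(n_plants, n_pollinators + 1)`` matrix of exact
    survival probabilities (column 0 is all ones).  Combinatorial, so
    restricted to ``n_pollinators <= max_pollinators``.
    """
    n_a, n_p = network.n_plants, network.n_pollinators
    if n_p > max_pollinators:
        raise SizeError(
            f"{n_p} pollinators exceed the enumeration cap ({max_pollinators})"
        )
    visits = network.visits
    ipd = dependence_array(network, dep)
    pos = visits > 0
    surv = np.zeros((n_a, n_p + 1))
    surv[:, 0] = 1.0
    full_p = (1 << n_a) - 1
    full_a = (1 << n_p) - 1
    n_orders = math.factorial(n_p)

    for order in itertools.permutations(range(n_p)):
        states: dict[tuple[int, int], float] = {(full_p, full_a): 1.0}
        for k, j in enumerate(order, start=1):
            new_states: dict[tuple[int, int], float] = {}
            for (pm, am), prob in states.items():
                if not (am >> j) & 1:  # already secondarily extinct: skip
                    new_states[(pm, am)] = new_states.get((pm, am), 0.0) + prob
                    continue
                partners = [i for i in range(n_a) if (pm >> i) & 1 and pos[i, j]]
                p_die = []
                for i in partners:
                    denom = sum(visits[i, jj] for jj in range(n_p) if (am >> jj) & 1)
                    p_die.append(ipd[i] * visits[i, j] / denom)
                for bits in range(1 << len(partners)):
                    branch = prob
                    dead = 0
                    for idx, i in enumerate(partners):
                        if (bits >> idx) & 1:
                            branch *= p_die[idx]
                            dead |= 1 << i
                        else:
                            branch *= 1.0 - p_die[idx]
                    if branch == 0.0:
                        continue
                    pm2 = pm & ~dead
                    am2 = am & ~(1 << j)
                    for jj in range(n_p):
                        if (am2 >> jj) & 1 and not any(
                            (pm2 >> i) & 1 and pos[i, jj] for i in range(n_a)
                        ):
                            am2 &= ~(1 << jj)
                    key = (pm2, am2)
                    new_states[key] = new_states.get(key, 0.0) + branch
            states = new_states
            for (pm, _), prob in states.items():
                for i in range(n_a):
                    if (pm >> i) & 1:
                        surv[i, k] += prob
    surv[:, 1:] /= n_orders
    return surv


# ----------------------------------------------------------------------
# Keystone identification
# ----------------------------------------------------------------------


def keystone_scan(
    network: InteractionNetwork,
    dep: DependenceVector,
    *,
    replicates: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Selective single-pollinator deletion scan.

    For every pollinator, simulates its removal from the intact network
    ``replicates`` times, lets the cascade settle, and records the mean
    number (and fraction) of surviving plants, alongside the species'
    structural covariates on the initial network: normalised degree,
    interaction evenness, eigenvector centrality, species strength and
    functional group.  Keystones are the pollinators whose loss leaves
    the fewest plants.
    """
    n_a = network.n_plants
    ipd = dependence_array(network, dep)
    row_sums = network.visits.sum(axis=1)
    centrality = eigenvector_centrality(network)
    rng = np.random.default_rng(seed)
    records = []
    for j, pol in enumerate(network.pollinator_ids):
        partners = np.flatnonzero(network.visits[:, j] > 0)
        d = network.visits[partners, j] / row_sums[partners]
        p_die = ipd[partners] * d
        deaths = (rng.random((replicates, partners.size)) < p_die).sum(axis=1)
        mean_survivors = n_a - float(deaths.mean())
        records.append(
            {
                "pollinator": pol,
                "mean_survivors": mean_survivors,
                "mean_surviving_fraction": mean_survivors / n_a,
                "mean_coextinctions": n_a - mean_survivors,
                "degree_norm": degree(network, pol, normalised=True),
                "evenness": interaction_evenness(network, pol),
                "centrality": centrality[pol],
                "strength": species_strength(network, pol),
                "guild": network.guild.get(pol, "unassigned"),
            }
        )
    return pd.DataFrame(records)


def functional_group_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Mean surviving-plant fraction per pollinator functional group.

    Also reports the overall single-removal average (species weighted
    equally) under the pseudo-group ``__overall__``.  Records without a
    guild are grouped under ``unassigned`` with a warning.
    """
    df = records.copy()
    if df["guild"].isna().any() or (df["guild"] == "unassigned").any():
        df["guild"] = df["guild"].fillna("unassigned")
        if (df["guild"] == "unassigned").any():
            warnings.warn("records without guild grouped under 'unassigned'",
                          stacklevel=2)
    out = (
        df.groupby("guild", sort=True)["mean_surviving_fraction"]
        .agg(mean_surviving_fraction="mean", n_species="size")
        .reset_index()
    )
    overall = pd.DataFrame(
        {
            "guild": ["__overall__"],
            "mean_surviving_fraction": [df["mean_surviving_fraction"].mean()],
            "n_species": [len(df)],
        }
    )
    return pd.concat([out, overall], ignore_index=True)


# ----------------------------------------------------------------------
# Correlations
# ----------------------------------------------------------------------


def trait_correlations(x, y, *, exact_threshold: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p-value.

    Ties receive average ranks.  For n > ``exact_threshold`` the usual
    t-approximation is used; for small samples the p-value is exact,
    from full enumeration of the n! rank permutations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DependenceError("correlation undefined for a constant vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if n > exact_threshold:
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    ry_c = ry - ry.mean()
    rx_c = rx - rx.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    target = abs(rho) - 1e-12
    count = 0
    total = math.factorial(n)
    chunk: list[tuple] = []

    def flush(chunk_perms) -> int:
        perms = np.array(chunk_perms)
        rhos = (rx_c[perms] * ry_c).sum(axis=1) / denom
        return int((np.abs(rhos) >= target).sum())

    for perm in itertools.permutations(range(n)):
        chunk.append(perm)
        if len(chunk) == 100_000:
            count += flush(chunk)
            chunk = []
    if chunk:
        count += flush(chunk)
    return rho, count / total
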