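"""Quantitative bipartite plant-pollinator networks: data model, I/O, metrics.

The central object is :class:`InteractionNetwork`, a weighted bipartite
visitation matrix (rows = plants, columns = pollinators, weights in
visits per flower per hour) with optional pollinator functional-group
("guild") labels.  :class:`CascadeState` tracks which species are still
extant during an extinction cascade; extinct species are masked, never
rewired, and relative dependences are recomputed from the masked matrix
after every extinction event.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConvergenceError, FormatError, NetworkValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "CascadeState",
    "read_network",
    "read_adjacency",
    "write_network",
    "relative_dependence",
    "degree",
    "interaction_evenness",
    "eigenvector_centrality",
    "species_strength",
    "connectance",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """A weighted bipartite visitation network.

    Parameters
    ----------
    plant_ids :
        Ordered plant labels (rows of ``visits``).
    pollinator_ids :
        Ordered pollinator labels (columns of ``visits``).
    visits :
        Non-negative matrix of interaction strengths, shape
        ``(n_plants, n_pollinators)``, in visits per flower per hour.
    guild :
        Optional map pollinator id -> functional-group label.

    Every plant row and pollinator column must contain at least one
    positive entry, and the two label sets must be disjoint and
    duplicate-free.
    """

    plant_ids: tuple[str, ...]
    pollinator_ids: tuple[str, ...]
    visits: np.ndarray
    guild: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "plant_ids", tuple(str(p) for p in self.plant_ids))
        object.__setattr__(
            self, "pollinator_ids", tuple(str(a) for a in self.pollinator_ids)
        )
        visits = np.asarray(self.visits, dtype=float)
        object.__setattr__(self, "visits", visits)
        self._validate()
        visits.setflags(write=False)

    def _validate(self) -> None:
        n_a, n_p = len(self.plant_ids), len(self.pollinator_ids)
        if self.visits.shape != (n_a, n_p):
            raise NetworkValidationError(
                f"visits shape {self.visits.shape} does not match "
                f"{n_a} plants x {n_p} pollinators"
            )
        if len(set(self.plant_ids)) != n_a:
            raise NetworkValidationError("duplicate plant labels")
        if len(set(self.pollinator_ids)) != n_p:
            raise NetworkValidationError("duplicate pollinator labels")
        overlap = set(self.plant_ids) & set(self.pollinator_ids)
        if overlap:
            raise NetworkValidationError(
                f"plant and pollinator label sets overlap: {sorted(overlap)}"
            )
        if not np.all(np.isfinite(self.visits)):
            raise NetworkValidationError("non-finite interaction weight")
        if np.any(self.visits < 0):
            i, j = np.argwhere(self.visits < 0)[0]
            raise NetworkValidationError(
                f"negative weight for ({self.plant_ids[i]}, {self.pollinator_ids[j]})"
            )
        row_ok = (self.visits > 0).any(axis=1)
        if not row_ok.all():
            bad = self.plant_ids[int(np.argmin(row_ok))]
            raise NetworkValidationError(f"plant {bad!r} has no positive interaction")
        col_ok = (self.visits > 0).any(axis=0)
        if not col_ok.all():
            bad = self.pollinator_ids[int(np.argmin(col_ok))]
            raise NetworkValidationError(
                f"pollinator {bad!r} has no positive interaction"
            )
        unknown = set(self.guild) - set(self.pollinator_ids)
        if unknown:
            raise NetworkValidationError(
                f"guild labels for unknown pollinators: {sorted(unknown)}"
            )

    # -- convenience ---------------------------------------------------

    @property
    def n_plants(self) -> int:
        return len(self.plant_ids)

    @property
    def n_pollinators(self) -> int:
        return len(self.pollinator_ids)

    def plant_index(self, plant: str) -> int:
        try:
            return self.plant_ids.index(plant)
        except ValueError:
            raise KeyError(f"unknown plant {plant!r}") from None

    def pollinator_index(self, pollinator: str) -> int:
        try:
            return self.pollinator_ids.index(pollinator)
        except ValueError:
            raise KeyError(f"unknown pollinator {pollinator!r}") from None

    def pollinator_degrees(self) -> np.ndarray:
        """Number of plant partners per pollinator (initial network)."""
        return (self.visits > 0).sum(axis=0)

    def plant_degrees(self) -> np.ndarray:
        """Number of pollinator partners per plant (initial network)."""
        return (self.visits > 0).sum(axis=1)


@dataclass
class CascadeState:
    """Extant species sets during one extinction-cascade replicate.

    The originating network is referenced, never copied: extinct species
    are represented by membership in the extant sets and their weights
    are treated as masked.  Extant sets only ever shrink.
    """

    network: InteractionNetwork
    extant_plants: set[str]
    extant_pollinators: set[str]

    @classmethod
    def initial(cls, network: InteractionNetwork) -> "CascadeState":
        return cls(
            network=network,
            extant_plants=set(network.plant_ids),
            extant_pollinators=set(network.pollinator_ids),
        )

    def pollinator_mask(self) -> np.ndarray:
        return np.array(
            [a in self.extant_pollinators for a in self.network.pollinator_ids]
        )

    def plant_mask(self) -> np.ndarray:
        return np.array([p in self.extant_plants for p in self.network.plant_ids])


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

_REQUIRED_COLS = ("plant", "pollinator", "weight")


def read_network(path, *, sep: str = ",") -> InteractionNetwork:
    """Read an edge-list table (plant,pollinator,weight[,guild]).

    Species order is first-appearance order; duplicate (plant, pollinator)
    rows sum their weights.  Negative weights and species left with no
    positive interaction are rejected.
    """
    df = pd.read_csv(path, sep=sep, dtype={0: str, 1: str},
                     float_precision="round_trip")
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"edge list missing column(s): {missing}")
    weights = pd.to_numeric(df["weight"], errors="coerce")
    if weights.isna().any():
        row = int(weights.index[weights.isna()][0])
        raise FormatError(f"non-numeric weight in row {row}: {df['weight'][row]!r}")
    if (weights < 0).any():
        row = int(weights.index[weights < 0][0])
        raise NetworkValidationError(
            f"negative weight in row {row}: "
            f"({df['plant'][row]}, {df['pollinator'][row]}, {weights[row]})"
        )
    plants = list(dict.fromkeys(df["plant"].astype(str)))
    pollinators = list(dict.fromkeys(df["pollinator"].astype(str)))
    visits = np.zeros((len(plants), len(pollinators)))
    p_idx = {p: i for i, p in enumerate(plants)}
    a_idx = {a: j for j, a in enumerate(pollinators)}
    for plant, pol, w in zip(df["plant"].astype(str), df["pollinator"].astype(str), weights):
        visits[p_idx[plant], a_idx[pol]] += w
    guild: dict[str, str] = {}
    if "guild" in df.columns:
        for pol, g in zip(df["pollinator"].astype(str), df["guild"]):
            if isinstance(g, str) and g:
                guild[pol] = g
    return InteractionNetwork(tuple(plants), tuple(pollinators), visits, guild)


def read_adjacency(path, *, sep: str = ",") -> InteractionNetwork:
    """Convenience reader for an adjacency-matrix CSV.

    Rows are plants (first column holds plant ids), columns pollinators
    (header row holds pollinator ids).  No guild information.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    visits = df.to_numpy(dtype=float)
    return InteractionNetwork(
        tuple(str(p) for p in df.index),
        tuple(str(a) for a in df.columns),
        visits,
    )


def write_network(network: InteractionNetwork, path, *, sep: str = ",") -> None:
    """Write the canonical edge-list CSV (positive edges only).

    Weights are written with ``repr`` round-trip precision so that
    read -> write -> read reproduces the matrix bit-exactly.
    """
    rows = []
    for i, plant in enumerate(network.plant_ids):
        for j, pol in enumerate(network.pollinator_ids):
            w = network.visits[i, j]
            if w > 0:
                rows.append(
                    {
                        "plant": plant,
                        "pollinator": pol,
                        "weight": repr(float(w)),
                        "guild": network.guild.get(pol, ""),
                    }
                )
    pd.DataFrame(rows, columns=["plant", "pollinator", "weight", "guild"]).to_csv(
        path, sep=sep, index=False
    )


# ----------------------------------------------------------------------
# Metrics
# ----------------------------------------------------------------------


def relative_dependence(state: CascadeState, plant: str) -> dict[str, float]:
    """Relative dependence d_ij of ``plant`` on each extant partner.

    d_ij is the fraction of the plant's visitation delivered by pollinator
    j among currently surviving partners (including j itself); values sum
    to one.  Recomputed from the masked matrix on every call, so partner
    losses redistribute dependence onto the survivors.
    """
    net = state.network
    if plant not in state.extant_plants:
        raise NetworkValidationError(f"plant {plant!r} is not extant")
    i = net.plant_index(plant)
    mask = state.pollinator_mask()
    row = np.where(mask, net.visits[i], 0.0)
    total = row.sum()
    if total <= 0:
        raise NetworkValidationError(f"plant {plant!r} has no extant partners")
    return {
        net.pollinator_ids[j]: row[j] / total
        for j in np.flatnonzero(row > 0)
    }


def _locate(network: InteractionNetwork, species: str) -> tuple[str, int]:
    if species in network.plant_ids:
        return "plant", network.plant_index(species)
    if species in network.pollinator_ids:
        return "pollinator", network.pollinator_index(species)
    raise KeyError(f"unknown species {species!r}")


def degree(network: InteractionNetwork, species: str, *, normalised: bool = False):
    """Partner count of a species; optionally divided by the opposite-set size."""
    side, idx = _locate(network, species)
    if side == "plant":
        k = int((network.visits[idx] > 0).sum())
        denom = network.n_pollinators
    else:
        k = int((network.visits[:, idx] > 0).sum())
        denom = network.n_plants
    return k / denom if normalised else k


def interaction_evenness(network: InteractionNetwork, species: str) -> float:
    """Normalised Shannon evenness of a species' interaction strengths.

    E = -sum p_j ln p_j / ln k over the k positive-weight partners; a
    single-partner species is trivially even (E = 1).
    """
    side, idx = _locate(network, species)
    w = network.visits[idx] if side == "plant" else network.visits[:, idx]
    w = w[w > 0]
    if w.size == 1:
        return 1.0
    p = w / w.sum()
    return float(-(p * np.log(p)).sum() / np.log(w.size))


def eigenvector_centrality(
    network: InteractionNetwork,
    *,
    weighted: bool = True,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Leading-eigenvector scores of the symmetric bipartite adjacency.

    The (n_plants + n_pollinators)-square symmetric form is used, with
    visitation weights by default (``weighted=False`` uses the binary
    adjacency).  Scores are non-negative and normalised to unit Euclidean
    norm.  On a disconnected network the scores are computed on the
    largest component; species outside it score 0 (with a warning).

    Power iteration is run on the diagonally shifted matrix A + sI
    (s = 1 + max row sum): a bipartite adjacency has a symmetric spectrum
    whose +/- lambda_max pair defeats unshifted iteration, while the shift
    leaves the leading eigenvector unchanged.
    """
    n_a, n_p = network.n_plants, network.n_pollinators
    n = n_a + n_p
    w = network.visits if weighted else (network.visits > 0).astype(float)
    adj = np.zeros((n, n))
    adj[:n_a, n_a:] = w
    adj[n_a:, :n_a] = w.T
    n_comp, labels = connected_components(csr_matrix(adj > 0), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        keep = labels == int(np.argmax(sizes))
        warnings.warn(
            f"network has {n_comp} components; centrality computed on the "
            f"largest ({int(keep.sum())} species), others score 0",
            stacklevel=2,
        )
        logger.warning("eigenvector centrality on disconnected network")
    else:
        keep = np.ones(n, dtype=bool)
    sub = adj[np.ix_(keep, keep)]
    shift = 1.0 + sub.sum(axis=1).max()
    x = np.full(sub.shape[0], 1.0 / np.sqrt(sub.shape[0]))
    for it in range(max_iter):
        y = sub @ x + shift * x
        y /= np.linalg.norm(y)
        if np.linalg.norm(y - x) < tol:
            x = y
            break
        x = y
    else:
        raise ConvergenceError(
            f"power iteration did not converge in {max_iter} iterations "
            f"(last delta {np.linalg.norm(y - x):.3e}, n={sub.shape[0]})"
        )
    scores = np.zeros(n)
    scores[keep] = np.abs(x)
    scores /= np.linalg.norm(scores)
    labels_all = list(network.plant_ids) + list(network.pollinator_ids)
    return dict(zip(labels_all, scores.tolist()))


def species_strength(network: InteractionNetwork, pollinator: str) -> float:
    """Sum over plants of their relative dependence on this pollinator.

    Computed on the full initial network; strengths over all pollinators
    sum to the number of plants.
    """
    j = network.pollinator_index(pollinator)
    row_sums = network.visits.sum(axis=1)
    return float((network.visits[:, j] / row_sums).sum())


def connectance(network: InteractionNetwork) -> float:
    """Fraction of realised links."""
    return float((network.visits > 0).mean())
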