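"""Intrinsic plant dependence on insect pollination (IPD).

IPD is the fraction of a plant's seed set attributable to pollinator
visits, estimated from paired pollination treatments:

    IPD = (SS_op - SS_pe) / SS_op = 1 - SS_pe / SS_op

where SS_op is mean seed set per marked flower unit under open
pollination and SS_pe under pollinator exclusion.  IPD = 0 means the
plant reproduces autonomously (selfing and/or wind); IPD = 1 means it
fully relies on animal pollination.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DependenceError, FormatError
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "SeedSetRecord",
    "compute_ipd",
    "community_ipd_summary",
    "read_ipd",
    "write_ipd",
    "dependence_array",
]

#: A dependence vector is a plain mapping plant id -> IPD in [0, 1].
DependenceVector = dict[str, float]


@dataclass(frozen=True)
class SeedSetRecord:
    """Species-level seed-set means for the two pollination treatments."""

    plant: str
    ss_op: float  # open pollination
    ss_pe: float  # pollinator exclusion


def compute_ipd(ss_op: float, ss_pe: float, *, clamp: bool = True) -> float:
    """IPD = 1 - ss_pe/ss_op, clamped to [0, 1] by default.

    Sampling noise can make the exclusion treatment out-yield open
    pollination; the resulting negative raw value is clamped to 0 (and
    logged) unless ``clamp=False``.
    """
    if not math.isfinite(ss_op) or not math.isfinite(ss_pe):
        raise DependenceError("seed-set values must be finite")
    if ss_pe < 0:
        raise DependenceError(f"negative exclusion seed set: {ss_pe}")
    if ss_op <= 0:
        raise DependenceError(
            "IPD undefined: no seed set under open pollination (ss_op <= 0)"
        )
    raw = 1.0 - ss_pe / ss_op
    if raw < 0 and clamp:
        logger.info("clamping negative IPD %.4f to 0", raw)
        return 0.0
    return raw


def community_ipd_summary(dep: DependenceVector) -> tuple[float, float, int]:
    """(mean, sample SD, n) of a community's IPD values.

    SD uses the n-1 denominator (NaN for a single species).
    """
    if not dep:
        raise DependenceError("empty dependence vector")
    values = np.array(list(dep.values()), dtype=float)
    n = values.size
    sd = float(values.std(ddof=1)) if n > 1 else float("nan")
    return float(values.mean()), sd, n


def read_ipd(path, *, sep: str = ",", clamp: bool = True) -> DependenceVector:
    """Read a per-plant dependence table.

    Two dialects, auto-detected by header:

    * ``plant,ipd`` — direct IPD values;
    * ``plant,ss_op,ss_pe`` — treatment means, converted via
      :func:`compute_ipd`.
    """
    df = pd.read_csv(path, sep=sep, dtype={"plant": str},
                     float_precision="round_trip")
    cols = set(df.columns)
    if "plant" not in cols:
        raise FormatError("IPD table missing 'plant' column")
    if "ipd" in cols:
        values = pd.to_numeric(df["ipd"], errors="coerce")
        if values.isna().any() or (values < 0).any() or (values > 1).any():
            raise DependenceError("ipd column must be numeric in [0, 1]")
        dep = dict(zip(df["plant"], values.astype(float)))
    elif {"ss_op", "ss_pe"} <= cols:
        dep = {
            plant: compute_ipd(float(op), float(pe), clamp=clamp)
            for plant, op, pe in zip(df["plant"], df["ss_op"], df["ss_pe"])
        }
    else:
        raise FormatError(
            "IPD table needs either an 'ipd' column or 'ss_op'/'ss_pe' columns"
        )
    if len(dep) != len(df):
        raise FormatError("duplicate plant ids in IPD table")
    return dep


def write_ipd(dep: DependenceVector, path, *, sep: str = ",") -> None:
    pd.DataFrame(
        {"plant": list(dep.keys()), "ipd": [repr(float(v)) for v in dep.values()]}
    ).to_csv(path, sep=sep, index=False)


def dependence_array(network: InteractionNetwork, dep: DependenceVector) -> np.ndarray:
    """IPD values aligned with the network's plant order; validates coverage."""
    missing = [p for p in network.plant_ids if p not in dep]
    if missing:
        raise DependenceError(f"dependence vector missing plants: {missing}")
    values = np.array([float(dep[p]) for p in network.plant_ids])
    if np.any((values < 0) | (values > 1)) or not np.all(np.isfinite(values)):
        raise DependenceError("IPD values must lie in [0, 1]")
    return values
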