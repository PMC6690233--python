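"""Quartet sequence-evolution simulation under JC69 and site-pattern sweeps.

Simulation samples each site independently: a uniform root state, an
optional gamma-distributed rate multiplier, and direct transition-probability
sampling along each branch (exact under JC69 — no event-level simulation is
needed). On a star tree the root is the central node; on a resolved tree it
is the internal node adjacent to the first pair (JC69 is reversible, so root
placement does not matter).

Replicate i of a seeded run uses its own generator seeded with seed + i, so
individual replicates are reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fit import Bounds
from .inference import star_vs_resolved_lrt
from .jc69 import NUCLEOTIDES, RateModel
from .likelihood import PAIRINGS, QuartetTree
from .patterns import (
    GROUP_SIZES,
    GROUP_SLICES,
    Alignment,
    PatternCounts,
    counts_from_alignment,
    counts_from_spec,
)

__all__ = ["SimConfig", "simulate_alignment", "simulate_counts",
           "symmetrize_truncating", "adjust_spec_n4", "sweep_n4_n3"]


@dataclass(frozen=True)
class SimConfig:
    """One simulation design: tree, rate model, length, replicates, seed."""

    tree: QuartetTree
    model: RateModel
    length: int
    replicates: int = 1
    seed: int = 0
    symmetrize: bool = False

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _evolve(states: np.ndarray, d: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Evolve site states over per-site branch lengths ``d`` under JC69.

    A site changes with probability 3/4 (1 - exp(-4d/3)) and lands uniformly
    on one of the other three nucleotides.
    """
    p_same = 0.25 + 0.75 * np.exp(-4.0 * d / 3.0)
    change = rng.random(states.shape) >= p_same
    offset = rng.integers(1, 4, size=states.shape)
    return np.where(change, (states + offset) % 4, states)


def simulate_alignment(config: SimConfig, replicate: int = 0) -> Alignment:
    """Simulate one replicate alignment (names S1..S4)."""
    if not 0 <= replicate < config.replicates:
        raise ValueError(f"replicate must be in [0, {config.replicates})")
    rng = np.random.default_rng(config.seed + replicate)
    L = config.length
    tree = config.tree
    if config.model.kind == "gamma":
        a = config.model.alpha
        rates = rng.gamma(shape=a, scale=1.0 / a, size=L)
    else:
        rates = np.ones(L)
    root = rng.integers(0, 4, size=L)
    tips = [None] * 4
    if tree.is_star:
        for k in range(4):
            tips[k] = _evolve(root, rates * tree.b[k], rng)
    else:
        (i, j), (k, l) = PAIRINGS[tree.topology]
        tips[i] = _evolve(root, rates * tree.b[i], rng)
        tips[j] = _evolve(root, rates * tree.b[j], rng)
        other = _evolve(root, rates * tree.b5, rng)
        tips[k] = _evolve(other, rates * tree.b[k], rng)
        tips[l] = _evolve(other, rates * tree.b[l], rng)
    seqs = tuple("".join(NUCLEOTIDES[s] for s in t) for t in tips)
    return Alignment(("S1", "S2", "S3", "S4"), seqs)


def symmetrize_truncating(counts: PatternCounts) -> PatternCounts:
    """Equalize counts within G2/G3/G4, truncating indivisible remainders.

    Simulated counts rarely divide evenly within groups; each group total is
    reduced to the nearest multiple of the group size (dropping at most
    5 + 3 + 2 sites in total) before exact equal redistribution. Use
    patterns.symmetrize for the strict, error-on-remainder variant.
    """
    out = counts.counts.copy()
    for g in ("G2", "G3", "G4"):
        sl = GROUP_SLICES[g]
        size = GROUP_SIZES[g]
        out[sl] = int(out[sl].sum()) // size
    return PatternCounts(out)


def simulate_counts(config: SimConfig) -> list[PatternCounts]:
    """Pattern counts for every replicate (symmetrized if configured)."""
    result = []
    for rep in range(config.replicates):
        counts = counts_from_alignment(simulate_alignment(config, rep))
        if config.symmetrize:
            counts = symmetrize_truncating(counts)
        result.append(counts)
    return result


def adjust_spec_n4(base_spec, delta: int) -> tuple[int, int, int, int, int]:
    """Shift n4 by ``delta`` while preserving total alignment length.

    The 3*delta sites gained or lost through G4 are absorbed by n1, n2 and
    n5 via proportional rebalancing (weights = current site contributions,
    n2 counting 6 sites per unit), rounded to integers exactly. Raises when
    no non-negative adjustment exists.
    """
    n1, n2, n3, n4, n5 = (int(v) for v in base_spec)
    if n4 + delta < 0:
        raise ValueError(f"delta {delta} drives n4 below zero")
    budget = 3 * delta  # sites to remove from the n1/n2/n5 pool
    pool = n1 + 6 * n2 + n5
    if budget > pool:
        raise ValueError(
            f"cannot absorb {budget} sites: only {pool} available in n1/n2/n5"
        )
    if pool == 0:
        if budget < 0:
            # grow n5 (single-site weight) to absorb removed G4 sites
            return (n1, n2, n3, n4 + delta, n5 - budget)
        return (n1, n2, n3, n4 + delta, n5)
    dn2 = round(budget * (6 * n2 / pool) / 6)
    dn2 = min(dn2, n2) if budget > 0 else max(dn2, -10**9)
    rem = budget - 6 * dn2
    if n1 + n5 > 0:
        dn1 = round(rem * n1 / (n1 + n5))
    else:
        dn1 = 0
    dn5 = rem - dn1
    new = (n1 - dn1, n2 - dn2, n3, n4 + delta, n5 - dn5)
    if any(v < 0 for v in new):
        raise ValueError(f"adjusted spec {new} has negative counts")
    assert sum(v * w for v, w in zip(new, (1, 6, 4, 3, 1))) == \
        sum(v * w for v, w in zip((n1, n2, n3, n4, n5), (1, 6, 4, 3, 1)))
    return new


def sweep_n4_n3(base_spec, deltas, bounds: Bounds = Bounds(), models=("constant",),
                adjust=adjust_spec_n4, n_restarts: int | None = None) -> pd.DataFrame:
    """Star-vs-resolved LRT statistic as a function of the G4/G3 imbalance.

    For each delta, n4 is shifted by ``adjust`` (length-preserving by
    default) and the LRT is run under each requested rate model. Returns a
    tidy table with one row per (delta, model): n-values, n4 - n3, 2*dlnL
    and the chi2_1 p-value — the raw material for the bias-vs-(n4-n3) plot.
    """
    rows = []
    for delta in deltas:
        spec = adjust(base_spec, int(delta))
        counts = counts_from_spec(*spec)
        for model in models:
            res = star_vs_resolved_lrt(counts, model, bounds, n_restarts=n_restarts)
            rows.append({
                "n1": spec[0], "n2": spec[1], "n3": spec[2], "n4": spec[3],
                "n5": spec[4], "n4_minus_n3": spec[3] - spec[2],
                "model": model if isinstance(model, str) else model.kind,
                "lnL_star": res.lnL_star, "lnL_resolved": res.lnL_resolved,
                "stat": res.stat, "p_value": res.p_value,
            })
    return pd.DataFrame(rows)
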