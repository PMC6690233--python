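"""Bounded maximum-likelihood fitting of quartet branch lengths (and alpha).

Branch lengths are optimised within [b_min, b_max] and the gamma shape on a
log scale within [alpha_min, alpha_max] using L-BFGS-B from a fixed,
deterministic grid of three restarts: a distance-based guess (b_i = d/2
from the mean pairwise JC69 distance), 0.1 b_max and 0.9 b_max, with the
gamma shape always started at 1. The best restart wins. Equidistant
datasets make the likelihood surface permutation-symmetric, with ridges
and multiple equivalent optima; maximised lnL (not individual branch
values) is the quantity of record on such surfaces.

Resolved-topology fits precede L-BFGS-B with a short pass of sequential
one-dimensional (coordinate-wise) optimisation. Sequential edge updates —
the strategy practical tree programs use — break the permutation symmetry
of equidistant data, without which gradient steps stay trapped on the
symmetric manifold and miss the asymmetric ridge optima characteristic of
the resolved surface. Star fits use plain gradient steps from the
symmetric start grid: the star tree of an equidistant dataset is
exchangeable in its four branches and the symmetric solution is the
standard reference answer (see the methods note for the pathological
counter-cases).

Hitting a bound is reported, not hidden: alpha_hat at alpha_max means "no
detectable rate heterogeneity"; branches at b_max indicate saturation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .jc69 import RateModel, jc69_distance
from .likelihood import PAIRINGS, QuartetTree, class_site_probs, gamma_class_probs
from .patterns import PatternCounts

__all__ = ["Bounds", "FitResult", "TopologyFits", "fit_tree", "profile_b5",
           "fit_all_topologies"]

# convergence targets for each L-BFGS-B restart
_FTOL = 1e-12   # relative lnL change
_GTOL = 1e-8
_MAXITER = 2000

@dataclass(frozen=True)
class Bounds:
    """Box bounds for branch lengths and the gamma shape parameter."""

    b_min: float = 0.0
    b_max: float = 10.0
    alpha_min: float = 1e-3
    alpha_max: float = 10000.0

    def __post_init__(self) -> None:
        if not 0 <= self.b_min < self.b_max:
            raise ValueError("require 0 <= b_min < b_max")
        if not 0 < self.alpha_min < self.alpha_max:
            raise ValueError("require 0 < alpha_min < alpha_max")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one bounded ML fit."""

    tree: QuartetTree
    model: RateModel            # fitted model (gamma carries alpha_hat)
    lnL: float
    alpha_hat: float | None = None
    bound_hits: tuple[str, ...] = ()
    converged: bool = True
    n_restarts_used: int = 0
    bounds: Bounds = field(default_factory=Bounds)
    b5_fixed: bool = False

    def to_dict(self) -> dict:
        return {
            "topology": self.tree.topology,
            "b": list(self.tree.b),
            "b5": None if self.tree.is_star else self.tree.b5,
            "alpha_hat": self.alpha_hat,
            "lnL": self.lnL,
            "bound_hits": list(self.bound_hits),
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
        }


def _model_kind(model) -> str:
    if isinstance(model, RateModel):
        return model.kind
    if model in ("constant", "gamma"):
        return model
    raise ValueError(f"model must be 'constant', 'gamma' or a RateModel, got {model!r}")


def _mean_p_distance(counts: PatternCounts) -> float:
    """Mean pairwise difference proportion implied by the pattern counts.

    Each class's column contributes a fixed number of differing pairs among
    the 6 OTU pairs: 6 (G1), 5 (G2), 3 (G3), 4 (G4), 0 (G5).
    """
    w = np.array([6] + [5] * 6 + [3] * 4 + [4] * 3 + [0])
    return float(np.dot(counts.counts, w)) / (6.0 * counts.length)


def _start_grid(counts: PatternCounts, n_branch: int, bounds: Bounds,
                gamma: bool) -> list[np.ndarray]:
    p = min(_mean_p_distance(counts), 0.7499)
    d = jc69_distance(p)
    b_hat = float(np.clip(d / 2.0, max(bounds.b_min, 1e-3), bounds.b_max))
    starts = []
    for base in (b_hat, 0.1 * bounds.b_max, 0.9 * bounds.b_max):
        x = np.full(n_branch, base)
        if gamma:
            x = np.append(x, 0.0)  # log alpha = 0 -> alpha = 1
        starts.append(x)
    return starts


def _make_tree(topology: str, branches: np.ndarray, b5: float) -> QuartetTree:
    if topology == "star":
        return QuartetTree("star", tuple(branches[:4]))
    return QuartetTree(topology, tuple(branches[:4]), b5)


def fit_tree(counts: PatternCounts, topology: str, model, bounds: Bounds = Bounds(),
             b5_fixed: float | None = None, n_restarts: int | None = None) -> FitResult:
    """Maximise lnL over branch lengths (and alpha) for one topology.

    For the star tree the four terminal branches are free and b5 is
    structurally 0; for a resolved topology b5 is a fifth free parameter
    unless ``b5_fixed`` pins it (profile likelihood). Under the gamma model
    the shape alpha is optimised on a log scale. Deterministic given inputs.
    """
    if counts.length == 0:
        raise ValueError("counts are empty")
    kind = _model_kind(model)
    gamma = kind == "gamma"
    is_star = topology == "star"
    if is_star and b5_fixed is not None:
        raise ValueError("star tree has no internal branch to fix")
    if not is_star and topology not in PAIRINGS:
        raise ValueError(f"unknown topology {topology!r}")
    if b5_fixed is not None and b5_fixed < 0:
        raise ValueError("fixed b5 must be >= 0")
    b5_free = (not is_star) and b5_fixed is None
    n_branch = 5 if b5_free else 4

    box = [(bounds.b_min, bounds.b_max)] * n_branch
    if gamma:
        box.append((np.log(bounds.alpha_min), np.log(bounds.alpha_max)))

    c = counts.counts
    pos = c > 0
    n_sites = counts.length

    # the objective is the per-site mean negative log-likelihood: gradients
    # of order 1 keep L-BFGS-B's first (unit-Hessian) step from overshooting
    # straight onto the b_max corner, where the projected gradient vanishes
    def negloglik(x: np.ndarray) -> float:
        branches = x[:n_branch]
        b5 = branches[4] if b5_free else (b5_fixed if b5_fixed is not None else 0.0)
        tree = _make_tree(topology, branches, float(b5))
        if gamma:
            probs = gamma_class_probs(tree, float(np.exp(x[-1])))
        else:
            probs = class_site_probs(tree, 1.0)
        # floor keeps the objective finite and steep where a class probability
        # vanishes (e.g. variable patterns at all-zero branch lengths), so the
        # line search can back off instead of stalling on a flat penalty
        return -float(np.dot(c[pos], np.log(np.maximum(probs[pos], 1e-310)))) / n_sites

    def coordinate_pass(x0: np.ndarray, rounds: int = 2) -> np.ndarray:
        # sequential 1-D bounded optimisation of each parameter in turn;
        # breaks the permutation symmetry of equidistant data the way
        # edge-by-edge tree optimisers do
        x = np.array(x0, dtype=float)
        for _ in range(rounds):
            for i in range(len(x)):
                def f1(v: float) -> float:
                    y = x.copy()
                    y[i] = v
                    return negloglik(y)
                r = optimize.minimize_scalar(
                    f1, bounds=box[i], method="bounded",
                    options={"xatol": 1e-8},
                )
                x[i] = r.x
        return x

    starts = _start_grid(counts, n_branch, bounds, gamma)
    if n_restarts is not None:
        starts = starts[: max(1, n_restarts)]
    best = None
    any_ok = False
    for x0 in starts:
        # b5 fixed at exactly 0 is structurally a star: use the star path so
        # the star <-> resolved-at-zero identity holds for fitted results too
        if not is_star and b5_fixed != 0.0:
            x0 = coordinate_pass(x0)
        # gamma objectives carry quadrature noise of order n_sites * rtol;
        # the finite-difference step must sit well above it for usable
        # gradients (the scipy default, ~1.5e-8, does not)
        opts = {"ftol": _FTOL, "gtol": _GTOL, "maxiter": _MAXITER}
        if gamma:
            opts["eps"] = 1e-6
        res = optimize.minimize(
            negloglik, x0, method="L-BFGS-B", bounds=box, options=opts,
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    if not np.isfinite(best.fun):
        raise RuntimeError("optimizer failed: objective non-finite at every restart")

    x = best.x
    branches = np.asarray(x[:n_branch], dtype=float)
    b5 = float(branches[4]) if b5_free else float(b5_fixed or 0.0)
    tree = _make_tree(topology, branches, b5)
    alpha_hat = float(np.exp(x[-1])) if gamma else None
    fitted_model = RateModel.gamma(alpha_hat) if gamma else RateModel.constant()

    hits = []
    names = ["b1", "b2", "b3", "b4"] + (["b5"] if b5_free else [])
    span = bounds.b_max - bounds.b_min
    for name, val in zip(names, branches):
        if val <= bounds.b_min + 1e-5 * span:
            hits.append(f"{name}=b_min")
        elif val >= bounds.b_max - 1e-4 * span:
            # the surface flattens toward saturation, so the optimiser can
            # legitimately stop a hair short of the cap
            hits.append(f"{name}=b_max")
    if gamma:
        if alpha_hat <= bounds.alpha_min * (1 + 1e-4):
            hits.append("alpha=alpha_min")
        elif alpha_hat >= bounds.alpha_max * (1 - 1e-4):
            hits.append("alpha=alpha_max")

    return FitResult(
        tree=tree, model=fitted_model, lnL=-float(best.fun) * n_sites, alpha_hat=alpha_hat,
        bound_hits=tuple(hits), converged=bool(any_ok),
        n_restarts_used=len(starts), bounds=bounds,
        b5_fixed=b5_fixed is not None,
    )


def profile_b5(counts: PatternCounts, topology: str, model, b5_values,
               bounds: Bounds = Bounds()) -> list[FitResult]:
    """Profile fits over a list of fixed internal branch lengths.

    For each b5 value, maximises over b1..b4 (and alpha under the gamma
    model) with b5 held fixed; results are returned in input order.
    """
    if topology not in PAIRINGS:
        raise ValueError("profile_b5 requires a resolved topology")
    return [
        fit_tree(counts, topology, model, bounds, b5_fixed=float(v))
        for v in b5_values
    ]


@dataclass(frozen=True)
class TopologyFits:
    """Star fit plus resolved fits across all three pairings."""

    star: FitResult
    resolved: FitResult  # best of the three (ties broken in fixed order)
    all_resolved: tuple[FitResult, FitResult, FitResult]


def fit_all_topologies(counts: PatternCounts, model, bounds: Bounds = Bounds(),
                       n_restarts: int | None = None) -> TopologyFits:
    """Fit the star tree and all three resolved pairings.

    The best resolved fit is selected by lnL, ties broken by the fixed order
    T12|34, T13|24, T14|23.
    """
    star = fit_tree(counts, "star", model, bounds, n_restarts=n_restarts)
    resolved = tuple(
        fit_tree(counts, topo, model, bounds, n_restarts=n_restarts)
        for topo in PAIRINGS
    )
    top = max(f.lnL for f in resolved)
    # numerically tied fits (within optimizer tolerance) resolve to the
    # first topology in the fixed order
    best = next(f for f in resolved if f.lnL >= top - 1e-6)
    return TopologyFits(star=star, resolved=best, all_resolved=resolved)
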