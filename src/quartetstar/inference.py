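"""Star-vs-resolved likelihood-ratio test and site-pattern goodness of fit.

The star tree is nested in every resolved quartet (b5 = 0), so twice the lnL
gap, 2*(lnL_resolved - lnL_star), is referred to a chi-square distribution
with 1 degree of freedom. Because b5 sits on the boundary of its parameter
space under the null, the textbook reference is a 50:50 mixture of chi2_0
and chi2_1; the plain chi2_1 test is the default and the mixture is opt-in.

The goodness-of-fit check asks a different question: does ANY single
tree+model explain the observed site-pattern counts? Observed class counts
are compared with their expectation under the fitted tree and model via the
G statistic, calibrated by parametric bootstrap (multinomial resampling
from the fitted expectation, refitting each replicate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fit import Bounds, FitResult, fit_all_topologies, fit_tree
from .likelihood import expected_class_probs
from .patterns import PatternCounts

__all__ = ["LrtResult", "GofResult", "chi2_upper_tail", "star_vs_resolved_lrt",
           "g_statistic", "pattern_gof"]


def chi2_upper_tail(stat: float, df: int = 1) -> float:
    """Upper-tail chi-square probability P(X >= stat)."""
    if stat < 0:
        raise ValueError("chi-square statistic must be >= 0")
    return float(stats.chi2.sf(stat, df))


@dataclass(frozen=True)
class LrtResult:
    """Star-vs-resolved likelihood-ratio test."""

    lnL_star: float
    lnL_resolved: float
    stat: float          # 2 * (lnL_resolved - lnL_star), clamped at 0
    df: int
    p_value: float
    star_fit: FitResult
    resolved_fit: FitResult
    boundary_mix: bool = False

    def to_dict(self) -> dict:
        return {
            "lnL_star": self.lnL_star,
            "lnL_resolved": self.lnL_resolved,
            "stat": self.stat,
            "df": self.df,
            "p_value": self.p_value,
            "resolved_topology": self.resolved_fit.tree.topology,
        }


def star_vs_resolved_lrt(counts: PatternCounts, model, bounds: Bounds = Bounds(),
                         boundary_mix: bool = False,
                         n_restarts: int | None = None) -> LrtResult:
    """Likelihood-ratio test of the star tree against the best resolved tree.

    With ``boundary_mix`` the p-value uses the 0.5*chi2_0 + 0.5*chi2_1
    boundary mixture instead of plain chi2_1.
    """
    fits = fit_all_topologies(counts, model, bounds, n_restarts=n_restarts)
    stat = 2.0 * (fits.resolved.lnL - fits.star.lnL)
    if stat < 0:
        if stat < -1e-6:
            raise RuntimeError(
                f"resolved fit below star fit by {-stat / 2:.3g} lnL units: "
                "optimizer failure (star is nested in resolved)"
            )
        stat = 0.0
    if boundary_mix:
        p = 0.5 * chi2_upper_tail(stat, 1) if stat > 0 else 1.0
    else:
        p = chi2_upper_tail(stat, 1)
    return LrtResult(
        lnL_star=fits.star.lnL, lnL_resolved=fits.resolved.lnL,
        stat=stat, df=1, p_value=p,
        star_fit=fits.star, resolved_fit=fits.resolved,
        boundary_mix=boundary_mix,
    )


def g_statistic(observed: np.ndarray, expected: np.ndarray) -> float:
    """G = 2 sum O_c ln(O_c / E_c) over classes with O_c > 0.

    Infinite when some observed class has zero expectation.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    mask = obs > 0
    if np.any(mask & (exp <= 0)):
        return float("inf")
    return float(2.0 * np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))


@dataclass(frozen=True)
class GofResult:
    """Site-pattern goodness of fit of a fitted tree+model."""

    observed: PatternCounts
    expected: np.ndarray     # expected class counts under the fitted model
    stat: float              # G statistic
    p_value: float           # parametric-bootstrap tail probability
    n_boot: int
    p_is_upper_bound: bool = False  # True when stat is infinite (p < 1/n_boot)


def pattern_gof(counts: PatternCounts, fitted: FitResult, n_boot: int = 200,
                seed: int = 0, refit_restarts: int = 2) -> GofResult:
    """Test whether the fitted tree+model reproduces the site-pattern counts.

    Expected counts are length * expected_class_probs(fitted tree, model).
    The null distribution of G is built by drawing ``n_boot`` multinomial
    datasets from the expected class probabilities, refitting the same
    topology/model/bounds to each, and recomputing G; the p-value is the
    fraction of bootstrap G values >= the observed one.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    probs = expected_class_probs(fitted.tree, fitted.model)
    length = counts.length
    expected = length * probs
    g_obs = g_statistic(counts.counts, expected)
    if np.isinf(g_obs):
        return GofResult(counts, expected, g_obs, 1.0 / n_boot, n_boot,
                         p_is_upper_bound=True)

    topology = fitted.tree.topology
    kind = fitted.model.kind
    b5_fixed = fitted.tree.b5 if fitted.b5_fixed else None
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_boot):
        sim = PatternCounts(rng.multinomial(length, probs))
        refit = fit_tree(sim, topology, kind, fitted.bounds,
                         b5_fixed=b5_fixed, n_restarts=refit_restarts)
        sim_expected = length * expected_class_probs(refit.tree, refit.model)
        if g_statistic(sim.counts, sim_expected) >= g_obs:
            exceed += 1
    return GofResult(counts, expected, g_obs, exceed / n_boot, n_boot)
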