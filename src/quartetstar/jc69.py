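"""Jukes-Cantor (JC69) substitution mathematics.

The JC69 model assumes equal equilibrium base frequencies (1/4 each) and a
single substitution rate, so the transition probability between any two
nucleotides depends only on whether they are equal and on the branch length
``d`` measured in expected substitutions per site:

    P(i -> i; d) = 1/4 + (3/4) exp(-4d/3)
    P(i -> j; d) = 1/4 - (1/4) exp(-4d/3),   i != j

Rate heterogeneity across sites is modelled by a mean-1 gamma distribution
with shape ``alpha`` (shape = rate = alpha), whose density is exposed here
for marginalising likelihoods over the site rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "RateModel",
    "transition_prob",
    "transition_matrix",
    "jc69_distance",
    "gamma_density",
    "NUCLEOTIDES",
    "NUC_INDEX",
]

NUCLEOTIDES = "ACGT"
NUC_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}


@dataclass(frozen=True)
class RateModel:
    """Across-site rate model: constant rate or mean-1 gamma with shape alpha.

    The gamma density has shape ``alpha`` and rate ``alpha`` so the mean site
    rate is exactly 1 (variance 1/alpha); small alpha means strong rate
    heterogeneity, large alpha approaches the constant-rate model.
    """

    kind: str  # "constant" | "gamma"
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "gamma"):
            raise ValueError(f"unknown rate model kind: {self.kind!r}")
        if self.kind == "gamma":
            if self.alpha is None or not self.alpha > 0:
                raise ValueError("gamma rate model requires alpha > 0")
        elif self.alpha is not None:
            raise ValueError("constant rate model takes no alpha")

    @classmethod
    def constant(cls) -> "RateModel":
        return cls("constant")

    @classmethod
    def gamma(cls, alpha: float) -> "RateModel":
        return cls("gamma", float(alpha))


def transition_matrix(d: float) -> np.ndarray:
    """4x4 JC69 transition probability matrix for branch length ``d``.

    ``d`` is in expected substitutions per site. Rows and columns are indexed
    A, C, G, T; each row sums to 1.
    """
    if d < 0:
        raise ValueError(f"branch length must be >= 0, got {d}")
    e = np.exp(-4.0 * d / 3.0)
    off = 0.25 - 0.25 * e
    P = np.full((4, 4), off)
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def transition_prob(from_nuc: str, to_nuc: str, d: float) -> float:
    """JC69 transition probability between two nucleotides over length ``d``."""
    if d < 0:
        raise ValueError(f"branch length must be >= 0, got {d}")
    try:
        same = NUC_INDEX[from_nuc] == NUC_INDEX[to_nuc]
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide: {exc.args[0]!r}") from None
    e = np.exp(-4.0 * d / 3.0)
    return 0.25 + 0.75 * e if same else 0.25 - 0.25 * e


def jc69_distance(p: float) -> float:
    """JC69 distance from an observed proportion ``p`` of differing sites.

    Inverts the expected difference proportion p(d) = (3/4)(1 - exp(-4d/3)).
    Raises for ``p >= 3/4`` where the distance is undefined (saturation).
    """
    if not 0 <= p:
        raise ValueError(f"difference proportion must be in [0, 3/4), got {p}")
    if p >= 0.75:
        raise ValueError(
            f"difference proportion {p} >= 3/4: sequences saturated, JC69 distance undefined"
        )
    return -0.75 * np.log1p(-4.0 * p / 3.0)


def gamma_density(r, alpha: float):
    """Density of the mean-1 gamma rate distribution (shape=rate=alpha) at ``r``."""
    if not alpha > 0:
        raise ValueError(f"gamma shape alpha must be > 0, got {alpha}")
    return stats.gamma.pdf(r, a=alpha, scale=1.0 / alpha)
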