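"""Posterior-summary machinery shared by all Bayesian stages.

Highest-density intervals, MCMC convergence diagnostics (rank-normalized
split R-hat and bulk effective sample size) and directional posterior
probabilities.  Draws are arranged as a matrix of shape (chains, draws);
one-dimensional inputs are treated as a single flattened sample where a
chain structure is not required.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

MIN_HDI_SAMPLES = 50


@dataclass(frozen=True)
class Interval:
    """A credible interval with its probability mass."""

    lower: float
    upper: float
    mass: float = 0.95

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise ValueError("interval lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def _as_chain_matrix(d: np.ndarray, min_draws: int = 4) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if d.ndim != 2:
        raise ValueError("draws must be a (chains, draws) matrix")
    if d.shape[0] < 2:
        raise ValueError("at least 2 chains are required")
    if d.shape[1] < min_draws:
        raise ValueError(f"at least {min_draws} draws per chain are required")
    return d


def hdi(samples: np.ndarray, mass: float = 0.95) -> Interval:
    """Shortest contiguous interval containing ``ceil(mass * n)`` samples.

    Ties between equally short windows are broken toward the lowest
    starting index.  Requires at least ``MIN_HDI_SAMPLES`` samples.
    """
    if not 0.0 < mass < 1.0:
        raise ValueError("mass must lie in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float).ravel())
    n = x.size
    if n < MIN_HDI_SAMPLES:
        raise ValueError(f"hdi requires at least {MIN_HDI_SAMPLES} samples, got {n}")
    k = int(np.ceil(mass * n))
    widths = x[k - 1 :] - x[: n - k + 1]
    i = int(np.argmin(widths))  # argmin takes the first minimum: lowest start
    return Interval(float(x[i]), float(x[i + k - 1]), mass)


def rhat(d: np.ndarray) -> float:
    """Rank-normalized split potential scale reduction factor.

    Chains that are identical constants are defined to have R-hat 1
    (zero-variance convention).
    """
    d = _as_chain_matrix(d)
    if np.ptp(d) == 0.0:
        return 1.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # rank normalization can dip a hair below 1 by sampling noise;
        # the statistic is >= 1 by construction, so clamp
        return max(float(az.rhat(d, method="rank")), 1.0)


def ess(d: np.ndarray) -> float:
    """Bulk effective sample size (Geyer initial-monotone truncation).

    Constant chains are degenerate and return 0.
    """
    d = _as_chain_matrix(d)
    if np.ptp(d) == 0.0:
        return 0.0
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(az.ess(d, method="bulk"))


def prob_greater(
    a: np.ndarray, b: np.ndarray | float = 0.0, paired: bool = True
) -> float:
    """Posterior probability P(a > b); exact ties contribute 1/2.

    With vector ``b`` and ``paired=True`` the draws are compared
    position-wise (same MCMC provenance); with ``paired=False`` every
    cross pair is compared (independent posteriors).  Satisfies
    ``prob_greater(a, b) == 1 - prob_greater(b, a)`` exactly.
    """
    a = np.asarray(a, dtype=float).ravel()
    if a.size == 0:
        raise ValueError("empty sample")
    if np.isscalar(b) or np.ndim(b) == 0:
        return float(np.mean((a > b) + 0.5 * (a == b)))
    b = np.asarray(b, dtype=float).ravel()
    if b.size == 0:
        raise ValueError("empty sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison requires equal lengths")
        return float(np.mean((a > b) + 0.5 * (a == b)))
    bs = np.sort(b)
    lo = np.searchsorted(bs, a, side="left")
    hi = np.searchsorted(bs, a, side="right")
    # lo = #(b < a_i), hi - lo = #(b == a_i)
    return float((lo + 0.5 * (hi - lo)).sum() / (a.size * b.size))
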