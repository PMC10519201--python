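"""Directional probabilistic niche overlap between groups.

The overlap of species A onto species B is the probability that a random
individual of A falls inside the α-level probability region of B's niche
distribution — asymmetric by construction.  Niche distributions are
bivariate normal with parameters drawn from each group's posterior; for
each paired posterior draw the probability is estimated by Monte Carlo,
yielding a posterior sample of overlap proportions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .niche_ellipse import NichePosterior, _check_cov


def mahalanobis_sq(x: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Squared Mahalanobis distance of points ``x`` from (μ, Σ)."""
    d = np.atleast_2d(np.asarray(x, dtype=float)) - np.asarray(mu, dtype=float)
    sol = np.linalg.solve(_check_cov(sigma), d.T)
    return np.einsum("ij,ji->i", d, sol)


def in_niche_region(
    x: np.ndarray, mu: np.ndarray, sigma: np.ndarray, conf: float = 0.95
) -> bool | np.ndarray:
    """Whether point(s) fall inside the ``conf``-level normal ellipse.

    Membership is (x−μ)ᵀ Σ⁻¹ (x−μ) ≤ χ²₂(conf).
    """
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    q = stats.chi2.ppf(conf, df=2)
    inside = mahalanobis_sq(x, mu, sigma) <= q
    return bool(inside[0]) if np.ndim(x) == 1 else inside


@dataclass
class OverlapResult:
    """Posterior overlap of group A onto group B's niche region."""

    a_label: str
    b_label: str
    conf: float
    draws: np.ndarray  # (ndraw,) overlap proportions in [0, 1]
    mean_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.mean_pct = float(100.0 * np.mean(self.draws))


def _chol2(sig: np.ndarray) -> np.ndarray:
    """Cholesky factors of a stack of 2×2 SPD matrices, closed form."""
    a = np.sqrt(sig[:, 0, 0])
    b = sig[:, 0, 1] / a
    c = np.sqrt(np.maximum(sig[:, 1, 1] - b * b, 1e-300))
    out = np.zeros_like(sig)
    out[:, 0, 0] = a
    out[:, 1, 0] = b
    out[:, 1, 1] = c
    return out


def directional_overlap(
    post_a: NichePosterior,
    post_b: NichePosterior,
    conf: float = 0.95,
    nmc: int = 10_000,
    seed: int = 0,
    chunk: int = 128,
) -> OverlapResult:
    """Posterior P(individual of A ∈ conf-level niche region of B).

    For each paired posterior draw d, ``nmc`` points are sampled from
    Normal(μ_A[d], Σ_A[d]) and the fraction inside B's per-draw ellipse
    {x : (x−μ_B)ᵀ Σ_B⁻¹ (x−μ_B) ≤ χ²₂(conf)} is recorded.  Posteriors of
    different lengths are truncated to the shorter one.
    """
    if not 0.0 < conf < 1.0:
        raise ValueError("conf must lie in (0, 1)")
    if nmc < 1_000:
        raise ValueError("nmc must be at least 1000")
    q = stats.chi2.ppf(conf, df=2)
    nd = min(post_a.ndraw, post_b.ndraw)
    rng = np.random.default_rng(seed)
    la = _chol2(post_a.sigma[:nd])
    # inverse Cholesky of B's covariances, closed form for 2x2
    lb = _chol2(post_b.sigma[:nd])
    inv00 = 1.0 / lb[:, 0, 0]
    inv11 = 1.0 / lb[:, 1, 1]
    inv10 = -lb[:, 1, 0] * inv00 * inv11
    out = np.empty(nd)
    for start in range(0, nd, chunk):
        sl = slice(start, min(start + chunk, nd))
        c = sl.stop - sl.start
        z = rng.standard_normal((c, nmc, 2))
        x = post_a.mu[sl, None, :] + np.einsum("cij,cnj->cni", la[sl], z)
        d = x - post_b.mu[sl, None, :]
        u0 = inv00[sl, None] * d[:, :, 0]
        u1 = inv10[sl, None] * d[:, :, 0] + inv11[sl, None] * d[:, :, 1]
        out[sl] = np.mean(u0 * u0 + u1 * u1 <= q, axis=1)
    return OverlapResult(
        a_label=post_a.label, b_label=post_b.label, conf=conf, draws=out
    )


def overlap_matrix(
    posteriors: list[NichePosterior],
    conf: float = 0.95,
    nmc: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean overlap (%) for every ordered pair of groups.

    Entry (row, column) is the mean posterior probability of a row-group
    individual lying inside the column group's niche region; the diagonal
    is empty (NaN).
    """
    if len(posteriors) < 2:
        raise ValueError("at least 2 groups are required")
    labels = [p.label for p in posteriors]
    if len(set(labels)) != len(labels):
        raise ValueError("group labels must be unique")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(labels) ** 2) % (2**31))
    mat = pd.DataFrame(np.nan, index=labels, columns=labels)
    for pa in posteriors:
        for pb in posteriors:
            s = int(next(seeds))
            if pa.label == pb.label:
                continue
            res = directional_overlap(pa, pb, conf=conf, nmc=nmc, seed=s)
            mat.loc[pa.label, pb.label] = res.mean_pct
    return mat
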