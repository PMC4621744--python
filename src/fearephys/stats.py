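"""Small statistical primitives shared across the spike and slice analyses."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Ecdf", "ecdf", "permutation_pvalue", "sem"]


@dataclass(frozen=True)
class Ecdf:
    """Right-continuous empirical CDF over the uncensored sample."""

    support: np.ndarray
    cumulative: np.ndarray
    n: int
    n_censored: int = 0

    def __call__(self, x) -> np.ndarray:
        """F(x) = fraction of sample values <= x."""
        idx = np.searchsorted(self.support, np.asarray(x, dtype=float), side="right")
        cum = np.concatenate(([0.0], self.cumulative))
        return cum[idx]


def ecdf(values, n_censored: int = 0) -> Ecdf:
    """ECDF with one step per distinct value; jump height = multiplicity / n."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("cannot build an ECDF from an empty sample")
    support, counts = np.unique(v, return_counts=True)
    cumulative = np.cumsum(counts) / v.size
    return Ecdf(support=support, cumulative=cumulative, n=int(v.size), n_censored=n_censored)


def sem(values, axis=None) -> float | np.ndarray:
    """Standard error of the mean with the sample (ddof=1) sd."""
    v = np.asarray(values, dtype=float)
    n = v.shape[axis] if axis is not None else v.size
    if n < 2:
        return np.nan if axis is None else np.full(np.mean(v, axis=axis).shape, np.nan)
    return np.std(v, axis=axis, ddof=1) / np.sqrt(n)


def permutation_pvalue(
    a: np.ndarray,
    b: np.ndarray,
    n_permutations: int = 10_000,
    seed: int | None = 0,
    alternative: str = "two-sided",
) -> float:
    """Permutation p-value for a difference in group means.

    Pools the two samples, reassigns group labels ``n_permutations`` times
    with a seeded generator, and counts permuted |mean(a*) - mean(b*)| at
    least as extreme as observed (add-one correction, so p > 0 always).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    observed = np.mean(a) - np.mean(b)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    n_a = a.size
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(pooled)
        stat = np.mean(perm[:n_a]) - np.mean(perm[n_a:])
        if alternative == "two-sided":
            hit = abs(stat) >= abs(observed) - 1e-15
        elif alternative == "greater":
            hit = stat >= observed - 1e-15
        else:
            hit = stat <= observed + 1e-15
        count += hit
    return (count + 1) / (n_permutations + 1)
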