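"""Exact test for the intersection of k gene sets from a common universe.

The null model: each of the k sets is an independent uniform draw of a
fixed-size subset of an n-gene universe. The distribution of the size of
the k-way intersection is built by iterated hypergeometric mixing:
intersecting the running intersection (size x) with the next set of size
m_j is hypergeometric with population n, x "successes" and m_j draws.
Evaluated with scipy's log-space hypergeometric pmf so universes of
~2 x 10^4 genes do not underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class IntersectionTestResult:
    universe_n: int
    set_sizes: tuple[int, ...]
    observed: int
    expected: float
    p_upper: float

    def as_dict(self) -> dict:
        return {
            "n": self.universe_n,
            "sizes": list(self.set_sizes),
            "observed": self.observed,
            "expected": self.expected,
            "p": self.p_upper,
        }


def _check_sizes(n: int, sizes) -> tuple[int, ...]:
    sizes = tuple(int(m) for m in sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if n < 0:
        raise ValueError("universe size must be >= 0")
    for m in sizes:
        if m < 0 or m > n:
            raise ValueError(f"set size {m} outside [0, {n}]")
    if n == 0 and any(sizes):
        raise ValueError("empty universe with nonzero set sizes")
    return sizes


def intersection_pmf(n: int, sizes) -> np.ndarray:
    """Pmf of the k-way intersection size, indices 0..min(sizes)."""
    sizes = _check_sizes(n, sizes)
    if n == 0:
        return np.array([1.0])
    m1, rest = sizes[0], sizes[1:]
    support = np.arange(min(sizes) + 1)
    # running distribution over the current intersection size
    cur_max = m1
    pmf = np.zeros(cur_max + 1)
    pmf[m1] = 1.0
    for m in rest:
        new_max = min(cur_max, m)
        x = np.arange(cur_max + 1)  # current intersection sizes
        t = np.arange(new_max + 1)  # next intersection sizes
        # transition[x, t] = P(Hypergeom(N=n, K=x, draws=m) = t)
        with np.errstate(divide="ignore"):
            logtrans = stats.hypergeom.logpmf(t[None, :], n, x[:, None], m)
        trans = np.exp(logtrans)
        trans[np.isnan(trans)] = 0.0
        pmf = pmf @ trans
        cur_max = new_max
    pmf = pmf[: min(sizes) + 1]
    total = pmf.sum()
    if not np.isclose(total, 1.0, atol=1e-9):
        raise AssertionError(f"pmf sums to {total}, expected 1")
    return pmf


def expected_intersection(n: int, sizes) -> float:
    """E[X] under independent uniform draws: n * prod(m_i / n)."""
    sizes = _check_sizes(n, sizes)
    if n == 0:
        return 0.0
    return float(n * np.prod([m / n for m in sizes]))


def intersection_test(universe, sets) -> IntersectionTestResult:
    """Observed k-way overlap of gene sets vs the exact null distribution.

    p_upper = P(X >= observed): enrichment only.
    """
    universe = set(universe)
    sets = [set(s) for s in sets]
    for i, s in enumerate(sets):
        extra = s - universe
        if extra:
            raise ValueError(f"set {i} has elements outside the universe: {sorted(extra)[:5]}")
    n = len(universe)
    sizes = tuple(len(s) for s in sets)
    observed = len(set.intersection(*sets)) if sets else 0
    pmf = intersection_pmf(n, sizes)
    p_upper = float(pmf[observed:].sum()) if observed <= len(pmf) - 1 else 0.0
    p_upper = min(max(p_upper, np.finfo(float).tiny), 1.0)
    return IntersectionTestResult(
        universe_n=n,
        set_sizes=sizes,
        observed=observed,
        expected=expected_intersection(n, sizes),
        p_upper=p_upper,
    )
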