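"""Significance of the overlap between two gene sets by resampling.

The null model: draw |A| and |B| genes uniformly without replacement from
the universe (the post-filter gene set) and record the intersection size;
repeating this builds the expected overlap distribution, and the observed
overlap is scored against a normal fit to it (upper tail). The marginal
distribution of the null overlap is Hypergeometric(N, a, b), so the exact
upper-tail hypergeometric probability is always reported alongside as an
analytic oracle, together with the conservative empirical count-based p.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .exceptions import InputError, NumericalError
from .de import adjust_bh

__all__ = [
    "OverlapResult",
    "overlap_permutation_test",
    "overlap_hypergeometric",
    "adjust_overlap_pvalues",
]

_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class OverlapResult:
    universe_size: int
    a: int
    b: int
    observed: int
    frac_of_a: float
    frac_of_b: float
    null_mean: float
    null_sd: float
    z: float
    p_perm: float
    p_empirical: float
    p_hyper: float
    n_permutations: int
    seed: int | None
    underflow: bool = False
    padj: float | None = None

    def to_dict(self) -> dict:
        return asdict(self)


def overlap_hypergeometric(universe_size: int, a: int, b: int, k: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, a, b), computed stably.

    k = 0 gives 1; impossible configurations (k > min(a, b), a or b > N,
    k < a + b - N) raise an input error.
    """
    if a > universe_size or b > universe_size:
        raise InputError("set size exceeds universe size")
    if k > min(a, b) or k < 0 or k < a + b - universe_size:
        raise InputError(
            f"impossible overlap k={k} for N={universe_size}, a={a}, b={b}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); hypergeom(M=N, n=a, N=b)
    return float(stats.hypergeom.sf(k - 1, universe_size, a, b))


def overlap_permutation_test(universe: list[str], set_a: list[str],
                             set_b: list[str], n_permutations: int = 100000,
                             seed: int | None = None) -> OverlapResult:
    """Resampling overlap test between two gene sets.

    Each iteration draws fresh sets of sizes |A| and |B| uniformly without
    replacement from the universe and records their intersection size. The
    observed overlap is scored against Normal(null mean, null sd) on the
    upper tail (with a half-count continuity correction so the discrete
    P(X >= k) is approximated); probabilities below the smallest positive
    double are floored and flagged as underflow. Reproducible given seed.
    """
    universe_arr = np.asarray(list(universe))
    n = universe_arr.size
    if len(set(universe)) != n:
        raise InputError("universe contains duplicate gene ids")
    uni = set(universe)
    missing_a = sorted(set(set_a) - uni)
    missing_b = sorted(set(set_b) - uni)
    if missing_a or missing_b:
        raise InputError(
            f"set members outside the universe: A-only {missing_a[:5]}, "
            f"B-only {missing_b[:5]}")
    a, b = len(set(set_a)), len(set(set_b))
    if a < 1 or b < 1:
        raise InputError("both sets must be non-empty")
    if n_permutations < 1:
        raise InputError("n_permutations must be >= 1")

    observed = len(set(set_a) & set(set_b))

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=np.int64)
    # Uniform subsets of sizes a and b via random-key argpartition, in
    # chunks to bound memory; equivalent to sampling without replacement.
    chunk = max(1, min(n_permutations, int(2_000_000 / max(n, 1)) + 1))
    done = 0
    while done < n_permutations:
        c = min(chunk, n_permutations - done)
        idx_a = np.argpartition(rng.random((c, n)), a - 1, axis=1)[:, :a]
        idx_b = np.argpartition(rng.random((c, n)), b - 1, axis=1)[:, :b]
        in_a = np.zeros((c, n), dtype=bool)
        np.put_along_axis(in_a, idx_a, True, axis=1)
        null[done:done + c] = np.take_along_axis(
            in_a, idx_b, axis=1).sum(axis=1)
        done += c

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1))
    if null_sd == 0.0:
        raise NumericalError(
            "degenerate null: resampled overlaps are constant "
            f"(N={n}, a={a}, b={b}); the normal-tail p is undefined")

    z = (observed - null_mean) / null_sd
    # continuity-corrected upper tail approximating P(X >= observed)
    p_perm = float(stats.norm.sf((observed - 0.5 - null_mean) / null_sd))
    underflow = p_perm <= _P_FLOOR
    p_perm = max(p_perm, _P_FLOOR)
    p_emp = float((int((null >= observed).sum()) + 1) / (n_permutations + 1))
    p_hyper = overlap_hypergeometric(n, a, b, observed)

    return OverlapResult(
        universe_size=n, a=a, b=b, observed=observed,
        frac_of_a=observed / a, frac_of_b=observed / b,
        null_mean=null_mean, null_sd=null_sd, z=float(z),
        p_perm=p_perm, p_empirical=p_emp, p_hyper=p_hyper,
        n_permutations=n_permutations, seed=seed, underflow=underflow)


def adjust_overlap_pvalues(results: list[OverlapResult]) -> list[OverlapResult]:
    """BH correction of the normal-tail p values across the tested pairs."""
    if not results:
        return results
    padj = adjust_bh(np.array([r.p_perm for r in results]))
    for r, q in zip(results, padj):
        r.padj = float(q)
    return results
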