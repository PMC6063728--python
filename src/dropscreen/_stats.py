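"""Exact hypergeometric tail probabilities.

Both the sgRNA position matrix and gene-set enrichment report exact
hypergeometric tails. They are computed with integer binomial coefficients
so the only floating-point error is the final division; populations in this
package are at most a few thousand, well within exact-arithmetic reach.
"""

from math import comb

__all__ = ["hypergeom_sf", "hypergeom_cdf"]


def _check(x: int, population: int, successes: int, draws: int) -> None:
    if not (0 <= successes <= population):
        raise ValueError(f"successes {successes} not in [0, {population}]")
    if not (0 <= draws <= population):
        raise ValueError(f"draws {draws} not in [0, {population}]")


def hypergeom_sf(x: int, population: int, successes: int, draws: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(population, successes, draws).

    Note the convention: this is the inclusive upper tail, not scipy's
    ``sf`` (which is strict). Exact integer tail sum.
    """
    _check(x, population, successes, draws)
    lo = max(x, max(0, draws - (population - successes)))
    hi = min(successes, draws)
    if lo > hi:
        return 0.0
    num = sum(comb(successes, i) * comb(population - successes, draws - i)
              for i in range(lo, hi + 1))
    return num / comb(population, draws)


def hypergeom_cdf(x: int, population: int, successes: int, draws: int) -> float:
    """P(X <= x), inclusive lower tail, exact integer sum."""
    _check(x, population, successes, draws)
    lo = max(0, draws - (population - successes))
    hi = min(x, min(successes, draws))
    if hi < lo:
        return 0.0
    num = sum(comb(successes, i) * comb(population - successes, draws - i)
              for i in range(lo, hi + 1))
    return num / comb(population, draws)
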