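"""Exact and resampling statistics for nested-gene comparisons.

All tests are two-tailed.  The exact binomial test uses the
minimum-likelihood convention (the p-value sums P(X = k) over every outcome
no more probable than the observed one), matching R's ``binom.test``;
Fisher's exact test sums hypergeometric probabilities at fixed margins the
same way.  The two-sample permutation test uses the difference in means,
enumerates all label arrangements exactly when there are at most 20,000 of
them, and otherwise draws seeded Monte-Carlo permutations with the add-one
estimator p = (b + 1) / (B + 1).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "BinomialSpec",
    "ContingencyTable2x2",
    "TestResult",
    "ChiGramBar",
    "binomial_two_tailed",
    "fisher_two_tailed",
    "permutation_two_sample",
    "bonferroni",
    "corrected",
    "hanging_chigram",
]

logger = logging.getLogger(__name__)

EXHAUSTIVE_LIMIT = 20_000
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class BinomialSpec:
    """x successes out of n trials against null probability p0."""

    x: int
    n: int
    p0: float = 0.5

    def __post_init__(self) -> None:
        if not 0 <= self.x <= self.n:
            raise ValueError(f"need 0 <= x <= n, got x={self.x}, n={self.n}")
        if not 0 < self.p0 < 1:
            raise ValueError(f"p0 must be in (0,1), got {self.p0}")


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("at least one margin must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    p_value: float
    method: str
    tails: str = "two-sided"
    n_permutations: Optional[int] = None
    corrected: bool = False
    correction_factor: int = 1


@dataclass(frozen=True)
class ChiGramBar:
    """One bar of a hanging chi-gram: the signed standardized residual
    (observed - expected) / sqrt(expected) with its per-category test."""

    category: str
    observed: int
    expected: float
    height: float
    test: Optional[TestResult]
    flagged: bool = False


def binomial_two_tailed(spec: BinomialSpec | None = None, *, x: int | None = None,
                        n: int | None = None, p0: float = 0.5) -> TestResult:
    """Exact two-tailed binomial test (minimum-likelihood convention)."""
    if spec is None:
        spec = BinomialSpec(x=int(x), n=int(n), p0=p0)
    p = sps.binomtest(spec.x, spec.n, spec.p0, alternative="two-sided").pvalue
    return TestResult(p_value=float(min(1.0, p)), method="binomial_exact")


def fisher_two_tailed(table: ContingencyTable2x2 | Sequence[Sequence[int]]) -> TestResult:
    """Exact two-tailed Fisher test on a 2x2 table (fixed margins).

    A table with a zero row or column margin carries no information about
    association; it is reported as p = 1 and logged.
    """
    if not isinstance(table, ContingencyTable2x2):
        (a, b), (c, d) = table
        table = ContingencyTable2x2(int(a), int(b), int(c), int(d))
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        logger.info("degenerate 2x2 table with a zero margin: p = 1")
        return TestResult(p_value=1.0, method="fisher_exact")
    p = sps.fisher_exact(arr, alternative="two-sided")[1]
    return TestResult(p_value=float(min(1.0, p)), method="fisher_exact")


def permutation_two_sample(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    n_perm: int = 1000,
    seed: int = 0,
) -> TestResult:
    """Two-sided two-sample permutation test on the difference in means.

    With ``C(n_a + n_b, n_a)`` label arrangements at or below 20,000 the
    reference distribution is enumerated exactly; otherwise ``n_perm``
    Monte-Carlo permutations are drawn and p = (b + 1) / (B + 1), where b
    counts permuted statistics at least as extreme as the observed one.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    t_obs = a.mean() - b.mean()
    n_arrangements = math.comb(na + nb, na)

    if n_arrangements <= EXHAUSTIVE_LIMIT:
        total = pooled.sum()
        hits = 0
        for idx in combinations(range(na + nb), na):
            sa = pooled[list(idx)].sum()
            t = sa / na - (total - sa) / nb
            if abs(t) >= abs(t_obs) - _TIE_EPS:
                hits += 1
        return TestResult(
            p_value=hits / n_arrangements,
            method="permutation",
            n_permutations=n_arrangements,
        )

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    t_star = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    hits = int((np.abs(t_star) >= abs(t_obs) - _TIE_EPS).sum())
    return TestResult(
        p_value=(hits + 1) / (n_perm + 1),
        method="permutation",
        n_permutations=n_perm,
    )


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-corrected p-value: min(1, p * m)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p must be in [0,1], got {p}")
    if m < 1:
        raise ValueError("m must be at least 1")
    return min(1.0, p * m)


def corrected(result: TestResult, m: int) -> TestResult:
    """A copy of ``result`` with Bonferroni correction applied."""
    return replace(
        result,
        p_value=bonferroni(result.p_value, m),
        corrected=True,
        correction_factor=m,
    )


def hanging_chigram(
    observed: Mapping[str, int],
    expected_props: Mapping[str, float],
    bonferroni_m: Optional[int] = None,
) -> list[ChiGramBar]:
    """Hanging chi-gram bars against an expectation model.

    ``expected_props`` gives the expected category proportions (e.g. the
    tissue distribution of unnested genes) and must sum to 1.  Each bar's
    height is (O - E)/sqrt(E); each category also gets a two-tailed binomial
    test of the observed count against the expected proportion, Bonferroni
    corrected over the number of categories (the default) or ``bonferroni_m``.
    A category with zero expected proportion but nonzero observed count has
    infinite height and is flagged.
    """
    cats = list(observed)
    if set(cats) != set(expected_props):
        raise ValueError("observed and expected categories differ")
    props = np.array([expected_props[c] for c in cats], dtype=float)
    if abs(props.sum() - 1.0) > 1e-6:
        raise ValueError(f"expected proportions must sum to 1, got {props.sum():.6f}")
    total = int(sum(observed.values()))
    if total < 1:
        raise ValueError("observed total must be at least 1")
    m = bonferroni_m if bonferroni_m is not None else len(cats)

    bars: list[ChiGramBar] = []
    for cat, prop in zip(cats, props):
        obs = int(observed[cat])
        exp = total * float(prop)
        if exp > 0:
            height = (obs - exp) / math.sqrt(exp)
            flagged = False
        else:
            height = math.inf if obs > 0 else 0.0
            flagged = obs > 0
        if 0 < prop < 1:
            test = corrected(binomial_two_tailed(x=obs, n=total, p0=float(prop)), m)
        else:
            test = None
        bars.append(
            ChiGramBar(
                category=cat,
                observed=obs,
                expected=exp,
                height=float(height),
                test=test,
                flagged=flagged,
            )
        )
    return bars
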