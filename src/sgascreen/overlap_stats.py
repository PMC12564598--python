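"""Gene-set overlap statistics from first principles.

Two families of exact tests, both accumulated in log space so p-values far
below the double-precision underflow threshold of naive products remain
meaningful:

* pairwise overlap — the one-sided hypergeometric tail ``P(X >= k)`` with
  ``X ~ Hypergeometric(N, |A|, |B|)``, equivalent to a one-sided Fisher
  exact test on the 2x2 membership table;
* multi-set intersection — the exact null distribution of the size of the
  common intersection of m independent uniform random subsets of fixed
  sizes, built as a recursive mixture of hypergeometrics:
  ``D_2 = HG(N, n_1, n_2)`` and
  ``D_j(k) = sum_i D_{j-1}(i) * HG_pmf(N, i, n_j)(k)``.

The background universe N must always be supplied by the caller: overlap
significance is meaningless without an explicit statement of which genes
could have been members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom


@dataclass
class GeneSet:
    """A named set of gene identifiers."""

    name: str
    members: frozenset[str]

    def __init__(self, name: str, members) -> None:
        self.name = name
        self.members = frozenset(members)

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class OverlapResult:
    """Outcome of an overlap test.

    ``expected`` is the null expectation ``N * prod(n_i / N)`` of the
    intersection size, ``fold_enrichment`` the ratio of observed to
    expected, ``log10_p`` the base-10 log of the tail probability (exact
    even when ``p_value`` underflows to 0), and ``odds_ratio`` the sample
    odds ratio of the 2x2 table (pairwise tests only, None otherwise).
    """

    set_names: tuple[str, ...]
    set_sizes: tuple[int, ...]
    background_n: int
    intersection: int
    expected: float
    fold_enrichment: float
    p_value: float
    log10_p: float
    odds_ratio: float | None = None


def _log_tail(log_pmf: np.ndarray, k: int) -> float:
    """log P(X >= k) from a vector of log pmf values over 0..len-1."""
    if k <= 0:
        return 0.0
    if k >= len(log_pmf):
        return -np.inf
    with np.errstate(divide="ignore"):
        return float(min(0.0, logsumexp(log_pmf[k:])))


def _hypergeom_logpmf(support: np.ndarray, N: int, n_a, n_b) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        out = hypergeom.logpmf(support, N, n_a, n_b)
    return np.where(np.isnan(out), -np.inf, out)


def _hypergeom_weights(N: int, n_a: int, n_b: int) -> tuple[int, np.ndarray]:
    """Unnormalized pmf weights over the support, anchored at the mode.

    Built from the exact pmf ratio
    ``pmf(j+1)/pmf(j) = (n_a-j)(n_b-j) / ((j+1)(N-n_a-n_b+j+1))``
    outward from the mode, so each weight carries only a few rounding
    errors and no log-gamma evaluation.  Weights far in the tails flush to
    zero; the caller falls back to log space there.
    """
    k_min, k_max = max(0, n_a + n_b - N), min(n_a, n_b)
    size = k_max - k_min + 1
    w = np.zeros(size)

    def ratio(j):  # pmf(j+1) / pmf(j)
        return ((n_a - j) * (n_b - j)) / ((j + 1) * (N - n_a - n_b + j + 1))

    mode = k_min
    while mode < k_max and ratio(mode) >= 1.0:
        mode += 1
    w[mode - k_min] = 1.0
    for j in range(mode, k_max):
        w[j - k_min + 1] = w[j - k_min] * ratio(j)
    for j in range(mode - 1, k_min - 1, -1):
        r = ratio(j)
        w[j - k_min] = w[j - k_min + 1] / r if r > 0 else 0.0
    return k_min, w


def _tail_prob(N: int, n_a: int, n_b: int, k: int,
               alternative: str = "greater") -> tuple[float, float]:
    """(p, log_p) of the hypergeometric tail at observed intersection k.

    The probability itself comes from the normalized ratio-recurrence
    weights (relative accuracy ~1e-13); log_p from log-space accumulation,
    which stays finite far below the linear-space underflow threshold.
    """
    k_min, k_max = max(0, n_a + n_b - N), min(n_a, n_b)
    support = np.arange(k_max + 1)
    log_pmf = _hypergeom_logpmf(support, N, n_a, n_b)
    if alternative == "greater":
        log_p = _log_tail(log_pmf, k)
    elif alternative == "less":
        with np.errstate(divide="ignore"):
            log_p = float(min(0.0, logsumexp(log_pmf[: k + 1])))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")

    w_min, weights = _hypergeom_weights(N, n_a, n_b)
    total = weights.sum()
    if alternative == "greater":
        part = weights[max(k - w_min, 0):].sum()
    else:
        part = weights[: max(k - w_min + 1, 0)].sum()
    p = part / total if part > 0 else math.exp(log_p)
    return min(p, 1.0), log_p


def fisher_overlap_counts(
    background_n: int,
    n_a: int,
    n_b: int,
    k: int,
    names: tuple[str, str] = ("A", "B"),
    alternative: str = "greater",
) -> OverlapResult:
    """Pairwise overlap test from counts alone.

    ``alternative="greater"`` (default) tests enrichment, ``"less"``
    depletion.  Raises ValueError when the counts are mutually impossible
    (inconsistent inputs).
    """
    N = background_n
    if not (0 <= n_a <= N and 0 <= n_b <= N):
        raise ValueError("set sizes must lie within the background")
    if k > min(n_a, n_b) or k < max(0, n_a + n_b - N):
        raise ValueError(
            f"impossible intersection k={k} for sizes ({n_a}, {n_b}) in N={N}"
        )
    p, log_p = _tail_prob(N, n_a, n_b, k, alternative)

    expected = N * (n_a / N) * (n_b / N) if N > 0 else 0.0
    # 2x2 table: in-both, a-only, b-only, neither
    d = N - n_a - n_b + k
    b_, c_ = n_a - k, n_b - k
    odds = (k * d / (b_ * c_)) if b_ > 0 and c_ > 0 else float("inf")
    return OverlapResult(
        set_names=names,
        set_sizes=(n_a, n_b),
        background_n=N,
        intersection=k,
        expected=expected,
        fold_enrichment=k / expected if expected > 0 else float("nan"),
        p_value=float(p),
        log10_p=log_p / np.log(10),
        odds_ratio=odds,
    )


def fisher_overlap(
    a: GeneSet,
    b: GeneSet,
    background_n: int,
    alternative: str = "greater",
) -> OverlapResult:
    """One-sided hypergeometric (Fisher) overlap test of two gene sets.

    The intersection is computed from set membership; significance is the
    exact tail probability of seeing an overlap at least this large when
    both sets are uniform random subsets of a background of
    ``background_n`` genes.
    """
    k = len(a.members & b.members)
    return fisher_overlap_counts(
        background_n, len(a), len(b), k,
        names=(a.name, b.name), alternative=alternative,
    )


# ---------------------------------------------------------------------------
# Exact multi-set intersection test
# ---------------------------------------------------------------------------


def multiset_log_distribution(
    background_n: int, sizes: Sequence[int]
) -> np.ndarray:
    """Log pmf of the common-intersection size of m random subsets.

    Built by the recursive mixture of hypergeometrics; support is
    ``0..min(sizes)``.  Sizes are sorted internally so the result is
    exactly permutation-invariant.
    """
    N = background_n
    sizes = sorted(int(s) for s in sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two sets")
    if any(s < 0 or s > N for s in sizes):
        raise ValueError("set sizes must lie within the background")

    cap = min(sizes[0], sizes[1])
    log_d = _hypergeom_logpmf(np.arange(cap + 1), N, sizes[0], sizes[1])
    for n_j in sizes[2:]:
        new_cap = min(cap, n_j)
        i = np.arange(cap + 1)[:, None]  # previous intersection size
        k = np.arange(new_cap + 1)[None, :]
        log_m = _hypergeom_logpmf(k, N, i, n_j)
        with np.errstate(divide="ignore"):
            log_d = logsumexp(log_d[:, None] + log_m, axis=0)
        cap = new_cap
    return log_d


def multiset_exact_test(
    sets: Sequence[GeneSet], background_n: int
) -> OverlapResult:
    """Exact test for the total intersection of m >= 2 gene sets.

    Under the null that each set is an independent uniform random subset of
    its observed size, returns ``p = P(X >= k_observed)`` for the size X of
    the common intersection.  For m = 2 this coincides exactly with
    :func:`fisher_overlap`.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    N = background_n
    members = [s.members for s in sets]
    inter = frozenset.intersection(*members)
    k = len(inter)
    sizes = [len(s) for s in sets]
    if len(sets) == 2:  # reduction case: identical to the pairwise test
        p, log_p = _tail_prob(N, sizes[0], sizes[1], k)
    else:
        log_d = multiset_log_distribution(N, sizes)
        log_p = _log_tail(log_d, k)
        p = float(np.exp(log_p))
    expected = N * float(np.prod([s / N for s in sizes])) if N > 0 else 0.0
    return OverlapResult(
        set_names=tuple(s.name for s in sets),
        set_sizes=tuple(sizes),
        background_n=N,
        intersection=k,
        expected=expected,
        fold_enrichment=k / expected if expected > 0 else float("nan"),
        p_value=p,
        log10_p=log_p / np.log(10),
        odds_ratio=None,
    )


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_REPORT_COLUMNS = [
    "sets", "set_sizes", "background_n", "intersection", "expected",
    "fold_enrichment", "p_value", "log10_p",
]


def overlap_report(
    sets: Sequence[GeneSet], background_n: int, out_path: str | Path
) -> pd.DataFrame:
    """All pairwise tests plus the full-intersection test, as a TSV.

    For two sets the pair and the full intersection coincide; the report is
    deduplicated to a single row.  Row order is deterministic: pairs in
    input order, then the ``all`` row.
    """
    if len(sets) < 2:
        raise ValueError("need at least two sets")
    results: list[OverlapResult] = []
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            results.append(fisher_overlap(sets[i], sets[j], background_n))
    if len(sets) > 2:
        results.append(multiset_exact_test(sets, background_n))

    rows = []
    for res in results:
        rows.append({
            "sets": "&".join(res.set_names),
            "set_sizes": ";".join(str(s) for s in res.set_sizes),
            "background_n": res.background_n,
            "intersection": res.intersection,
            "expected": "%.6g" % res.expected,
            "fold_enrichment": "%.6g" % res.fold_enrichment,
            "p_value": "%.6g" % res.p_value,
            "log10_p": "%.6g" % res.log10_p,
        })
    df = pd.DataFrame(rows, columns=_REPORT_COLUMNS)
    df.to_csv(out_path, sep="\t", index=False)
    return df
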