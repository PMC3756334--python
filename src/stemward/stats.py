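"""Cross-dataset statistics.

Exact binomial tests on direction counts, the log-likelihood-ratio G
test on 2x2 condition x direction tables, the shared rank-based
permutation p-value convention, and a dataset-level jackknife that
re-pools the node-recovery comparison over random subsets of matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import stats as sps

from .matrix import StemwardError

__all__ = [
    "rank_p",
    "binomial_test",
    "expected_significant",
    "ContingencyTable2x2",
    "GTestResult",
    "g_test",
    "dataset_jackknife",
    "JackknifeReport",
]


def rank_p(r: int, n: int) -> float:
    """Permutation p-value by rank: ``(r + 1) / (n + 1)``.

    ``r`` counts null replicates at or beyond the observed value (ties
    included).  0 of 500 gives 1/501 ~ 0.002; 259 of 500 gives
    260/501 ~ 0.52.
    """
    if n < 1 or r < 0 or r > n:
        raise StemwardError(f"invalid rank {r} of {n}")
    return (r + 1) / (n + 1)


def binomial_test(k: int, n: int, p0: float = 0.5, sided: str = "two") -> float:
    """Exact binomial tail probability.

    ``sided='two'`` sums all outcomes at least as improbable as ``k``;
    ``'one'`` (alias ``'greater'``) is the upper tail, ``'less'`` the
    lower.
    """
    if n == 0:
        raise StemwardError("binomial test requires n > 0")
    if not 0 <= k <= n:
        raise StemwardError(f"k={k} outside [0, {n}]")
    if not 0 < p0 < 1:
        raise StemwardError("null probability must be in (0, 1)")
    alternative = {"two": "two-sided", "one": "greater",
                   "greater": "greater", "less": "less"}.get(sided)
    if alternative is None:
        raise StemwardError(f"unknown sidedness {sided!r}")
    return float(sps.binomtest(k, n, p0, alternative=alternative).pvalue)


def expected_significant(n_tests: int, alpha: float = 0.05) -> float:
    """Expected count of significant tests under the global null."""
    return n_tests * alpha


@dataclass(frozen=True)
class ContingencyTable2x2:
    """condition x direction counts (rows: conditions, cols: directions)."""

    counts: tuple[tuple[int, int], tuple[int, int]]
    row_labels: tuple[str, str] = ("fossilization", "random")
    col_labels: tuple[str, str] = ("down", "up")

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (2, 2) or (arr < 0).any():
            raise StemwardError("need a 2x2 table of non-negative counts")
        if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
            raise StemwardError("G test requires positive margins")

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


class GTestResult(NamedTuple):
    G: float
    p_value: float
    df: int


def g_test(table: ContingencyTable2x2) -> GTestResult:
    """Log-likelihood-ratio test of independence on a 2x2 table.

    ``G = 2 * sum O * ln(O / E)`` with expectations from the margins;
    the p-value is the chi-square upper tail with 1 df (no continuity
    correction).
    """
    obs = table.as_array()
    total = obs.sum()
    exp = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
    G = float(2.0 * terms.sum())
    return GTestResult(G=G, p_value=float(sps.chi2.sf(G, 1)), df=1)


@dataclass
class JackknifeReport:
    mode: str
    n_resamples: int
    inclusion_p: float
    alpha: float
    p_values: list[float] = field(default_factory=list)
    n_significant: int = 0
    n_redrawn_empty: int = 0

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "n_resamples": self.n_resamples,
            "inclusion_p": self.inclusion_p,
            "alpha": self.alpha,
            "n_significant": self.n_significant,
            "n_redrawn_empty": self.n_redrawn_empty,
            "p_values": list(self.p_values),
        }


def dataset_jackknife(
    results,
    n_resamples: int = 50,
    inclusion_p: float = 0.5,
    rng=None,
    alpha: float = 0.05,
) -> JackknifeReport:
    """Stability of the pooled node-recovery comparison.

    Each resample includes each matrix's result with probability
    ``inclusion_p`` and re-pools recovery counts and the paired null on
    the subset; resamples that include nothing are redrawn (counted).
    """
    from .node_recovery import NodeRecoveryResult, aggregate_node_recovery

    usable = [r for r in results if not r.undefined]
    if not usable:
        raise StemwardError("no usable results to jackknife")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    report = JackknifeReport(
        mode=usable[0].mode, n_resamples=n_resamples,
        inclusion_p=inclusion_p, alpha=alpha,
    )
    for _ in range(n_resamples):
        while True:
            mask = gen.random(len(usable)) < inclusion_p
            if mask.any():
                break
            report.n_redrawn_empty += 1
        subset = [r for r, m in zip(usable, mask) if m]
        agg = aggregate_node_recovery(subset)
        report.p_values.append(agg.p_value)
        if agg.p_value < alpha:
            report.n_significant += 1
    return report
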