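"""Statistical tests for leadership tallies.

The central test asks whether per-individual counts (who departed
first, who walked in front, who displayed pre-departure behavior) could
have arisen from a discrete uniform distribution over the group.  With
group sizes of 6-12 and a few dozen movements, asymptotic chi-square
reference distributions are unreliable, so the log-likelihood-ratio G
statistic is used with Williams' small-sample correction and its null
distribution is obtained by Monte-Carlo simulation.

Per-individual follow-up is an exact two-sided binomial test of each
count against the chance probability 1/N, with Holm step-down control
of the family-wise error rate.  Rank-based helpers (tie-aware Spearman,
Kruskal-Wallis) cover the age-correlation and joining-efficiency
questions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GTestResult",
    "PosthocResult",
    "IndividualTest",
    "g_statistic",
    "williams_correct",
    "mc_uniform_test",
    "posthoc_chance_tests",
    "holm_adjust",
    "spearman",
    "kruskal_wallis",
]


@dataclass(frozen=True)
class GTestResult:
    """Williams-corrected G against a uniform null, with Monte-Carlo p."""

    G_raw: float
    williams_q: float
    G_adj: float
    df: int
    p_mc: float
    n_simulations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "G_raw": self.G_raw,
            "williams_q": self.williams_q,
            "G_adj": self.G_adj,
            "df": self.df,
            "p_mc": self.p_mc,
            "n_simulations": self.n_simulations,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class IndividualTest:
    individual: str
    observed: int
    expected: float
    p_raw: float
    p_holm: float
    significant: bool
    direction: str  # "above" or "below"


@dataclass(frozen=True)
class PosthocResult:
    """Per-individual chance-level tests, Holm-adjusted at family alpha."""

    tests: tuple[IndividualTest, ...]
    alpha: float

    @property
    def flagged(self) -> tuple[str, ...]:
        return tuple(t.individual for t in self.tests if t.significant)

    @property
    def flagged_above(self) -> tuple[str, ...]:
        return tuple(
            t.individual for t in self.tests if t.significant and t.direction == "above"
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "tests": [vars(t).copy() for t in self.tests],
        }


def g_statistic(
    counts: Sequence[int], expected: Sequence[float]
) -> Optional[float]:
    """Log-likelihood-ratio goodness-of-fit statistic.

    G = 2 * sum_i o_i * ln(o_i / e_i); zero-count cells contribute 0.
    Returns ``None`` when every count is zero (the statistic is
    undefined — there is nothing to test).  Observed and expected totals
    must agree.
    """
    o = np.asarray(counts, dtype=float)
    e = np.asarray(expected, dtype=float)
    if o.shape != e.shape:
        raise ValueError("counts and expected must have equal length")
    if np.any(o < 0) or np.any(e <= 0):
        raise ValueError("counts must be >= 0 and expected > 0")
    if o.sum() == 0:
        return None
    if not math.isclose(o.sum(), e.sum(), rel_tol=1e-9, abs_tol=1e-6):
        raise ValueError(
            f"observed total {o.sum()} does not match expected total {e.sum()}"
        )
    nz = o > 0
    return float(2.0 * np.sum(o[nz] * np.log(o[nz] / e[nz])))


def williams_correct(G: float, n: float, k: int) -> tuple[float, float]:
    """Williams' small-sample correction for a k-cell goodness-of-fit G.

    q = 1 + (k^2 - 1) / (6 n (k - 1)); the corrected statistic is G / q.
    q > 1 for any finite n, so the correction always shrinks G.
    """
    if n < 1 or k < 2:
        raise ValueError("need total count n >= 1 and k >= 2 cells")
    q = 1.0 + (k * k - 1.0) / (6.0 * n * (k - 1.0))
    return q, G / q


def _g_adj_uniform_batch(sim_counts: np.ndarray, expected: float, q: float) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = sim_counts * np.log(sim_counts / expected)
    terms = np.where(sim_counts > 0, terms, 0.0)
    return 2.0 * terms.sum(axis=1) / q


def mc_uniform_test(
    counts: Sequence[int], B: int = 2000, seed: int = 0
) -> GTestResult:
    """Monte-Carlo test of uniformity for per-individual counts.

    Simulates ``B`` multinomial samples of the same total from the
    uniform distribution over the k individuals, applies the identical
    Williams correction to each simulated G for exchangeability with the
    observed statistic, and reports the add-one p estimate
    ``(1 + #{G_sim >= G_obs}) / (B + 1)`` — never exactly zero.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    o = np.asarray(counts, dtype=float)
    k = len(o)
    n = int(o.sum())
    if n == 0:
        raise ValueError("all counts zero: uniformity test undefined")
    expected = np.full(k, n / k)
    G_raw = g_statistic(counts, expected)
    assert G_raw is not None
    q, G_adj = williams_correct(G_raw, n, k)
    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, np.full(k, 1.0 / k), size=B)
    g_sims = _g_adj_uniform_batch(sims.astype(float), n / k, q)
    p = (1 + int(np.sum(g_sims >= G_adj - 1e-12))) / (B + 1)
    return GTestResult(
        G_raw=float(G_raw),
        williams_q=float(q),
        G_adj=float(G_adj),
        df=k - 1,
        p_mc=float(p),
        n_simulations=B,
        seed=seed,
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment, monotone and capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="holm")[1]


def posthoc_chance_tests(
    counts: Sequence[int],
    n: int,
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> PosthocResult:
    """Exact binomial tests of each individual's count against chance 1/k.

    Each count is tested two-sided against Binomial(n, 1/k) — interest
    lies in both above- and below-chance contributions — and the k
    p-values are Holm-adjusted as one family.
    """
    k = len(counts)
    if k < 2:
        raise ValueError("need at least 2 individuals")
    if labels is None:
        labels = [f"i{j + 1}" for j in range(k)]
    p0 = 1.0 / k
    raw = [stats.binomtest(int(c), n, p0).pvalue for c in counts]
    adj = holm_adjust(raw)
    expected = n * p0
    tests = tuple(
        IndividualTest(
            individual=str(lab),
            observed=int(c),
            expected=expected,
            p_raw=float(pr),
            p_holm=float(pa),
            significant=bool(pa < alpha),
            direction="above" if c > expected else "below",
        )
        for lab, c, pr, pa in zip(labels, counts, raw, adj)
    )
    return PosthocResult(tests=tests, alpha=alpha)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        return math.nan
    return float(a @ b) / denom


def spearman(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 9
) -> tuple[Optional[float], Optional[float]]:
    """Tie-aware Spearman rank correlation.

    rs is the Pearson correlation of the mid-rank vectors.  For short
    series (n <= ``exact_max_n``) the two-sided p-value is the exact
    permutation probability of |rs| at least as large as observed;
    longer series use the usual t approximation.  Returns
    ``(None, None)`` when either rank vector has zero variance.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d sequences")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = _midranks(xa)
    ry = _midranks(ya)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        return None, None
    rs = _pearson(rx, ry)
    if n <= exact_max_n:
        rxc = rx - rx.mean()
        ryc = ry - ry.mean()
        denom = math.sqrt(float(rxc @ rxc) * float(ryc @ ryc))
        perms = np.array(list(permutations(range(n))), dtype=np.intp)
        rs_all = (ryc[perms] @ rxc) / denom
        p = float(np.mean(np.abs(rs_all) >= abs(rs) - 1e-12))
    else:
        t = rs * math.sqrt((n - 2) / max(1e-300, 1.0 - rs * rs))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rs, min(1.0, p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H with a chi-square p on k-1 df.

    Degenerate input (every observation identical) gives H = 0, p = 1.
    """
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    H, p = stats.kruskal(*[np.asarray(g, dtype=float) for g in groups])
    return float(H), float(p)
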