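"""Platform-bias screening for allele frequencies.

Reference panels aggregate samples sequenced on several instrument platforms.
A variant whose alternate/reference allele counts are not homogeneous across
platforms is suspect (batch artifact rather than biology) and is excluded from
the pathogenic-variant screen.

Homogeneity is assessed with the exact conditional independence test on the
2 × k table of alternate/reference counts per platform: classic two-sided
Fisher for k = 2 and its Freeman–Halton extension for k > 2, using the
standard probability-ordering definition of the two-sided p value — the
probability, with all margins fixed, of tables no more probable than the
observed one. The null table space is enumerated exhaustively when it is
small enough; otherwise p is estimated by Monte Carlo sampling from the
multivariate hypergeometric null with an add-one correction.

Variants with p < 0.001 (strict inequality) are flagged as platform-biased.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

logger = logging.getLogger(__name__)

__all__ = [
    "PlatformCounts",
    "exact_independence_test",
    "screen_platform_bias",
    "read_platform_table",
]

#: Relative tolerance when comparing table probabilities to the observed one
#: (guards against float noise in "p(T) <= p(observed)"; same convention as
#: other exact-test implementations).
_REL_TOL = 1e-7


@dataclass
class PlatformCounts:
    """Alternate/reference allele counts for one variant across platforms."""

    key: str
    platforms: list[str]
    alt_counts: list[int]
    ref_counts: list[int]
    p_value: float | None = None
    mc_stderr: float | None = None
    biased: bool = False

    def table(self) -> np.ndarray:
        """2 × k table (row 0 = alt, row 1 = ref), platforms with data only."""
        alt = np.asarray(self.alt_counts, dtype=np.int64)
        ref = np.asarray(self.ref_counts, dtype=np.int64)
        keep = (alt + ref) > 0
        if not keep.all():
            logger.debug("%s: dropping %d platform(s) with zero alleles", self.key, (~keep).sum())
        return np.vstack([alt[keep], ref[keep]])


def _log_table_prob(a: np.ndarray, col_totals: np.ndarray, n: int, r0: int) -> np.ndarray:
    """Log multivariate-hypergeometric probability of row-0 allocation(s) ``a``.

    P(a) = prod_j C(c_j, a_j) / C(N, r0), vectorized over the leading axis.
    """
    a = np.atleast_2d(a)
    c = col_totals[None, :]
    log_binom = gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
    denom = gammaln(n + 1) - gammaln(r0 + 1) - gammaln(n - r0 + 1)
    return log_binom.sum(axis=1) - denom


def _count_tables(col_totals: np.ndarray, r0: int) -> int:
    """Number of 2×k tables with the given margins (DP over columns)."""
    reachable = {0: 1}
    for c in col_totals:
        nxt: dict[int, int] = {}
        for s, cnt in reachable.items():
            for a in range(0, min(int(c), r0 - s) + 1):
                nxt[s + a] = nxt.get(s + a, 0) + cnt
        reachable = nxt
    return reachable.get(r0, 0)


def _enumerate_allocations(col_totals: np.ndarray, r0: int) -> np.ndarray:
    """All row-0 allocations a (len k, 0<=a_j<=c_j, sum=r0), as an (m, k) array."""
    k = len(col_totals)
    out: list[tuple[int, ...]] = []
    a = [0] * k

    def rec(j: int, remaining: int) -> None:
        if j == k - 1:
            if 0 <= remaining <= col_totals[j]:
                a[j] = remaining
                out.append(tuple(a))
            return
        tail_capacity = int(col_totals[j + 1 :].sum())
        lo = max(0, remaining - tail_capacity)
        hi = min(int(col_totals[j]), remaining)
        for v in range(lo, hi + 1):
            a[j] = v
            rec(j + 1, remaining - v)

    rec(0, r0)
    return np.asarray(out, dtype=np.int64)


def exact_independence_test(
    table: Sequence[Sequence[int]] | np.ndarray,
    enum_cap: int = 200_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[float, float | None]:
    """Exact two-sided test of allele-count homogeneity on a 2 × k table.

    Returns ``(p, mc_stderr)``; ``mc_stderr`` is None when the table space was
    enumerated exactly, else the binomial standard error of the Monte Carlo
    estimate. Degenerate tables (an all-zero row or column) return p = 1 with
    a warning — no frequency contrast exists to test.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] < 2:
        raise ValueError(f"need a 2 x k table with k >= 2, got shape {t.shape}")
    if (t < 0).any():
        raise ValueError("negative cell counts")
    col_totals = t.sum(axis=0)
    row_totals = t.sum(axis=1)
    if (row_totals == 0).any() or (col_totals == 0).any():
        logger.warning("degenerate table (all-zero row or column); p = 1")
        return 1.0, None

    n = int(t.sum())
    r0 = int(row_totals[0])
    log_p_obs = float(_log_table_prob(t[0], col_totals, n, r0)[0])
    cutoff = log_p_obs + math.log1p(_REL_TOL)

    if _count_tables(col_totals, r0) <= enum_cap:
        allocations = _enumerate_allocations(col_totals, r0)
        log_probs = _log_table_prob(allocations, col_totals, n, r0)
        mask = log_probs <= cutoff
        if mask.all():  # observed table is modal: every table counts
            return 1.0, None
        p = float(np.exp(log_probs[mask]).sum())
        return min(p, 1.0), None

    rng = np.random.default_rng(seed)
    draws = rng.multivariate_hypergeometric(col_totals, r0, size=n_mc)
    log_probs = _log_table_prob(draws, col_totals, n, r0)
    b = int((log_probs <= cutoff).sum())
    p = (b + 1) / (n_mc + 1)
    stderr = math.sqrt(p * (1 - p) / n_mc)
    return p, stderr


def screen_platform_bias(
    counts: Iterable[PlatformCounts],
    alpha: float = 0.001,
    enum_cap: int = 200_000,
    n_mc: int = 100_000,
    seed: int = 0,
) -> tuple[list[str], list[str]]:
    """Partition variant keys into (unbiased, biased) at the given threshold.

    ``biased ⇔ p < alpha`` (strict); biased variants are meant to be excluded
    from tiering input. p values and flags are written back onto the records.
    A variant with fewer than two informative platforms cannot be tested and
    is passed through as unbiased with ``p_value=None``.
    """
    unbiased, biased = [], []
    for pc in counts:
        t = pc.table()
        if t.shape[1] < 2:
            logger.warning("%s: <2 platforms with data; bias untestable", pc.key)
            pc.p_value, pc.biased = None, False
            unbiased.append(pc.key)
            continue
        pc.p_value, pc.mc_stderr = exact_independence_test(
            t, enum_cap=enum_cap, n_mc=n_mc, seed=seed
        )
        pc.biased = pc.p_value < alpha
        (biased if pc.biased else unbiased).append(pc.key)
    return unbiased, biased


def read_platform_table(path) -> list[PlatformCounts]:
    """Read the long-format platform count TSV (key, platform, alt_count, ref_count)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"key": str, "platform": str})
    out = []
    for key, grp in df.groupby("key", sort=True):
        out.append(
            PlatformCounts(
                key=str(key),
                platforms=list(grp["platform"]),
                alt_counts=[int(x) for x in grp["alt_count"]],
                ref_counts=[int(x) for x in grp["ref_count"]],
            )
        )
    return out


def platform_counts_frame(counts: Sequence[PlatformCounts]) -> pd.DataFrame:
    """Long-format table with per-variant p value and bias flag."""
    rows = []
    for pc in counts:
        for plat, a, r in zip(pc.platforms, pc.alt_counts, pc.ref_counts):
            rows.append(
                {
                    "key": pc.key,
                    "platform": plat,
                    "alt_count": a,
                    "ref_count": r,
                    "p_value": pc.p_value,
                    "biased": pc.biased,
                }
            )
    return pd.DataFrame(rows)
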