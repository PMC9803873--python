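"""Over-representation analysis and phase set enrichment (PSEA).

ORA: upper-tail hypergeometric test of a query gene list (e.g. the diurnal
genes of one layer) against a caller-supplied background, per gene set, with
BH correction across the tested sets. Sets are intersected with the
background first; sets smaller than ``min_set`` within the background are
excluded before correction.

PSEA: for each gene set, the acrophases of its diurnal members (rounded to
the full hour) are compared with a uniform distribution around the clock by
the Kuiper test, the rotation-invariant variant of Kolmogorov–Smirnov
(V = D+ + D-), so antiphase clusters that cancel in a Rayleigh test are still
detected. The p-value uses Stephens' asymptotic series with the standard
small-sample factor; an exact-style Monte-Carlo null is available for very
small sets.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import DEFAULT_PERIOD, bh_fdr
from .io_metadata import GeneSetCollection


# ---------------------------------------------------------------------------
# Hypergeometric over-representation
# ---------------------------------------------------------------------------

def hypergeom_ora(
    query: Sequence[str],
    collections: GeneSetCollection,
    background: Sequence[str],
    min_set: int = 20,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each gene set.

    ``query`` must be a subset of ``background``; sets are intersected with
    the background and those with fewer than ``min_set`` background members
    are dropped before BH correction.
    """
    bg = set(map(str, background))
    if not bg:
        raise ValueError("background gene set is empty")
    q = set(map(str, query))
    stray = q - bg
    if stray:
        raise ValueError(f"query genes missing from background: {sorted(stray)[:5]}")
    N, n = len(bg), len(q)
    rows = []
    for name, members in collections:
        in_bg = bg.intersection(members)
        K = len(in_bg)
        if K < min_set:
            continue
        k = len(q.intersection(in_bg))
        # P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append({"set_name": name, "overlap": k, "set_size_in_background": K,
                     "query_size": n, "background_size": N, "p": min(p, 1.0)})
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size_in_background",
                                      "query_size", "background_size", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else np.nan
    return out.sort_values("p", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Kuiper uniformity test
# ---------------------------------------------------------------------------

def _kuiper_statistic(u: np.ndarray) -> float:
    """V = D+ + D- of sorted unit-interval values against the uniform CDF."""
    u = np.sort(u)
    n = u.size
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def kuiper_pvalue(V: float, n: int) -> float:
    """Stephens' asymptotic tail probability with small-sample correction."""
    lam = (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n)) * V
    if lam < 0.4:
        return 1.0
    j = np.arange(1, 101)
    terms = 2.0 * (4.0 * j**2 * lam**2 - 1.0) * np.exp(-2.0 * j**2 * lam**2)
    return float(min(max(terms.sum(), 0.0), 1.0))


def kuiper_uniform_test(
    phases: Sequence[float],
    period: float = DEFAULT_PERIOD,
    monte_carlo: bool = False,
    n_mc: int = 100_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Kuiper test of circular uniformity of acrophases (hours).

    Returns ``(V, p)``. With ``monte_carlo=True`` the p-value is estimated
    from ``n_mc`` uniform null draws of the same sample size (preferable for
    n < 20 where the asymptotic series is approximate).
    """
    ph = np.asarray(phases, dtype=float)
    if ph.size < 5:
        raise ValueError("Kuiper test needs at least 5 phases (min-set rule)")
    u = np.mod(ph, period) / period
    V = _kuiper_statistic(u)
    if monte_carlo:
        rng = np.random.default_rng(0) if rng is None else rng
        null = rng.random((n_mc, ph.size))
        null.sort(axis=1)
        i = np.arange(1, ph.size + 1)
        vnull = (i / ph.size - null).max(axis=1) + (null - (i - 1) / ph.size).max(axis=1)
        p = float((np.count_nonzero(vnull >= V) + 1) / (n_mc + 1))
    else:
        p = kuiper_pvalue(V, ph.size)
    return V, p


# ---------------------------------------------------------------------------
# Phase set enrichment
# ---------------------------------------------------------------------------

def psea(
    phase_table: Mapping[str, float],
    collections: GeneSetCollection,
    min_set: int = 5,
    q_threshold: float = 0.05,
    period: float = DEFAULT_PERIOD,
    monte_carlo: bool = False,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Phase set enrichment: Kuiper non-uniformity of each set's acrophases.

    ``phase_table`` maps diurnal genes to acrophases in hours. Phases are
    rounded to the full hour before testing; sets with fewer than ``min_set``
    diurnal members are excluded before BH correction. Rows are flagged
    significant at ``q < q_threshold``.
    """
    if not (0 < q_threshold < 1):
        raise ValueError("q_threshold must lie in (0, 1)")
    phases = {str(g): float(p) for g, p in phase_table.items()}
    rows = []
    for name, members in collections:
        ph = [phases[g] for g in members if g in phases]
        if len(ph) < min_set:
            continue
        rounded = np.mod(np.round(ph), period)
        V, p = kuiper_uniform_test(rounded, period=period,
                                   monte_carlo=monte_carlo, rng=rng)
        rows.append({"set_name": name, "n_diurnal_members": len(ph),
                     "kuiper_V": V, "p": p})
    out = pd.DataFrame(rows, columns=["set_name", "n_diurnal_members", "kuiper_V", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["significant"] = out["q"] < q_threshold
    else:
        out["q"] = np.nan
        out["significant"] = pd.Series(dtype=bool)
    return out.sort_values(["q", "p"], kind="stable").reset_index(drop=True)
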