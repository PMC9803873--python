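"""Per-gene cosinor (harmonic) regression against internal time.

The population rhythm of a gene is modelled as

    y(t) = m + a*cos(omega*t) + b*sin(omega*t),   omega = 2*pi/period

fit by ordinary least squares over all samples of one layer pooled across
subjects. Rhythmicity is the F test of H0: a = b = 0 with (2, n-3) degrees of
freedom; non-uniform time points (the chronotype correction de-synchronises
the sampling grid across subjects) are handled naturally by the regression.

Amplitude is A = sqrt(a^2 + b^2) — half the peak-to-trough swing on the log2
scale, so peak-to-trough fold change = 2^(2A). The acrophase is the peak time
(atan2(b, a)/omega) mod period, reported in hours after MSF_sc when internal
time is the regressor.

An optional empirical-Bayes moderation of residual variances (shrinkage of
per-gene variances toward a pooled prior, moment-matched on the log scale) is
available for matrix-wide scans; the unmoderated test follows the exact F
distribution and is the default for single fits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io_metadata import SampleRecord

DEFAULT_PERIOD = 24.0


@dataclass(frozen=True)
class CosinorFit:
    """Rhythm parameters and test results of one gene in one layer."""

    gene_id: str
    layer: str
    mesor_m: float
    coef_a: float
    coef_b: float
    amplitude_A: float
    acrophase_h: float
    resid_var: float
    p_rhythm: float
    q_rhythm: float | None
    n_obs: int


def harmonic_design(times: np.ndarray, period: float = DEFAULT_PERIOD) -> np.ndarray:
    """n x 3 design matrix [1, cos(omega*t), sin(omega*t)]."""
    t = np.asarray(times, dtype=float)
    w = 2.0 * np.pi / period
    return np.column_stack([np.ones(t.shape[0]), np.cos(w * t), np.sin(w * t)])


def acrophase_from_coefs(a, b, period: float = DEFAULT_PERIOD):
    """Peak time (hours in [0, period)) of m + a*cos(omega t) + b*sin(omega t)."""
    w = 2.0 * np.pi / period
    out = np.mod(np.arctan2(b, a) / w, period)
    # float wrap can land exactly on the period; [0, period) is the contract
    out = np.where(np.isclose(out, period), 0.0, out)
    return float(out) if np.ndim(a) == 0 and np.ndim(b) == 0 else out


def amplitude_to_fold_change(amplitude_A):
    """Peak-to-trough fold change 2^(2A) of a log2-scale cosinor amplitude."""
    A = np.asarray(amplitude_A, dtype=float)
    if np.any(A < 0):
        raise ValueError("amplitude must be non-negative")
    out = 2.0 ** (2.0 * A)
    return float(out) if np.isscalar(amplitude_A) else out


def fold_change_to_amplitude(fold_change):
    """Inverse of :func:`amplitude_to_fold_change`: A = log2(FC)/2."""
    fc = np.asarray(fold_change, dtype=float)
    if np.any(fc < 1):
        raise ValueError("peak-to-trough fold change must be >= 1")
    out = np.log2(fc) / 2.0
    return float(out) if np.isscalar(fold_change) else out


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values.

    q_(i) = min_{j>=i} p_(j) * m / j after sorting; monotone in p and >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _check_times(times: np.ndarray, period: float) -> None:
    if np.unique(np.asarray(times, float)).size < 4:
        raise ValueError("cosinor fit needs at least 4 distinct time points")
    tm = np.mod(np.asarray(times, float), period)
    if np.unique(np.round(tm, 9)).size < 3:
        raise ValueError("design is rank deficient: all times coincide mod period")


def fit_cosinor(
    values: Sequence[float],
    times: Sequence[float],
    period: float = DEFAULT_PERIOD,
    gene_id: str = "",
    layer: str = "dermis",
) -> CosinorFit:
    """OLS cosinor fit of one gene with the exact (2, n-3) rhythm F test."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    if y.shape != t.shape:
        raise ValueError("values and times must have equal length")
    _check_times(t, period)
    X = harmonic_design(t, period)
    n = y.size
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < 3:
        raise ValueError("design is rank deficient")
    resid = y - X @ beta
    rss = float(resid @ resid)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    df_resid = n - 3
    s2 = rss / df_resid
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss) / 2.0) / s2 if s2 > 0 else np.inf
    p = float(stats.f.sf(f, 2, df_resid)) if np.isfinite(f) else 0.0
    m, a, b = beta
    return CosinorFit(
        gene_id=gene_id,
        layer=layer,
        mesor_m=float(m),
        coef_a=float(a),
        coef_b=float(b),
        amplitude_A=float(np.hypot(a, b)),
        acrophase_h=float(acrophase_from_coefs(a, b, period)),
        resid_var=s2,
        p_rhythm=p,
        q_rhythm=None,
        n_obs=n,
    )


# ---------------------------------------------------------------------------
# Empirical-Bayes residual-variance moderation
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    # Newton solve of trigamma(x) = y; monotone decreasing, so well behaved.
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float]:
    """Shrink per-gene residual variances toward a pooled prior.

    Models s2 ~ scaled F around a prior variance s0^2 with d0 prior degrees of
    freedom; (d0, s0^2) are moment-matched on log(s2) via digamma/trigamma.
    Returns the posterior variances (d0*s0^2 + df*s2)/(d0 + df) and d0
    (``inf`` collapses every gene to the common variance).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        return s2.copy(), 0.0
    z = np.log(s2[pos])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    ebar = e.mean()
    evar = e.var(ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        d0 = np.inf
        s02 = float(np.exp(ebar))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = float(np.exp(ebar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    if np.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, float(d0)


# ---------------------------------------------------------------------------
# Matrix-wide scan
# ---------------------------------------------------------------------------

def _ols_scan(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised OLS of every row of Y on X. Returns (coefs, rss)."""
    XtX = X.T @ X
    coefs = np.linalg.solve(XtX, X.T @ Y.T).T  # genes x p
    fitted = coefs @ X.T
    resid = Y - fitted
    return coefs, np.sum(resid * resid, axis=1)


def layerwise_rhythm_scan(
    matrix: pd.DataFrame,
    records: Sequence[SampleRecord],
    layer: str,
    period: float = DEFAULT_PERIOD,
    moderate: bool = False,
) -> pd.DataFrame:
    """Population cosinor scan of every gene in one layer.

    All samples of the layer are pooled across subjects (the population
    rhythm); q-values are BH-corrected across the genes of the scan. Output is
    a tidy table with one row per gene.
    """
    recs = [r for r in records if r.layer == layer]
    if not recs:
        raise ValueError(f"no samples with layer {layer!r} in metadata")
    if any(r.internal_time_h is None for r in recs):
        raise ValueError("records lack internal_time_h; run to_internal_time first")
    cols = [r.sample_id for r in recs]
    missing = [c for c in cols if c not in matrix.columns]
    if missing:
        raise ValueError(f"samples missing from matrix: {missing[:5]}")
    if matrix.shape[0] == 0:
        return pd.DataFrame(
            columns=["gene_id", "layer", "mesor", "a", "b", "amplitude",
                     "fold_change", "acrophase_h", "p", "q", "n"]
        )
    t = np.array([r.internal_time_h for r in recs], dtype=float)
    _check_times(t, period)
    Y = matrix[cols].to_numpy(dtype=float)
    X = harmonic_design(t, period)
    n = t.size
    coefs, rss = _ols_scan(Y, X)
    rss0 = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    df_resid = n - 3
    s2 = rss / df_resid
    if moderate:
        s2_post, d0 = squeeze_variances(s2, df_resid)
        df2 = df_resid + d0 if np.isfinite(d0) else 1e9
        denom = s2_post
    else:
        df2 = df_resid
        denom = s2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss0 - rss) / 2.0) / denom
    f = np.where(denom > 0, f, np.inf)
    p = stats.f.sf(f, 2, df2)
    p = np.where(np.isfinite(f), p, 0.0)
    a, b = coefs[:, 1], coefs[:, 2]
    amp = np.hypot(a, b)
    out = pd.DataFrame(
        {
            "gene_id": matrix.index.astype(str),
            "layer": layer,
            "mesor": coefs[:, 0],
            "a": a,
            "b": b,
            "amplitude": amp,
            "fold_change": amplitude_to_fold_change(amp),
            "acrophase_h": acrophase_from_coefs(a, b, period),
            "p": p,
            "q": bh_fdr(p),
            "n": n,
        }
    )
    return out.reset_index(drop=True)
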