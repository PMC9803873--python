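"""Differential rhythmicity between the two skin layers.

Each gene is fit jointly over both layers with layer-specific intercept and
harmonic terms (6 coefficients), which is algebraically identical to two
independent per-layer cosinor fits. Two nested F tests follow:

* any-rhythm:    H0: a_d = b_d = a_e = b_e = 0        F(4, n-6)
* differential:  H0: (a_d, b_d) = (a_e, b_e)          F(2, n-6)

Genes pass the rhythmic-in-at-least-one-layer gate when q_any < FDR and the
larger of the two layers' peak-to-trough fold changes exceeds the threshold
(default 1.5, strict). Among gated genes the differential q-value is
BH-corrected within the gated set only. Gated genes whose rhythms are
statistically indistinguishable count as rhythmic in BOTH layers even when one
layer's fold change sits below the threshold (sub-threshold inclusion rule);
distinguishable genes are assigned dermis-only / epidermis-only /
both-differential by their per-layer fold changes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import (
    DEFAULT_PERIOD,
    acrophase_from_coefs,
    amplitude_to_fold_change,
    bh_fdr,
    harmonic_design,
    squeeze_variances,
    _ols_scan,
)
from .io_metadata import LAYERS, SampleRecord

CATEGORIES = (
    "not_rhythmic",
    "dermis_only",
    "epidermis_only",
    "both_differential",
    "both_indistinguishable",
)


@dataclass
class JointFit:
    """Joint two-layer cosinor fit of one gene (6 coefficients)."""

    beta: np.ndarray          # (m_d, a_d, b_d, m_e, a_e, b_e)
    cov: np.ndarray           # 6x6 OLS covariance of beta
    rss: float
    n: int
    period: float
    y: np.ndarray
    times: np.ndarray
    layer_labels: np.ndarray  # 0 = dermis, 1 = epidermis

    @property
    def delta_ab(self) -> np.ndarray:
        """(a_e - a_d, b_e - b_d)."""
        return np.array([self.beta[4] - self.beta[1], self.beta[5] - self.beta[2]])


def _joint_design(times: np.ndarray, is_epi: np.ndarray, period: float) -> np.ndarray:
    H = harmonic_design(times, period)
    X = np.zeros((times.size, 6))
    X[~is_epi, :3] = H[~is_epi]
    X[is_epi, 3:] = H[is_epi]
    return X


def fit_joint_model(
    values: Sequence[float],
    times: Sequence[float],
    layer_labels: Sequence[str],
    period: float = DEFAULT_PERIOD,
) -> JointFit:
    """Single least-squares fit with layer-specific intercept and harmonics.

    Verifies at run time that the joint coefficients coincide with two
    independent per-layer OLS fits (they must, the design is block diagonal).
    """
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    lab = np.asarray([str(l) for l in layer_labels])
    bad = set(lab) - set(LAYERS)
    if bad:
        raise ValueError(f"unknown layer label(s): {sorted(bad)}")
    is_epi = lab == "epidermis"
    if is_epi.all() or (~is_epi).all():
        raise ValueError("both layers must be represented")
    if y.size < 8:
        raise ValueError("joint fit needs at least 8 observations")
    X = _joint_design(t, is_epi, period)
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < 6:
        raise ValueError("joint design is rank deficient")
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    rss = float(resid @ resid)
    s2 = rss / (y.size - 6)
    cov = s2 * np.linalg.inv(XtX)
    # block-diagonal design => joint fit == per-layer OLS; verify
    for mask, sl in ((~is_epi, slice(0, 3)), (is_epi, slice(3, 6))):
        bl = np.linalg.lstsq(harmonic_design(t[mask], period), y[mask], rcond=None)[0]
        if not np.allclose(bl, beta[sl], atol=1e-8, rtol=1e-8):
            raise AssertionError("joint fit diverged from per-layer OLS")
    return JointFit(beta=beta, cov=cov, rss=rss, n=y.size, period=period,
                    y=y, times=t, layer_labels=is_epi.astype(int))


def _f_test(rss_restricted: float, rss_full: float, df_num: int, df_den: int) -> float:
    if df_den <= 0:
        raise ValueError("insufficient residual degrees of freedom")
    s2 = rss_full / df_den
    if s2 <= 0:
        return 0.0
    f = ((rss_restricted - rss_full) / df_num) / s2
    return float(stats.f.sf(f, df_num, df_den))


def test_any_rhythm(fit: JointFit) -> float:
    """F test of H0: all four layer harmonic coefficients are zero."""
    is_epi = fit.layer_labels.astype(bool)
    Xr = np.column_stack([(~is_epi).astype(float), is_epi.astype(float)])
    br = np.linalg.lstsq(Xr, fit.y, rcond=None)[0]
    rss_r = float(np.sum((fit.y - Xr @ br) ** 2))
    return _f_test(rss_r, fit.rss, 4, fit.n - 6)


def test_differential(fit: JointFit) -> float:
    """F test of H0: the sine and cosine terms are equal across layers."""
    is_epi = fit.layer_labels.astype(bool)
    H = harmonic_design(fit.times, fit.period)
    Xr = np.column_stack([(~is_epi).astype(float), is_epi.astype(float), H[:, 1], H[:, 2]])
    br = np.linalg.lstsq(Xr, fit.y, rcond=None)[0]
    rss_r = float(np.sum((fit.y - Xr @ br) ** 2))
    return _f_test(rss_r, fit.rss, 2, fit.n - 6)


# ---------------------------------------------------------------------------
# Matrix-wide scan and categorisation
# ---------------------------------------------------------------------------

def differential_scan(
    matrix: pd.DataFrame,
    records: Sequence[SampleRecord],
    period: float = DEFAULT_PERIOD,
    moderate: bool = False,
) -> pd.DataFrame:
    """Joint two-layer fits and both F tests for every gene (vectorised).

    Returns per-layer rhythm parameters, ``p_any`` and ``p_diff`` per gene;
    q-values and categories are added by :func:`categorize`.
    """
    recs = [r for r in records if r.layer in LAYERS]
    if any(r.internal_time_h is None for r in recs):
        raise ValueError("records lack internal_time_h; run to_internal_time first")
    cols = [r.sample_id for r in recs]
    t = np.array([r.internal_time_h for r in recs], dtype=float)
    is_epi = np.array([r.layer == "epidermis" for r in recs])
    if is_epi.all() or (~is_epi).all():
        raise ValueError("both layers must be present in the metadata")
    Y = matrix[cols].to_numpy(dtype=float)
    n = t.size
    if n - 6 <= 0:
        raise ValueError("insufficient residual degrees of freedom")

    # full model decomposes into per-layer OLS
    out: dict[str, np.ndarray] = {}
    rss_full = np.zeros(Y.shape[0])
    for name, mask in (("dermis", ~is_epi), ("epidermis", is_epi)):
        Xl = harmonic_design(t[mask], period)
        coefs, rss = _ols_scan(Y[:, mask], Xl)
        rss_full += rss
        a, b = coefs[:, 1], coefs[:, 2]
        amp = np.hypot(a, b)
        suffix = "_d" if name == "dermis" else "_e"
        out["m" + suffix] = coefs[:, 0]
        out["a" + suffix] = a
        out["b" + suffix] = b
        out["amplitude" + suffix] = amp
        out["fold_change" + suffix] = amplitude_to_fold_change(amp)
        out["acrophase_h" + suffix] = acrophase_from_coefs(a, b, period)

    # restricted: per-layer intercepts only (any-rhythm null)
    X_any = np.column_stack([(~is_epi).astype(float), is_epi.astype(float)])
    _, rss_any = _ols_scan(Y, X_any)
    # restricted: shared harmonics, per-layer intercepts (differential null)
    H = harmonic_design(t, period)
    X_diff = np.column_stack([X_any, H[:, 1], H[:, 2]])
    _, rss_diff = _ols_scan(Y, X_diff)

    df_den = n - 6
    s2 = rss_full / df_den
    if moderate:
        s2_post, d0 = squeeze_variances(s2, df_den)
        df2 = df_den + d0 if np.isfinite(d0) else 1e9
        denom = s2_post
    else:
        df2 = df_den
        denom = s2
    with np.errstate(divide="ignore", invalid="ignore"):
        f_any = ((rss_any - rss_full) / 4.0) / denom
        f_diff = ((rss_diff - rss_full) / 2.0) / denom
    p_any = np.where(denom > 0, stats.f.sf(f_any, 4, df2), 0.0)
    p_diff = np.where(denom > 0, stats.f.sf(f_diff, 2, df2), 1.0)

    df = pd.DataFrame({"gene_id": matrix.index.astype(str), **out})
    df["delta_a"] = df["a_e"] - df["a_d"]
    df["delta_b"] = df["b_e"] - df["b_d"]
    df["p_any"] = p_any
    df["p_diff"] = p_diff
    df["n"] = n
    return df.reset_index(drop=True)


def categorize(
    scan: pd.DataFrame, fdr: float = 0.05, fc_threshold: float = 1.5
) -> pd.DataFrame:
    """Assign each gene to one of the five rhythmicity categories.

    Gate: q_any < fdr AND max-layer fold change > fc_threshold (strict).
    q_diff is BH-corrected within the gated set. Gated, indistinguishable
    genes are ``both_indistinguishable`` regardless of the weaker layer's fold
    change; distinguishable genes go by per-layer fold change.
    """
    if not (0 < fdr < 1):
        raise ValueError("fdr must lie in (0, 1)")
    if not fc_threshold > 1:
        raise ValueError("fc_threshold must exceed 1")
    df = scan.copy()
    df["q_any"] = bh_fdr(df["p_any"].to_numpy())
    gate = (df["q_any"] < fdr) & (
        np.maximum(df["fold_change_d"], df["fold_change_e"]) > fc_threshold
    )
    q_diff = np.full(len(df), np.nan)
    if gate.any():
        q_diff[gate.to_numpy()] = bh_fdr(df.loc[gate, "p_diff"].to_numpy())
    df["q_diff"] = q_diff

    cat = np.full(len(df), "not_rhythmic", dtype=object)
    gated = gate.to_numpy()
    indist = gated & (q_diff >= fdr)
    diff = gated & (q_diff < fdr)
    d_above = (df["fold_change_d"] > fc_threshold).to_numpy()
    e_above = (df["fold_change_e"] > fc_threshold).to_numpy()
    cat[indist] = "both_indistinguishable"
    cat[diff & d_above & e_above] = "both_differential"
    cat[diff & d_above & ~e_above] = "dermis_only"
    cat[diff & ~d_above & e_above] = "epidermis_only"
    df["category"] = cat
    return df


def rhythmic_gene_ids(categorized: pd.DataFrame) -> list[str]:
    """Genes rhythmic in at least one layer (everything past the gate)."""
    mask = categorized["category"] != "not_rhythmic"
    return categorized.loc[mask, "gene_id"].tolist()


# ---------------------------------------------------------------------------
# Circular phase statistics
# ---------------------------------------------------------------------------

def wrap_phase_difference(delta_h, period: float = DEFAULT_PERIOD):
    """Map hour differences onto (-period/2, period/2]."""
    d = np.asarray(delta_h, dtype=float)
    out = period / 2.0 - np.mod(period / 2.0 - d, period)
    return float(out) if np.isscalar(delta_h) else out


def rayleigh_p(R: float, n: int) -> float:
    """Rayleigh uniformity p for mean resultant length R of n angles."""
    Z = n * R * R
    p = np.exp(-Z) * (
        1.0
        + (2.0 * Z - Z * Z) / (4.0 * n)
        - (24.0 * Z - 132.0 * Z**2 + 76.0 * Z**3 - 9.0 * Z**4) / (288.0 * n * n)
    )
    return float(min(max(p, 0.0), 1.0))


def circular_phase_stats(
    phases_layer1: Sequence[float],
    phases_layer2: Sequence[float],
    period: float = DEFAULT_PERIOD,
) -> tuple[float, float, float]:
    """Circular summary of paired acrophase differences.

    Returns ``(mean_difference_h, rayleigh_R, rayleigh_p)`` where the mean
    difference is the circular mean of layer1 - layer2 wrapped to
    (-period/2, period/2] and R is the mean resultant length of the
    difference angles.
    """
    p1 = np.asarray(phases_layer1, dtype=float)
    p2 = np.asarray(phases_layer2, dtype=float)
    if p1.shape != p2.shape:
        raise ValueError("phase lists must have equal length")
    if p1.size == 0:
        raise ValueError("phase lists must be non-empty")
    d = wrap_phase_difference(p1 - p2, period)
    theta = 2.0 * np.pi * d / period
    C, S = np.cos(theta).mean(), np.sin(theta).mean()
    R = float(np.hypot(C, S))
    mean_h = wrap_phase_difference(np.arctan2(S, C) * period / (2.0 * np.pi), period)
    return float(mean_h), R, rayleigh_p(R, p1.size)
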