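"""Per-gene linear mixed models and error propagation of rhythm variability.

Model (one gene, observations across subjects, layers and times):

    y = (m + dm_subj + dm_layer)
        + (a + da_subj + da_layer) * cos(omega t)
        + (b + db_subj + db_layer) * sin(omega t) + eps

with crossed random effects: one (dm, da, db) vector per subject drawn from an
unrestricted 3x3 covariance Sigma_subj, one per layer drawn from a diagonal
3x3 covariance Sigma_layer (diagonal keeps the two-level layer factor
estimable), and iid Gaussian residuals. Estimation is maximum likelihood with
fixed effects profiled out by GLS; Sigma_subj is log-Cholesky parameterised
and Sigma_layer/residual variances are log-parameterised, so boundary
solutions appear as variances driven to (numerically) zero.

Amplitude A = sqrt(a^2 + b^2) and phase phi = atan2(b, a) are nonlinear in the
coefficients, so their between-subject / between-layer standard deviations are
obtained by first-order (delta-method) propagation:

    sigma_A^2   = J_A  Sigma J_A^T,   J_A   = (0,  a/A,    b/A)
    sigma_phi^2 = J_phi Sigma J_phi^T, J_phi = (0, -b/A^2,  a/A^2)   [radians]

with phase SD reported in hours via period/(2*pi). The linearisation is
trustworthy while the propagated SDs are small relative to A (amplitude) and
to the period (phase); a per-gene validity flag is emitted.

The fraction of a rhythm parameter's variance explained by subject is
sigma^2_subj / (sigma^2_subj + sigma^2_layer).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .cosinor import DEFAULT_PERIOD, acrophase_from_coefs, harmonic_design
from .io_metadata import LAYERS, SampleRecord

logger = logging.getLogger("skinrhythm")

_LOG_SD_MIN, _LOG_SD_MAX = -12.0, 4.0
PHASE_SD_LINEAR_BOUND_H = 2.0  # delta-method trust region for phase SD


@dataclass
class MixedFit:
    """ML fit of the crossed random-effects cosinor model for one gene."""

    gene_id: str
    fixed: np.ndarray            # (m, a, b)
    sigma_subj: np.ndarray       # 3x3 PSD
    sigma_layer: np.ndarray | None  # diagonal 3x3, or None (single layer)
    resid_var: float
    loglik: float
    converged: bool
    grad_norm: float
    n_obs: int

    @property
    def amplitude(self) -> float:
        return float(np.hypot(self.fixed[1], self.fixed[2]))

    @property
    def acrophase_h(self) -> float:
        return float(acrophase_from_coefs(self.fixed[1], self.fixed[2]))


# ---------------------------------------------------------------------------
# Profiled marginal likelihood via the Woodbury identity
# ---------------------------------------------------------------------------

class _LMMProblem:
    """Precomputed cross-products for fast likelihood evaluation.

    V = s2 * (I + Z Gt Z') with Gt the residual-scaled random-effect
    covariance, block diagonal (subject blocks share the full scaled
    Sigma_subj; layer blocks are diagonal). The residual variance is profiled
    out analytically (s2_hat = GLS quadratic form / n), so the optimiser only
    sees the variance ratios. All terms reduce to q x q algebra via
    (I + Z Gt Z')^-1 = I - Z W^-1 Z' with W = Gt^-1 + Z'Z and
    log|I + Z Gt Z'| = log|Gt| + log|W|.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, subj_codes: np.ndarray,
                 layer_codes: np.ndarray | None):
        self.n = y.size
        self.n_subj = int(subj_codes.max()) + 1
        self.with_layer = layer_codes is not None
        self.n_layer = int(layer_codes.max()) + 1 if self.with_layer else 0
        q = 3 * self.n_subj + 3 * self.n_layer
        Z = np.zeros((self.n, q))
        rows = np.arange(self.n)
        for j in range(3):
            Z[rows, 3 * subj_codes + j] = X[:, j]
        if self.with_layer:
            off = 3 * self.n_subj
            for j in range(3):
                Z[rows, off + 3 * layer_codes + j] = X[:, j]
        self.q = q
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n_par = 6 + (3 if self.with_layer else 0)
        # index template of the subject blocks within Ginv
        self._subj_rows = np.arange(3 * self.n_subj).reshape(self.n_subj, 3)

    # parameter layout: [l11, l21, l22, l31, l32, l33] (Cholesky of the
    # residual-scaled subject covariance, diagonals on log scale), then 3 log
    # layer SD ratios (if layers are present).
    def unpack(self, theta: np.ndarray):
        L = np.zeros((3, 3))
        L[0, 0] = np.exp(theta[0])
        L[1, 0] = theta[1]
        L[1, 1] = np.exp(theta[2])
        L[2, 0] = theta[3]
        L[2, 1] = theta[4]
        L[2, 2] = np.exp(theta[5])
        layer_var = np.exp(2.0 * theta[6:9]) if self.with_layer else None
        return L, layer_var

    def nll(self, theta: np.ndarray) -> float:
        val, _, _ = self._nll_full(theta)
        return val

    def _nll_full(self, theta: np.ndarray):
        L, layer_var = self.unpack(theta)
        Linv = np.linalg.inv(L)
        subj_inv = Linv.T @ Linv
        logdet_G = 2.0 * self.n_subj * float(np.sum(np.log(np.diag(L))))
        Ginv = np.zeros((self.q, self.q))
        for block in self._subj_rows:
            Ginv[np.ix_(block, block)] = subj_inv
        if self.with_layer:
            off = 3 * self.n_subj
            idx = np.arange(off, self.q)
            Ginv[idx, idx] = np.tile(1.0 / layer_var, self.n_layer)
            logdet_G += self.n_layer * float(np.sum(np.log(layer_var)))
        W = Ginv + self.ZtZ
        try:
            cW = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return 1e12, None, None
        logdet_W = 2.0 * float(np.sum(np.log(np.diag(cW))))

        u = np.linalg.solve(cW, np.column_stack([self.ZtX, self.Zty]))
        ux, uy = u[:, :3], u[:, 3]
        XVX = self.XtX - ux.T @ ux
        XVy = self.Xty - ux.T @ uy
        yVy = self.yty - float(uy @ uy)
        try:
            beta = np.linalg.solve(XVX, XVy)
        except np.linalg.LinAlgError:
            return 1e12, None, None
        quad = yVy - float(beta @ XVy)
        if quad <= 0:
            quad = 1e-300
        s2 = quad / self.n
        nll = 0.5 * (self.n * np.log(2.0 * np.pi * s2) + logdet_G + logdet_W
                     + self.n)
        if not np.isfinite(nll):
            return 1e12, None, None
        return float(nll), beta, s2


def _starts(with_layer: bool) -> list[np.ndarray]:
    # deterministic restarts in variance-ratio space (SD relative to residual)
    starts = []
    for ratio in (0.6, 0.05, 2.0):
        t = [np.log(ratio), 0.0, np.log(ratio), 0.0, 0.0, np.log(ratio)]
        if with_layer:
            t += [np.log(ratio)] * 3
        starts.append(np.clip(np.array(t), _LOG_SD_MIN + 1e-9, _LOG_SD_MAX - 1e-9))
    return starts


def _fit(problem: _LMMProblem, y: np.ndarray, X: np.ndarray, gene_id: str) -> MixedFit:
    bounds = []
    for i in range(problem.n_par):
        if i in (1, 3, 4):  # off-diagonal Cholesky entries: unconstrained sign
            bounds.append((-20.0, 20.0))
        else:
            bounds.append((_LOG_SD_MIN, _LOG_SD_MAX))

    results = []
    for x0 in _starts(problem.with_layer):
        res = optimize.minimize(
            problem.nll, x0, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-6},
        )
        results.append(res)
    best = min(results, key=lambda r: r.fun)
    nll, beta, s2 = problem._nll_full(best.x)
    L, layer_ratio = problem.unpack(best.x)
    sigma_subj = s2 * (L @ L.T)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    # a restart that ends clean at (numerically) the same optimum vouches for
    # a boundary fit whose own line search tripped
    tol = 1e-6 * (1.0 + abs(best.fun))
    converged = np.isfinite(nll) and any(
        r.success and r.fun <= best.fun + tol for r in results)
    if not converged:
        logger.warning("LMM fit for gene %s flagged non-converged (%s)",
                       gene_id, best.message)
    return MixedFit(
        gene_id=gene_id,
        fixed=np.asarray(beta, dtype=float),
        sigma_subj=sigma_subj,
        sigma_layer=np.diag(s2 * layer_ratio) if layer_ratio is not None else None,
        resid_var=float(s2),
        loglik=-nll,
        converged=converged,
        grad_norm=grad_norm,
        n_obs=problem.n,
    )


def _codes(labels: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    uniq = sorted(set(str(x) for x in labels))
    lookup = {u: i for i, u in enumerate(uniq)}
    return np.array([lookup[str(x)] for x in labels]), uniq


def fit_gene_lmm(
    values: Sequence[float],
    times: Sequence[float],
    subject_ids: Sequence[str],
    layer_labels: Sequence[str],
    period: float = DEFAULT_PERIOD,
    gene_id: str = "",
) -> MixedFit:
    """ML fit of the crossed subject x layer random-effects cosinor model."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    subj, subj_names = _codes(subject_ids)
    lay, lay_names = _codes(layer_labels)
    if len(subj_names) < 2:
        raise ValueError("need >= 2 subjects (use fit_gene_lmm_single_layer "
                         "for one layer / subject-only decomposition)")
    if len(lay_names) != 2:
        raise ValueError("need exactly 2 layers; got " + repr(lay_names))
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct time points")
    X = harmonic_design(t, period)
    problem = _LMMProblem(y, X, subj, lay)
    return _fit(problem, y, X, gene_id)


def fit_gene_lmm_single_layer(
    values: Sequence[float],
    times: Sequence[float],
    subject_ids: Sequence[str],
    period: float = DEFAULT_PERIOD,
    gene_id: str = "",
) -> MixedFit:
    """Subject-only random-effects model (one layer at a time)."""
    y = np.asarray(values, dtype=float)
    t = np.asarray(times, dtype=float)
    subj, subj_names = _codes(subject_ids)
    if len(subj_names) < 2:
        raise ValueError("need >= 2 subjects")
    if np.unique(t).size < 4:
        raise ValueError("need >= 4 distinct time points")
    X = harmonic_design(t, period)
    problem = _LMMProblem(y, X, subj, None)
    return _fit(problem, y, X, gene_id)


def ols_loglik(values: Sequence[float], times: Sequence[float],
               period: float = DEFAULT_PERIOD) -> float:
    """Gaussian ML log-likelihood of the zero-random-effects cosinor model."""
    y = np.asarray(values, dtype=float)
    X = harmonic_design(np.asarray(times, dtype=float), period)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    s2 = float(np.mean((y - X @ beta) ** 2))
    n = y.size
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


# ---------------------------------------------------------------------------
# Delta-method propagation
# ---------------------------------------------------------------------------

def _check_cov(cov: np.ndarray) -> np.ndarray:
    cov = np.asarray(cov, dtype=float)
    if cov.shape != (3, 3):
        raise ValueError("covariance must be 3x3 over (m, a, b)")
    return cov


def propagate_amplitude_sd(fixed: Sequence[float], cov: np.ndarray) -> float:
    """Between-source SD of amplitude A = sqrt(a^2+b^2) by the delta method."""
    m, a, b = np.asarray(fixed, dtype=float)
    cov = _check_cov(cov)
    A = float(np.hypot(a, b))
    if A <= 0:
        raise ValueError("amplitude is zero; the amplitude Jacobian is undefined")
    J = np.array([0.0, a / A, b / A])
    return float(np.sqrt(max(J @ cov @ J, 0.0)))


def propagate_phase_sd(fixed: Sequence[float], cov: np.ndarray,
                       period: float = DEFAULT_PERIOD) -> float:
    """Between-source SD of the acrophase in hours by the delta method."""
    m, a, b = np.asarray(fixed, dtype=float)
    cov = _check_cov(cov)
    A = float(np.hypot(a, b))
    if A <= 0:
        raise ValueError("amplitude is zero; the phase Jacobian is undefined")
    J = np.array([0.0, -b / (A * A), a / (A * A)])  # radians
    sd_rad = float(np.sqrt(max(J @ cov @ J, 0.0)))
    return sd_rad * period / (2.0 * np.pi)


def variance_fraction(var_subj: float, var_layer: float) -> float:
    """Fraction of variance explained by subject: vs / (vs + vl)."""
    if var_subj < 0 or var_layer < 0:
        raise ValueError("variances must be non-negative")
    total = var_subj + var_layer
    if total == 0:
        raise ValueError("both variances are zero; the fraction is undefined")
    return float(var_subj / total)


# ---------------------------------------------------------------------------
# Gene-list table
# ---------------------------------------------------------------------------

def variability_table(
    matrix: pd.DataFrame,
    records: Sequence[SampleRecord],
    gene_list: Sequence[str],
    period: float = DEFAULT_PERIOD,
    phase_cv_mode: str = "period",
) -> pd.DataFrame:
    """Mixed-model variability decomposition for a list of genes.

    One row per gene: fixed effects, per-source (subject/layer) SDs of
    magnitude, amplitude and phase, amplitude CV (sigma_A / A), relative phase
    variability and the subject variance fractions. ``phase_cv_mode`` selects
    the normaliser of the relative phase column: ``"period"`` (default,
    sigma_phi / period) or ``"phase"`` (sigma_phi / phi, ill-defined near
    phi = 0 and kept only as an alternative convention).
    """
    if phase_cv_mode not in ("period", "phase"):
        raise ValueError("phase_cv_mode must be 'period' or 'phase'")
    missing = [g for g in gene_list if g not in matrix.index]
    if missing:
        raise ValueError(f"gene(s) not in matrix: {missing[:5]}")
    recs = [r for r in records if r.layer in LAYERS]
    if any(r.internal_time_h is None for r in recs):
        raise ValueError("records lack internal_time_h; run to_internal_time first")
    cols = [r.sample_id for r in recs]
    t = np.array([r.internal_time_h for r in recs], dtype=float)
    subj = [r.subject_id for r in recs]
    lay = [r.layer for r in recs]

    rows = []
    for g in gene_list:
        y = matrix.loc[g, cols].to_numpy(dtype=float)
        fit = fit_gene_lmm(y, t, subj, lay, period=period, gene_id=g)
        m, a, b = fit.fixed
        A = fit.amplitude
        row: dict[str, object] = {
            "gene_id": g, "m": m, "a": a, "b": b,
            "amplitude": A, "acrophase_h": fit.acrophase_h,
            "resid_var": fit.resid_var, "converged": fit.converged,
        }
        for src, cov in (("subj", fit.sigma_subj), ("layer", fit.sigma_layer)):
            row[f"sd_m_{src}"] = float(np.sqrt(cov[0, 0]))
            try:
                sd_A = propagate_amplitude_sd(fit.fixed, cov)
                sd_ph = propagate_phase_sd(fit.fixed, cov, period)
            except ValueError:
                sd_A = np.nan
                sd_ph = np.nan
            row[f"sd_A_{src}"] = sd_A
            row[f"sd_phase_{src}"] = sd_ph
            row[f"cv_A_{src}"] = sd_A / A if A > 0 else np.nan
            if phase_cv_mode == "period":
                row[f"rel_phase_{src}"] = sd_ph / period
            else:
                phi = fit.acrophase_h
                row[f"rel_phase_{src}"] = sd_ph / phi if phi > 0 else np.nan
        for name, i in (("f_m", 0),):
            vs = fit.sigma_subj[i, i]
            vl = fit.sigma_layer[i, i]
            row[name] = variance_fraction(vs, vl) if vs + vl > 0 else np.nan
        for name, key in (("f_A", "sd_A"), ("f_phase", "sd_phase")):
            vs = row[f"{key}_subj"] ** 2
            vl = row[f"{key}_layer"] ** 2
            row[name] = (variance_fraction(vs, vl)
                         if np.isfinite(vs) and np.isfinite(vl) and vs + vl > 0
                         else np.nan)
        row["phase_sd_linear_ok"] = bool(
            np.nan_to_num(row["sd_phase_subj"], nan=0.0) < PHASE_SD_LINEAR_BOUND_H
            and np.nan_to_num(row["sd_phase_layer"], nan=0.0) < PHASE_SD_LINEAR_BOUND_H
        )
        rows.append(row)
    return pd.DataFrame(rows)
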