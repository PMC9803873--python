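"""Single-sample internal-time prediction from sparse gene-expression components.

The predictor follows the sparse-principal-component time-telling recipe:

1. centre/scale each gene over the training samples;
2. fit a smooth periodic mean curve per gene (harmonic basis of order
   n_knots-1 by default, periodic cubic B-splines optional) against internal
   time modulo the period;
3. extract sparse principal components (SPCs) of the row-centred curve matrix
   by rank-1 penalised matrix decomposition — each loading column v solves
   max u'Xv s.t. ||u||2 <= 1, ||v||2 <= 1, ||v||1 <= sumabsv via alternating
   soft-thresholded power iterations, deflating after each component;
4. fit a periodic mean curve plus a constant Gaussian variance to each SPC
   score over training time;
5. predict a new sample's time by maximising the Gaussian log-likelihood of
   its observed SPC scores over a 0.1-h grid (ties -> earliest grid time).

Accuracy is evaluated by leave-one-subject-out cross-validation over a
(sumabsv, nSPC) grid, scoring the median circular absolute error (MAE) in
hours; the circular error never exceeds period/2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .cosinor import DEFAULT_PERIOD
from .io_metadata import SampleRecord

DEFAULT_SUMABSV_GRID = (1.0, 1.5, 2.0, 3.0)
DEFAULT_NSPC_GRID = (2, 3)
PREDICTION_GRID_H = 0.1


# ---------------------------------------------------------------------------
# Periodic basis and per-gene mean curves
# ---------------------------------------------------------------------------

def periodic_design(times, period: float = DEFAULT_PERIOD, n_knots: int = 3,
                    basis: str = "harmonic") -> np.ndarray:
    """Design matrix of a periodic basis evaluated at ``times`` (hours).

    ``harmonic``: [1, cos, sin, ..., cos k, sin k] with k = n_knots - 1
    (2*n_knots - 1 columns). ``spline``: periodic cubic B-splines with
    2*n_knots - 1 basis functions (same dimension).
    """
    t = np.mod(np.asarray(times, dtype=float), period)
    p = 2 * n_knots - 1
    if basis == "harmonic":
        w = 2.0 * np.pi / period
        cols = [np.ones(t.size)]
        for k in range(1, n_knots):
            cols += [np.cos(k * w * t), np.sin(k * w * t)]
        return np.column_stack(cols)
    if basis == "spline":
        deg = 3
        knots = np.linspace(0.0, period, p + 1)
        ext = np.concatenate([knots[-deg - 1:-1] - period, knots,
                              knots[1:deg + 1] + period])
        dm = BSpline.design_matrix(t, ext, deg).toarray()  # t x (p + deg)
        dm[:, :deg] += dm[:, -deg:]
        return dm[:, :p]
    raise ValueError("basis must be 'harmonic' or 'spline'")


@dataclass
class PeriodicCurves:
    """Least-squares periodic mean curves of many genes."""

    coefs: np.ndarray  # genes x p
    period: float
    n_knots: int
    basis: str

    def evaluate(self, times) -> np.ndarray:
        """Curve values (genes x len(times))."""
        B = periodic_design(times, self.period, self.n_knots, self.basis)
        return self.coefs @ B.T


def fit_periodic_curves(Y: np.ndarray, times, period: float = DEFAULT_PERIOD,
                        n_knots: int = 3, basis: str = "harmonic") -> PeriodicCurves:
    """Row-wise least squares of a genes x samples matrix on the periodic basis."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    t = np.asarray(times, dtype=float)
    n_distinct = np.unique(np.round(np.mod(t, period), 9)).size
    if n_distinct < 2 * n_knots - 1:
        raise ValueError(
            f"degenerate time support: {n_distinct} distinct times mod period "
            f"for a {2 * n_knots - 1}-dimensional basis")
    B = periodic_design(t, period, n_knots, basis)
    coefs = np.linalg.lstsq(B, Y.T, rcond=None)[0].T
    return PeriodicCurves(coefs=coefs, period=period, n_knots=n_knots, basis=basis)


# ---------------------------------------------------------------------------
# Sparse principal components (penalised matrix decomposition)
# ---------------------------------------------------------------------------

def _soft(x: np.ndarray, d: float) -> np.ndarray:
    return np.sign(x) * np.maximum(np.abs(x) - d, 0.0)


def _l1_constrained_unit(x: np.ndarray, c: float) -> np.ndarray:
    """argmax_v x'v s.t. ||v||2 <= 1, ||v||1 <= c: soft-threshold + renormalise."""
    nx = np.linalg.norm(x)
    if nx == 0:
        return np.zeros_like(x)
    v = x / nx
    if np.abs(v).sum() <= c + 1e-12:
        return v
    lo, hi = 0.0, float(np.max(np.abs(x)))
    for _ in range(80):
        d = 0.5 * (lo + hi)
        s = _soft(x, d)
        ns = np.linalg.norm(s)
        if ns == 0 or np.abs(s / ns).sum() > c:
            lo = d
        else:
            hi = d
    s = _soft(x, hi)
    s[np.abs(s) < 1e-11 * np.max(np.abs(s), initial=1.0)] = 0.0
    ns = np.linalg.norm(s)
    return s / ns if ns > 0 else np.zeros_like(x)


def sparse_pcs(curve_matrix: np.ndarray, sumabsv: float, n_spc: int) -> np.ndarray:
    """Sparse gene loadings (genes x n_spc) of a genes x timegrid curve matrix.

    Rank-1 deflation: each component maximises u' X v over unit-l2 u (time
    direction) and unit-l2, l1-bounded v (gene direction), initialised from
    the leading singular vector (sign fixed so the largest-magnitude entry is
    positive) for determinism.
    """
    if sumabsv < 1:
        raise ValueError("sumabsv must be >= 1 (unit-l2 vectors have l1 >= 1)")
    X = np.asarray(curve_matrix, dtype=float).T  # timegrid x genes
    n_genes = X.shape[1]
    loadings = np.zeros((n_genes, n_spc))
    M = X.copy()
    for comp in range(n_spc):
        if not np.any(M):
            break
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        v = v * np.sign(v[np.argmax(np.abs(v))] or 1.0)
        for _ in range(500):
            Mv = M @ v
            nu = np.linalg.norm(Mv)
            if nu == 0:
                v = np.zeros(n_genes)
                break
            u = Mv / nu
            v_new = _l1_constrained_unit(M.T @ u, sumabsv)
            if np.linalg.norm(v_new - v) < 1e-10:
                v = v_new
                break
            v = v_new
        if np.linalg.norm(v) == 0:
            break
        u = M @ v
        nu = np.linalg.norm(u)
        if nu == 0:
            break
        u = u / nu
        d = float(u @ M @ v)
        loadings[:, comp] = v
        M = M - d * np.outer(u, v)
    return loadings


# ---------------------------------------------------------------------------
# Predictor model
# ---------------------------------------------------------------------------

@dataclass
class TimePredictor:
    """Sparse-loading single-sample internal-time predictor."""

    gene_ids: list[str]
    center: np.ndarray            # per-gene train means
    scale: np.ndarray             # per-gene train SDs (floored)
    loadings: np.ndarray          # genes x nSPC, unit l2, l1 <= sumabsv
    spc_coefs: np.ndarray         # nSPC x p periodic mean-curve coefficients
    spc_var: np.ndarray           # nSPC constant score variances
    period: float
    n_knots: int
    basis: str
    sumabsv: float
    n_spc: int
    informative: bool = True

    @property
    def selected_genes(self) -> list[str]:
        mask = np.any(self.loadings != 0, axis=1)
        return [g for g, m in zip(self.gene_ids, mask) if m]

    def score_curves(self, times) -> np.ndarray:
        """Per-SPC periodic mean scores (nSPC x len(times))."""
        B = periodic_design(times, self.period, self.n_knots, self.basis)
        return self.spc_coefs @ B.T

    def to_json(self, path: str | Path) -> None:
        payload = {
            "gene_ids": self.gene_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "spc_coefs": self.spc_coefs.tolist(),
            "spc_var": self.spc_var.tolist(),
            "period": self.period,
            "n_knots": self.n_knots,
            "basis": self.basis,
            "sumabsv": self.sumabsv,
            "n_spc": self.n_spc,
            "informative": self.informative,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TimePredictor":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_ids=list(d["gene_ids"]),
            center=np.asarray(d["center"], float),
            scale=np.asarray(d["scale"], float),
            loadings=np.asarray(d["loadings"], float),
            spc_coefs=np.asarray(d["spc_coefs"], float),
            spc_var=np.asarray(d["spc_var"], float),
            period=float(d["period"]),
            n_knots=int(d["n_knots"]),
            basis=str(d["basis"]),
            sumabsv=float(d["sumabsv"]),
            n_spc=int(d["n_spc"]),
            informative=bool(d["informative"]),
        )


def train_predictor(
    matrix: pd.DataFrame,
    records: Sequence[SampleRecord],
    sumabsv: float,
    n_spc: int,
    period: float = DEFAULT_PERIOD,
    n_knots: int = 3,
    basis: str = "harmonic",
    curve_grid_size: int = 24,
) -> TimePredictor:
    """Train the sparse-component time predictor on one layer's samples.

    ``records`` must already be restricted to a single layer and carry
    internal times. Flat (uninformative) training data yields a model with
    ``informative=False``.
    """
    recs = list(records)
    if any(r.internal_time_h is None for r in recs):
        raise ValueError("records lack internal_time_h; run to_internal_time first")
    if len(recs) < n_spc + 2:
        raise ValueError(f"need at least nSPC+2 = {n_spc + 2} samples")
    cols = [r.sample_id for r in recs]
    t = np.array([r.internal_time_h for r in recs], dtype=float)
    Y = matrix[cols].to_numpy(dtype=float)

    center = Y.mean(axis=1)
    sd = Y.std(axis=1, ddof=1)
    scale = np.where(sd > 1e-10, sd, 1.0)
    Ys = (Y - center[:, None]) / scale[:, None]

    curves = fit_periodic_curves(Ys, t, period, n_knots, basis)
    grid = np.linspace(0.0, period, curve_grid_size, endpoint=False)
    C = curves.evaluate(grid)
    C = C - C.mean(axis=1, keepdims=True)
    loadings = sparse_pcs(C, sumabsv, n_spc)

    scores = Ys.T @ loadings  # samples x nSPC
    score_curves = fit_periodic_curves(scores.T, t, period, n_knots, basis)
    fitted = score_curves.evaluate(t)  # nSPC x samples
    resid = scores.T - fitted
    dof = max(scores.shape[0] - score_curves.coefs.shape[1], 1)
    spc_var = np.maximum(np.sum(resid * resid, axis=1) / dof, 1e-8)

    curve_span = score_curves.evaluate(grid)
    informative = bool(np.ptp(curve_span, axis=1).max() > 1e-6)

    return TimePredictor(
        gene_ids=[str(g) for g in matrix.index],
        center=center, scale=scale, loadings=loadings,
        spc_coefs=score_curves.coefs, spc_var=spc_var,
        period=period, n_knots=n_knots, basis=basis,
        sumabsv=float(sumabsv), n_spc=int(n_spc), informative=informative,
    )


def predict_time(model: TimePredictor, sample, grid_h: float = PREDICTION_GRID_H) -> float:
    """Maximum-likelihood internal time in [0, period) for one sample.

    ``sample`` is a pandas Series indexed by gene id (must cover the model's
    genes) or an array already aligned to ``model.gene_ids``.
    """
    if isinstance(sample, pd.Series):
        missing = [g for g in model.gene_ids if g not in sample.index]
        if missing:
            raise ValueError(f"sample is missing model gene(s): {missing[:5]}")
        x = sample.loc[model.gene_ids].to_numpy(dtype=float)
    else:
        x = np.asarray(sample, dtype=float)
        if x.size != len(model.gene_ids):
            raise ValueError("sample length does not match model gene list")
    xs = (x - model.center) / model.scale
    s = xs @ model.loadings  # nSPC
    tgrid = np.arange(0.0, model.period, grid_h)
    mu = model.score_curves(tgrid)  # nSPC x T
    ll = -np.sum((s[:, None] - mu) ** 2 / (2.0 * model.spc_var[:, None]), axis=0)
    return float(tgrid[int(np.argmax(ll))])  # argmax -> earliest tie


def circular_error_h(predicted, truth, period: float = DEFAULT_PERIOD):
    """Absolute circular difference in hours, in [0, period/2]."""
    d = np.abs(np.asarray(predicted, float) - np.asarray(truth, float)) % period
    out = np.minimum(d, period - d)
    return float(out) if np.isscalar(predicted) and np.isscalar(truth) else out


@dataclass
class CvResult:
    """Leave-one-subject-out grid search results."""

    table: pd.DataFrame                       # sumabsv, n_spc, mae_h, n_genes
    errors: dict = field(default_factory=dict)       # (sumabsv, n_spc) -> {subject: [err]}
    gene_lists: dict = field(default_factory=dict)   # (sumabsv, n_spc) -> [gene ids]

    @property
    def best(self) -> pd.Series:
        return self.table.loc[self.table["mae_h"].idxmin()]


def loso_cv(
    matrix: pd.DataFrame,
    records: Sequence[SampleRecord],
    sumabsv_grid: Sequence[float] = DEFAULT_SUMABSV_GRID,
    nspc_grid: Sequence[int] = DEFAULT_NSPC_GRID,
    period: float = DEFAULT_PERIOD,
    n_knots: int = 3,
    basis: str = "harmonic",
) -> CvResult:
    """Leave-one-subject-out CV of the predictor over a hyperparameter grid.

    For each grid point, each subject is held out in turn, the predictor is
    trained on the rest and every held-out sample's internal time is
    predicted; the grid point's MAE is the median circular absolute error
    over all held-out samples. Selected gene lists come from a final fit on
    the full data.
    """
    recs = list(records)
    subjects = sorted({r.subject_id for r in recs})
    if len(subjects) < 3:
        raise ValueError("leave-one-subject-out CV needs >= 3 subjects")
    rows = []
    errors: dict = {}
    gene_lists: dict = {}
    for c in sumabsv_grid:
        for k in nspc_grid:
            per_subject: dict[str, list[float]] = {}
            for held in subjects:
                train = [r for r in recs if r.subject_id != held]
                test = [r for r in recs if r.subject_id == held]
                if not test:
                    import logging
                    logging.getLogger("skinrhythm").warning(
                        "subject %s has no samples; skipped", held)
                    continue
                model = train_predictor(matrix, train, c, k, period, n_knots, basis)
                errs = []
                for r in test:
                    pred = predict_time(model, matrix[r.sample_id])
                    errs.append(circular_error_h(pred, r.internal_time_h % period, period))
                per_subject[held] = errs
            all_errs = [e for v in per_subject.values() for e in v]
            full = train_predictor(matrix, recs, c, k, period, n_knots, basis)
            genes = full.selected_genes
            rows.append({"sumabsv": c, "n_spc": k,
                         "mae_h": float(np.median(all_errs)),
                         "n_genes": len(genes)})
            errors[(c, k)] = per_subject
            gene_lists[(c, k)] = genes
    return CvResult(table=pd.DataFrame(rows), errors=errors, gene_lists=gene_lists)
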