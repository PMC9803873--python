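"""Synthetic paired-layer diurnal cohorts with known ground truth.

The generator draws data from exactly the generative model the analysis
assumes: per gene, fixed cosinor coefficients (m, a, b) plus one random
(dm, da, db) vector per subject (full 3x3 covariance), one per layer
(diagonal covariance or a deterministic layer contrast), and iid Gaussian
residuals, observed at fixed wall-clock sampling times that map to
subject-specific internal times through each subject's chronotype (MSF_sc).

Defaults emulate the study design this package targets: 11 subjects x 2 skin
layers x 7 timepoints at 4-h spacing (8 h to 32 h wall time), chronotype
spread <= 3.5 h, ~10% rhythmic genes with a bimodal acrophase distribution
peaking near 1 h and 13 h after MSF_sc, lognormal amplitudes with a larger
epidermis median, and additive Gaussian noise.

Randomness: one master seed; a dedicated child stream per gene (spawned from
the master seed sequence), so outputs are bit-identical for a given seed and
stable under any future parallelisation across genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cosinor import DEFAULT_PERIOD, acrophase_from_coefs
from .io_metadata import GeneSetCollection, SampleRecord, to_internal_time

_DEFAULT_SIGMA_SUBJ = (np.diag([0.2, 0.1, 0.1])
                       @ (np.full((3, 3), 0.3) + 0.7 * np.eye(3))
                       @ np.diag([0.2, 0.1, 0.1]))
_DEFAULT_SIGMA_LAYER = np.diag([0.3**2, 0.05**2, 0.05**2])


@dataclass
class CohortConfig:
    """Study-design and generative parameters of a simulated cohort."""

    seed: int
    n_subjects: int = 11
    timepoints: tuple[float, ...] = (8.0, 12.0, 16.0, 20.0, 24.0, 28.0, 32.0)
    layers: tuple[str, str] = ("dermis", "epidermis")
    msf_low_h: float = 2.5
    msf_high_h: float = 6.0
    n_genes: int = 2000
    frac_rhythmic: float = 0.10
    amp_median_dermis: float = 0.35
    amp_median_epidermis: float = 0.50
    amp_log_sd: float = 0.35
    phase_centers_h: tuple[float, float] = (1.0, 13.0)
    phase_weights: tuple[float, float] = (0.5, 0.5)
    phase_kappa: float = 2.0
    mesor_mean: float = 8.0
    mesor_sd: float = 1.5
    sigma_subj: np.ndarray = field(default_factory=lambda: _DEFAULT_SIGMA_SUBJ.copy())
    sigma_layer: np.ndarray = field(default_factory=lambda: _DEFAULT_SIGMA_LAYER.copy())
    resid_sd: float = 0.2
    layer_mode: str = "random"  # or "fixed_contrast"
    period: float = DEFAULT_PERIOD
    planted: pd.DataFrame | None = None  # explicit per-layer truth (see below)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (0.0 <= self.frac_rhythmic <= 1.0):
            raise ValueError("frac_rhythmic must lie in [0, 1]")
        if self.msf_high_h - self.msf_low_h > 3.5 + 1e-9:
            raise ValueError("chronotype interval width must be <= 3.5 h")
        if self.msf_high_h < self.msf_low_h:
            raise ValueError("msf_high_h must be >= msf_low_h")
        if tuple(self.layers) != ("dermis", "epidermis"):
            raise ValueError("layers must be ('dermis', 'epidermis')")
        if self.layer_mode not in ("random", "fixed_contrast"):
            raise ValueError("layer_mode must be 'random' or 'fixed_contrast'")
        if self.resid_sd < 0:
            raise ValueError("resid_sd must be non-negative")
        for name, m, full in (("sigma_subj", self.sigma_subj, True),
                              ("sigma_layer", self.sigma_layer, False)):
            arr = np.asarray(m, dtype=float)
            if arr.shape not in ((3, 3), (self.n_genes, 3, 3)):
                raise ValueError(f"{name} must be 3x3 or (n_genes, 3, 3)")
            stack = arr if arr.ndim == 3 else arr[None]
            for s in stack:
                if not np.allclose(s, s.T, atol=1e-10):
                    raise ValueError(f"{name} is not symmetric")
                if np.linalg.eigvalsh(s).min() < -1e-10:
                    raise ValueError(f"{name} is not positive semi-definite")
                if not full and not np.allclose(s, np.diag(np.diag(s)), atol=1e-12):
                    raise ValueError(f"{name} must be diagonal")


@dataclass
class SimulationTruth:
    """Ground truth of one simulated cohort."""

    genes: pd.DataFrame        # gene_id, rhythmic, m, a, b, per-layer coefs, ...
    subjects: pd.DataFrame     # subject_id, msf_sc_h
    u_subj: np.ndarray         # n_genes x n_subjects x 3 realised subject effects
    u_layer: np.ndarray        # n_genes x 2 x 3 realised layer effects
    config: CohortConfig


def _per_gene_cov(m: np.ndarray, i: int) -> np.ndarray:
    arr = np.asarray(m, dtype=float)
    return arr[i] if arr.ndim == 3 else arr


def _chol_psd(S: np.ndarray) -> np.ndarray:
    # tolerate exact-zero variance components
    w, v = np.linalg.eigh(S)
    return v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))


def simulate_cohort(
    config: CohortConfig,
) -> tuple[pd.DataFrame, list[SampleRecord], SimulationTruth]:
    """Generate (expression matrix, sample records, truth) from the config.

    Expression follows the crossed random-effects cosinor model evaluated at
    internal time; sampling happens on a shared wall-clock grid, so internal
    times differ between subjects exactly as chronotype correction implies.
    Identical seeds give bit-identical outputs.
    """
    config.validate()
    S, L = config.n_subjects, 2
    w = 2.0 * np.pi / config.period

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_genes + 1)
    cohort_rng = np.random.default_rng(children[0])

    subject_ids = [f"P{101 + i}" for i in range(S)]
    msf = cohort_rng.uniform(config.msf_low_h, config.msf_high_h, S)

    records: list[SampleRecord] = []
    subj_idx, layer_idx, t_internal = [], [], []
    for si, sid in enumerate(subject_ids):
        for li, layer in enumerate(config.layers):
            for wall in config.timepoints:
                prefix = "D" if layer == "dermis" else "E"
                records.append(SampleRecord(
                    sample_id=f"{prefix}{wall:02g}_{sid}",
                    subject_id=sid, layer=layer,
                    wall_time_h=float(wall), msf_sc_h=float(msf[si]),
                ))
                subj_idx.append(si)
                layer_idx.append(li)
    records = to_internal_time(records)
    subj_idx = np.array(subj_idx)
    layer_idx = np.array(layer_idx)
    t_internal = np.array([r.internal_time_h for r in records])
    cos_t, sin_t = np.cos(w * t_internal), np.sin(w * t_internal)
    n_samples = len(records)

    # ---- gene-level truth (cohort stream) ----
    n_genes = config.n_genes
    gene_ids = [f"g{i + 1:05d}" for i in range(n_genes)]
    planted = config.planted
    if planted is not None:
        if len(planted) != n_genes:
            raise ValueError("planted truth must have n_genes rows")
        mesor = planted["m"].to_numpy(dtype=float)
        ab_layer = np.stack([
            planted[["a_dermis", "b_dermis"]].to_numpy(dtype=float),
            planted[["a_epidermis", "b_epidermis"]].to_numpy(dtype=float),
        ], axis=1)  # n_genes x 2 x 2
        rhythmic = np.any(np.abs(ab_layer).sum(axis=2) > 0, axis=1)
        gene_ids = planted["gene_id"].astype(str).tolist()
    else:
        mesor = cohort_rng.normal(config.mesor_mean, config.mesor_sd, n_genes)
        n_rhythmic = int(round(config.frac_rhythmic * n_genes))
        rhythmic = np.zeros(n_genes, dtype=bool)
        rhythmic[cohort_rng.choice(n_genes, size=n_rhythmic, replace=False)] = True
        comp = cohort_rng.choice(2, size=n_genes, p=list(config.phase_weights))
        centers = np.asarray(config.phase_centers_h)[comp]
        jitter = cohort_rng.vonmises(0.0, config.phase_kappa, n_genes)
        phase = np.mod(centers + jitter * config.period / (2.0 * np.pi), config.period)
        amp_d = np.exp(cohort_rng.normal(np.log(config.amp_median_dermis),
                                         config.amp_log_sd, n_genes))
        if config.layer_mode == "fixed_contrast":
            ratio = config.amp_median_epidermis / config.amp_median_dermis
            amp_e = amp_d * ratio
        else:
            geo = np.sqrt(config.amp_median_dermis * config.amp_median_epidermis)
            amp_d = amp_e = amp_d * geo / config.amp_median_dermis
        ab_layer = np.zeros((n_genes, L, 2))
        for li, amp in enumerate((amp_d, amp_e)):
            ab_layer[:, li, 0] = np.where(rhythmic, amp * np.cos(w * phase), 0.0)
            ab_layer[:, li, 1] = np.where(rhythmic, amp * np.sin(w * phase), 0.0)

    fixed = np.zeros((n_genes, 3))
    fixed[:, 0] = mesor
    fixed[:, 1:] = ab_layer.mean(axis=1)

    deterministic_layer_ab = (planted is not None
                              or config.layer_mode == "fixed_contrast")

    # ---- realised effects and expression (per-gene streams) ----
    expr = np.empty((n_genes, n_samples))
    u_subj_all = np.empty((n_genes, S, 3))
    u_layer_all = np.empty((n_genes, L, 3))
    for i in range(n_genes):
        rng = np.random.default_rng(children[i + 1])
        Ls = _chol_psd(_per_gene_cov(config.sigma_subj, i))
        u_subj = rng.standard_normal((S, 3)) @ Ls.T
        Ll = _chol_psd(_per_gene_cov(config.sigma_layer, i))
        u_layer = rng.standard_normal((L, 3)) @ Ll.T
        if not rhythmic[i]:
            # flat genes keep baseline (mesor) offsets only; a truly flat gene
            # has no rhythm to vary between subjects or layers
            u_subj[:, 1:] = 0.0
            u_layer[:, 1:] = 0.0
        if deterministic_layer_ab:
            # (a, b) layer deviations fixed by the per-layer truth; only the
            # mesor keeps a random layer component
            u_layer[:, 1:] = ab_layer[i] - fixed[i, 1:]
        eps = rng.normal(0.0, config.resid_sd, n_samples)
        B = fixed[i] + u_subj[subj_idx] + u_layer[layer_idx]  # n_samples x 3
        expr[i] = B[:, 0] + B[:, 1] * cos_t + B[:, 2] * sin_t + eps
        u_subj_all[i] = u_subj
        u_layer_all[i] = u_layer

    matrix = pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene_id"),
                          columns=[r.sample_id for r in records])

    amp_fixed = np.hypot(fixed[:, 1], fixed[:, 2])
    genes = pd.DataFrame({
        "gene_id": gene_ids,
        "rhythmic": rhythmic,
        "m": fixed[:, 0], "a": fixed[:, 1], "b": fixed[:, 2],
        "amplitude": amp_fixed,
        "acrophase_h": acrophase_from_coefs(fixed[:, 1], fixed[:, 2], config.period),
        "a_dermis": ab_layer[:, 0, 0], "b_dermis": ab_layer[:, 0, 1],
        "a_epidermis": ab_layer[:, 1, 0], "b_epidermis": ab_layer[:, 1, 1],
        "amplitude_dermis": np.hypot(ab_layer[:, 0, 0], ab_layer[:, 0, 1]),
        "amplitude_epidermis": np.hypot(ab_layer[:, 1, 0], ab_layer[:, 1, 1]),
        "resid_sd": config.resid_sd,
    })
    if planted is not None and "category" in planted.columns:
        genes["category"] = planted["category"].to_numpy()
    subjects = pd.DataFrame({"subject_id": subject_ids, "msf_sc_h": msf})
    truth = SimulationTruth(genes=genes, subjects=subjects,
                            u_subj=u_subj_all, u_layer=u_layer_all, config=config)
    return matrix, records, truth


# ---------------------------------------------------------------------------
# Planted-category truth for differential-rhythmicity recovery runs
# ---------------------------------------------------------------------------

def planted_category_frame(
    seed: int,
    n_shared: int = 20,
    n_dermis_only: int = 10,
    n_epidermis_only: int = 10,
    n_phase_shift: int = 5,
    n_flat: int = 155,
    amplitude: float = 0.6,
    mesor_mean: float = 8.0,
    period: float = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Per-layer coefficient truth with known rhythmicity categories.

    Shared genes have identical rhythms in both layers; layer-only genes are
    flat in the other layer; phase-shift genes are antiphase between layers
    (both above the amplitude threshold, clearly differential).
    """
    rng = np.random.default_rng(seed)
    w = 2.0 * np.pi / period
    rows = []
    counters = {
        "both_indistinguishable": n_shared,
        "dermis_only": n_dermis_only,
        "epidermis_only": n_epidermis_only,
        "both_differential": n_phase_shift,
        "not_rhythmic": n_flat,
    }
    i = 0
    for category, count in counters.items():
        for _ in range(count):
            i += 1
            phase = rng.uniform(0.0, period)
            a, b = amplitude * np.cos(w * phase), amplitude * np.sin(w * phase)
            m = rng.normal(mesor_mean, 1.0)
            if category == "both_indistinguishable":
                ad, bd, ae, be = a, b, a, b
            elif category == "dermis_only":
                ad, bd, ae, be = a, b, 0.0, 0.0
            elif category == "epidermis_only":
                ad, bd, ae, be = 0.0, 0.0, a, b
            elif category == "both_differential":
                ad, bd, ae, be = a, b, -a, -b  # antiphase
            else:
                ad = bd = ae = be = 0.0
            rows.append({"gene_id": f"g{i:05d}", "m": m,
                         "a_dermis": ad, "b_dermis": bd,
                         "a_epidermis": ae, "b_epidermis": be,
                         "category": category})
    return pd.DataFrame(rows)


def synthetic_gene_sets(
    gene_ids: Sequence[str],
    rng: np.random.Generator,
    n_sets: int = 20,
    set_size: int = 30,
) -> GeneSetCollection:
    """Random gene sets over the given universe (for pipeline smoke runs)."""
    genes = [str(g) for g in gene_ids]
    size = min(set_size, len(genes))
    sets = {f"set_{i + 1:02d}": list(rng.choice(genes, size=size, replace=False))
            for i in range(n_sets)}
    return GeneSetCollection(sets=sets,
                             descriptions={k: "synthetic random set" for k in sets})


# ---------------------------------------------------------------------------
# Truth-vs-estimate recovery reporting
# ---------------------------------------------------------------------------

def truth_vs_estimates_report(
    truth: pd.DataFrame,
    estimates: pd.DataFrame,
    quantities: Sequence[tuple[str, str]] | None = None,
    circular: Sequence[str] = ("acrophase_h",),
    period: float = DEFAULT_PERIOD,
) -> pd.DataFrame:
    """Bias, RMSE and rank correlation of estimates against ground truth.

    ``truth`` and ``estimates`` must both carry ``gene_id``; ``quantities``
    lists (truth_column, estimate_column) pairs (defaults to all shared
    numeric columns). Phase-like columns named in ``circular`` use wrapped
    differences. A shared ``category`` column is scored by accuracy.
    """
    t_ids, e_ids = set(truth["gene_id"]), set(estimates["gene_id"])
    if t_ids != e_ids:
        raise ValueError("gene ids of truth and estimates do not match: "
                         f"{sorted(t_ids ^ e_ids)[:5]}")
    merged = truth.merge(estimates, on="gene_id", suffixes=("_true", "_est"))
    if quantities is None:
        shared = [c for c in truth.columns
                  if c in estimates.columns and c != "gene_id"
                  and pd.api.types.is_numeric_dtype(truth[c])]
        quantities = [(c, c) for c in shared]
    rows = []
    for tcol, ecol in quantities:
        tv = merged[tcol if tcol in merged.columns else tcol + "_true"].to_numpy(float)
        ev = merged[ecol if ecol + "_est" not in merged.columns else ecol + "_est"].to_numpy(float)
        diff = ev - tv
        base = tcol.removesuffix("_true")
        if base in circular:
            diff = period / 2.0 - np.mod(period / 2.0 - diff, period)
        ok = np.isfinite(diff)
        rho = (stats.spearmanr(tv[ok], ev[ok]).statistic
               if ok.sum() > 2 and np.unique(tv[ok]).size > 1 else np.nan)
        rows.append({"quantity": base, "n": int(ok.sum()),
                     "bias": float(np.mean(diff[ok])),
                     "rmse": float(np.sqrt(np.mean(diff[ok] ** 2))),
                     "rank_corr": float(rho) if rho == rho else np.nan})
    if "category" in truth.columns and "category" in estimates.columns:
        acc = float(np.mean(merged["category_true"] == merged["category_est"]))
        rows.append({"quantity": "category", "n": len(merged),
                     "bias": np.nan, "rmse": np.nan, "rank_corr": np.nan,
                     "accuracy": acc})
    return pd.DataFrame(rows)
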