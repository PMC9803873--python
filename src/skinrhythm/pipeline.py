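"""Configuration-driven orchestration of the full diurnal analysis.

A single :class:`RunConfig` (YAML-loadable) drives: input loading or cohort
simulation -> outlier flagging -> per-layer population rhythm scans ->
differential-rhythmicity categorisation -> mixed-model variability (gated to
genes rhythmic in at least one layer) -> ORA + PSEA enrichment -> predictor
leave-one-subject-out CV. Every stage writes a tidy TSV; a JSON summary and a
log (package/library versions, seed, thresholds) round off the bundle. All
randomness flows from the one seed in the config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import io_metadata
from .cosinor import layerwise_rhythm_scan
from .differential import (CATEGORIES, categorize, circular_phase_stats,
                           differential_scan)
from .enrichment import hypergeom_ora, psea
from .io_metadata import (GeneSetCollection, check_matrix_metadata,
                          flag_outlier_samples, load_expression, load_gmt,
                          load_metadata, to_internal_time, use_wall_time)
from .predictor import DEFAULT_NSPC_GRID, DEFAULT_SUMABSV_GRID, loso_cv
from .synthetic import CohortConfig, simulate_cohort, synthetic_gene_sets
from .variability import variability_table

logger = logging.getLogger("skinrhythm")

ALL_STAGES = ("rhythms", "differential", "variability", "enrich", "predict")


@dataclass
class RunConfig:
    """Everything one analysis run needs; exactly one of input/simulate."""

    seed: int
    output_dir: str = "skinrhythm_out"
    expression: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    simulate: dict | None = None
    period: float = 24.0
    fdr: float = 0.05
    fc_threshold: float = 1.5
    ora_min_set: int = 20
    psea_min_set: int = 5
    sumabsv_grid: tuple[float, ...] = DEFAULT_SUMABSV_GRID
    nspc_grid: tuple[int, ...] = DEFAULT_NSPC_GRID
    outlier_k: float = 4.0
    moderate_variances: bool = True
    wall_time: bool = False
    max_variability_genes: int | None = 100
    predictor_layers: tuple[str, ...] = ("dermis", "epidermis")

    def validate(self) -> None:
        has_input = self.expression is not None or self.metadata is not None
        if has_input == (self.simulate is not None):
            raise ValueError("exactly one of input paths or a simulate block "
                             "must be provided")
        if has_input and (self.expression is None or self.metadata is None):
            raise ValueError("both expression and metadata paths are required")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must lie in (0, 1)")
        if not self.fc_threshold > 1:
            raise ValueError("fc_threshold must exceed 1")
        if self.ora_min_set < 0 or self.psea_min_set < 0:
            raise ValueError("min-set sizes must be non-negative")
        if self.outlier_k < 0:
            raise ValueError("outlier_k must be non-negative")
        if self.period <= 0:
            raise ValueError("period must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        stray = set(raw) - known
        if stray:
            raise ValueError(f"unknown config key(s): {sorted(stray)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def summarize_categories(categorized: pd.DataFrame) -> dict:
    """Category counts plus the per-layer totals implied by the partition.

    Dermis total = indistinguishable + dermis_only + both_differential (all
    both_differential genes clear the fold-change bar in both layers), and
    symmetrically for epidermis.
    """
    labels = set(categorized["category"])
    unknown = labels - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown category label(s): {sorted(unknown)}")
    counts = {c: int((categorized["category"] == c).sum()) for c in CATEGORIES}
    counts["dermis_total"] = (counts["both_indistinguishable"]
                              + counts["both_differential"]
                              + counts["dermis_only"])
    counts["epidermis_total"] = (counts["both_indistinguishable"]
                                 + counts["both_differential"]
                                 + counts["epidermis_only"])
    counts["rhythmic_any"] = len(categorized) - counts["not_rhythmic"]
    return counts


def _setup_logging(outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)


def _log_environment(config: RunConfig) -> None:
    import scipy

    from . import __version__
    logger.info("skinrhythm %s | numpy %s scipy %s pandas %s | python %s",
                __version__, np.__version__, scipy.__version__, pd.__version__,
                sys.version.split()[0])
    logger.info("seed=%s fdr=%s fc_threshold=%s period=%s wall_time=%s",
                config.seed, config.fdr, config.fc_threshold, config.period,
                config.wall_time)


def run_full_analysis(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> dict:
    """Execute the pipeline and return the JSON-serialisable summary."""
    config.validate()
    outdir = Path(config.output_dir)
    _setup_logging(outdir)
    _log_environment(config)
    summary: dict = {"seed": config.seed, "stages": {}}
    stage = "input"
    try:
        # ---- input ----
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            cohort = CohortConfig(**sim_kwargs)
            matrix, records, truth = simulate_cohort(cohort)
            io_metadata.write_expression(matrix, outdir / "expression.tsv")
            io_metadata.write_metadata(records, outdir / "metadata.tsv")
            truth.genes.to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
        else:
            matrix = load_expression(config.expression)
            records = load_metadata(config.metadata)
            truth = None
        check_matrix_metadata(matrix, records)

        stage = "outliers"
        flagged = flag_outlier_samples(matrix, k=config.outlier_k)
        if len(flagged) > 0.1 * matrix.shape[1]:
            # distances concentrated far from the centroid (e.g. layer
            # separation on PC1) are structure, not outliers
            logger.warning("outlier rule flagged %d/%d samples; ignoring "
                           "(dominant structure, not outliers)",
                           len(flagged), matrix.shape[1])
            flagged = []
        if flagged:
            logger.info("removing flagged outlier sample(s): %s", flagged)
            matrix = matrix.drop(columns=flagged)
            records = [r for r in records if r.sample_id not in flagged]
        summary["stages"]["outliers"] = {"flagged": flagged}

        stage = "time_axis"
        records = (use_wall_time(records) if config.wall_time
                   else to_internal_time(records))

        # ---- per-layer population scans ----
        stage = "rhythms"
        scans = {}
        for layer in ("dermis", "epidermis"):
            scan = layerwise_rhythm_scan(matrix, records, layer,
                                         period=config.period,
                                         moderate=config.moderate_variances)
            scan.to_csv(outdir / f"rhythms_{layer}.tsv", sep="\t", index=False)
            scans[layer] = scan
        summary["stages"]["rhythms"] = {
            layer: {"n_genes": int(len(s)),
                    "n_q_lt_fdr": int((s["q"] < config.fdr).sum())}
            for layer, s in scans.items()
        }
        if stages == ("rhythms",):
            return _finish(summary, outdir)

        # ---- differential rhythmicity ----
        stage = "differential"
        dscan = differential_scan(matrix, records, period=config.period,
                                  moderate=config.moderate_variances)
        cat = categorize(dscan, fdr=config.fdr, fc_threshold=config.fc_threshold)
        cat.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        counts = summarize_categories(cat)
        both = cat[cat["category"].isin(["both_indistinguishable",
                                         "both_differential"])]
        phase_block = {}
        if len(both):
            mean_diff, R, p_ray = circular_phase_stats(
                both["acrophase_h_d"], both["acrophase_h_e"], config.period)
            phase_block = {"mean_phase_difference_h": mean_diff,
                           "rayleigh_R": R, "rayleigh_p": p_ray}
        summary["stages"]["differential"] = {"categories": counts,
                                             "phase_stats": phase_block}
        rhythmic = cat[cat["category"] != "not_rhythmic"]

        # ---- variability ----
        if "variability" in stages:
            stage = "variability"
            ordered = rhythmic.sort_values("q_any", kind="stable")
            genes = ordered["gene_id"].tolist()
            if config.max_variability_genes is not None:
                genes = genes[: config.max_variability_genes]
            vtab = variability_table(matrix, records, genes, period=config.period)
            vtab.to_csv(outdir / "variability.tsv", sep="\t", index=False)
            block = {"n_genes": int(len(vtab))}
            for col in ("f_m", "f_A", "f_phase", "cv_A_subj", "cv_A_layer"):
                if len(vtab):
                    block[f"median_{col}"] = float(np.nanmedian(vtab[col]))
            summary["stages"]["variability"] = block

        # ---- enrichment ----
        if "enrich" in stages:
            stage = "enrich"
            if config.gmt is not None:
                collections = load_gmt(config.gmt)
            else:
                collections = synthetic_gene_sets(matrix.index, rng)
                logger.info("no GMT supplied; using synthetic random gene sets")
            background = [str(g) for g in matrix.index]
            enr_block = {}
            for layer, cats in (("dermis", ("both_indistinguishable",
                                            "both_differential", "dermis_only")),
                                ("epidermis", ("both_indistinguishable",
                                               "both_differential",
                                               "epidermis_only"))):
                calls = cat[cat["category"].isin(cats)]
                query = calls["gene_id"].tolist()
                ora = hypergeom_ora(query, collections, background,
                                    min_set=config.ora_min_set)
                ora.to_csv(outdir / f"ora_{layer}.tsv", sep="\t", index=False)
                ph_col = "acrophase_h_d" if layer == "dermis" else "acrophase_h_e"
                phase_map = dict(zip(calls["gene_id"], calls[ph_col]))
                ps = psea(phase_map, collections, min_set=config.psea_min_set,
                          q_threshold=config.fdr, period=config.period)
                ps.to_csv(outdir / f"psea_{layer}.tsv", sep="\t", index=False)
                enr_block[layer] = {
                    "ora_sets_tested": int(len(ora)),
                    "ora_sets_q_lt_fdr": int((ora["q"] < config.fdr).sum())
                    if len(ora) else 0,
                    "psea_sets_tested": int(len(ps)),
                    "psea_sets_significant": int(ps["significant"].sum())
                    if len(ps) else 0,
                }
            summary["stages"]["enrich"] = enr_block

        # ---- predictor ----
        if "predict" in stages:
            stage = "predict"
            pred_block = {}
            for layer in config.predictor_layers:
                recs = [r for r in records if r.layer == layer]
                cv = loso_cv(matrix, recs, config.sumabsv_grid,
                             config.nspc_grid, period=config.period)
                cv.table.to_csv(outdir / f"cv_{layer}.tsv", sep="\t", index=False)
                best = cv.best
                pred_block[layer] = {
                    "mae_grid": cv.table.to_dict(orient="records"),
                    "best": {"sumabsv": float(best["sumabsv"]),
                             "n_spc": int(best["n_spc"]),
                             "mae_h": float(best["mae_h"]),
                             "n_genes": int(best["n_genes"])},
                }
            summary["stages"]["predict"] = pred_block
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
    return _finish(summary, outdir)


def _finish(summary: dict, outdir: Path) -> dict:
    text = json.dumps(summary, indent=2, sort_keys=True, default=float)
    (outdir / "summary.json").write_text(text + "\n")
    logger.info("summary written to %s", outdir / "summary.json")
    return summary
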