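"""End-to-end pipeline runner with config, logging and a run manifest.

Ties the stages (simulate -> behavior -> expression -> compare) into a
reproducible run: a :class:`RunConfig` records every parameter, each stage
logs its inputs and choices, and a JSON manifest records parameters, the
seed and SHA-256 hashes of every output, so a rerun with the same config is
verifiably identical. Partial outputs are removed if a stage fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior, comparative, expression, io, synthetic
from .schedule import LightSchedule

__all__ = ["RunConfig", "ConfigError", "run_pipeline"]

log = logging.getLogger("dielrhythm")


class ConfigError(ValueError):
    """Raised before any computation when a run configuration is unusable."""


@dataclass
class RunConfig:
    """Parameters for a full pipeline run. ``seed`` drives every stage."""

    out_dir: str
    seed: int
    # inputs; None means "simulate"
    activity_csv: str | None = None
    schedule_file: str | None = None
    counts_tsv: str | None = None
    homologs_tsv: str | None = None
    # simulation
    n_animals: int = 35
    duration_h: int = 72
    condition: str = "LD"
    n_genes: int = 2000
    frac_rhythmic: float = 0.1
    # behavior analysis
    period_min_h: float = 16.0
    period_max_h: float = 32.0
    period_step_h: float = 0.01
    n_permutations: int = 1000
    alpha: float = 0.05
    # expression analysis
    interval_h: float = 4.0
    start_zt: float = 1.0
    g_cutoff: float = 0.5
    k_clusters: int = 5
    kmeans_restarts: int = 50
    # comparative
    fold_threshold: float = 3.0
    stages: tuple[str, ...] = ("simulate", "behavior", "expression", "compare")

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        if not (0 < self.period_min_h < self.period_max_h):
            raise ConfigError("need 0 < period_min_h < period_max_h")
        if self.period_step_h <= 0:
            raise ConfigError("period_step_h must be positive")
        if self.n_permutations < 100:
            raise ConfigError("n_permutations must be >= 100")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 <= self.g_cutoff <= 1:
            raise ConfigError("g_cutoff must lie in [0, 1]")
        if self.k_clusters < 1 or self.kmeans_restarts < 1:
            raise ConfigError("k_clusters and kmeans_restarts must be >= 1")
        if self.fold_threshold <= 0:
            raise ConfigError("fold_threshold must be positive")
        unknown = set(self.stages) - {"simulate", "behavior", "expression", "compare"}
        if unknown:
            raise ConfigError(f"unknown stages {sorted(unknown)}")
        if "behavior" in self.stages and "simulate" not in self.stages:
            if self.activity_csv is None:
                raise ConfigError("behavior stage needs activity_csv when not simulating")
            if self.schedule_file is None:
                raise ConfigError("behavior stage needs a schedule")
        if "expression" in self.stages and "simulate" not in self.stages:
            if self.counts_tsv is None:
                raise ConfigError("expression stage needs counts_tsv when not simulating")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and write a manifest; returns the manifest.

    Reruns with an identical config produce byte-identical outputs and an
    identical manifest.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _track(path: Path) -> Path:
        written.append(path)
        return path

    try:
        manifest: dict = {
            "parameters": asdict(config),
            "seed": config.seed,
            "outputs": {},
        }
        schedule: LightSchedule | None = None
        traces = None
        counts = None

        if "simulate" in config.stages:
            log.info(
                "simulate: n_animals=%d duration_h=%d condition=%s n_genes=%d seed=%d",
                config.n_animals, config.duration_h, config.condition,
                config.n_genes, config.seed,
            )
            aspec = synthetic.ActivitySimSpec(
                n_animals=config.n_animals,
                duration_h=config.duration_h,
                condition=config.condition,
                seed=config.seed,
            )
            traces, atruth = synthetic.simulate_activity_cohort(aspec)
            schedule = aspec.resolved_schedule()
            io.write_activity_csv(_track(out / "activity.csv"), traces)
            io.write_schedule(_track(out / "schedule.yaml"), schedule)
            atruth.animal_scales.to_csv(
                _track(out / "activity_truth.tsv"), sep="\t", index_label="animal_id"
            )
            espec = synthetic.ExpressionSimSpec(
                n_genes=config.n_genes,
                frac_rhythmic=config.frac_rhythmic,
                interval_h=config.interval_h,
                start_zt=config.start_zt,
                seed=config.seed + 1,
            )
            counts, etruth = synthetic.simulate_expression_timecourse(espec)
            io.write_counts_tsv(_track(out / "counts.tsv"), counts)
            pd.DataFrame(
                {
                    "rhythmic": etruth.rhythmic_flag,
                    "phase_zt": etruth.true_phase_zt,
                }
            ).to_csv(_track(out / "counts_truth.tsv"), sep="\t", index_label="gene_id")

        if "behavior" in config.stages:
            if traces is None:
                traces = io.read_activity_csv(config.activity_csv)
                schedule = io.read_schedule(config.schedule_file)
            assert schedule is not None
            log.info(
                "behavior: n=%d grid=[%g, %g] step=%g perms=%d alpha=%g",
                len(traces), config.period_min_h, config.period_max_h,
                config.period_step_h, config.n_permutations, config.alpha,
            )
            normalized = []
            for tr in traces:
                try:
                    normalized.append(
                        behavior.normalize_to_max(behavior.bin_hourly(tr), tr.animal_id)
                    )
                except behavior.DegenerateTraceError:
                    log.warning("excluding all-zero trace %s", tr.animal_id)
            cohort = behavior.aggregate_cohort(normalized)
            io.write_cohort_profile(_track(out / "cohort_profile.tsv"), cohort)
            grid = behavior.default_period_grid(
                config.period_min_h, config.period_max_h, config.period_step_h
            )
            pg = behavior.dft_periodogram(cohort.mean_pct, grid)
            io.write_periodogram(_track(out / "periodogram.tsv"), pg)
            rt = behavior.test_rhythmicity(
                cohort.mean_pct,
                grid,
                n_permutations=config.n_permutations,
                alpha=config.alpha,
                seed=config.seed,
            )
            io.write_rhythm_test(_track(out / "rhythm_test.json"), rt, pg.dominant_period_h)
            summary = behavior.day_night_summary(traces, schedule)
            peaks = behavior.daily_peaks(cohort, schedule)
            (out / "day_night.json").write_text(
                json.dumps(
                    {
                        "mean_dark_total_cm": summary.mean_dark_total_cm,
                        "se_dark": summary.se_dark,
                        "mean_light_total_cm": summary.mean_light_total_cm,
                        "se_light": summary.se_light,
                        "n": summary.n,
                        "daily_peak_zt": peaks,
                    },
                    indent=2,
                )
                + "\n"
            )
            _track(out / "day_night.json")

        dcgs = None
        if "expression" in config.stages:
            if counts is None:
                counts = io.read_counts_tsv(config.counts_tsv)
            log.info(
                "expression: %d genes x %d samples, cutoff=%g k=%d",
                counts.shape[0], counts.shape[1], config.g_cutoff, config.k_clusters,
            )
            factors, norm = expression.poisson_tmm_normalize(counts)
            factors.factors.to_frame().to_csv(
                _track(out / "size_factors.tsv"), sep="\t", index_label="sample"
            )
            norm = expression.collapse_replicates(norm)
            norm.round(6).to_csv(
                _track(out / "normalized.tsv"), sep="\t", index_label="gene_id"
            )
            gt = expression.g_factor_table(norm, interval_h=config.interval_h)
            dcgs = expression.select_dcgs(gt, cutoff=config.g_cutoff)
            gtab = gt.table.copy()
            gtab["selected"] = gtab.index.isin(dcgs)
            gtab.round(6).to_csv(
                _track(out / "gfactor.tsv"), sep="\t", index_label="gene_id"
            )
            if len(dcgs) >= config.k_clusters:
                cl = expression.kmeans_phase_clusters(
                    norm.loc[dcgs],
                    k=config.k_clusters,
                    seed=config.seed,
                    restarts=config.kmeans_restarts,
                    interval_h=config.interval_h,
                    start_zt=config.start_zt,
                )
                peaks_zt = [
                    expression.estimate_peak_zt(
                        norm.loc[g].to_numpy(),
                        interval_h=config.interval_h,
                        start_zt=config.start_zt,
                    )
                    for g in dcgs
                ]
                pd.DataFrame(
                    {"cluster": cl.assignment, "peak_zt": np.round(peaks_zt, 3)}
                ).to_csv(_track(out / "clusters.tsv"), sep="\t", index_label="gene_id")
            else:
                log.warning("only %d DCGs; skipping clustering", len(dcgs))

        if "compare" in config.stages:
            hom = (
                comparative.load_homolog_table(config.homologs_tsv)
                if config.homologs_tsv
                else comparative.packaged_table("table3")
            )
            log.info("compare: %d homolog rows, threshold=%g", len(hom), config.fold_threshold)
            if {"day_count", "night_count"} <= set(hom.columns):
                pairs = comparative.table_pairs(hom)
                day_up, night_up = comparative.fold_change_filter(
                    pairs, threshold=config.fold_threshold
                )
                pd.DataFrame(
                    [
                        (p.nv_gene_id, p.am_seqindex, p.day_count, p.night_count, p.direction)
                        for p in day_up + night_up
                    ],
                    columns=["nv_gene_id", "am_seqindex", "day_count", "night_count", "direction"],
                ).to_csv(_track(out / "fold_change.tsv"), sep="\t", index=False)
            if dcgs is not None:
                joined, unmapped = comparative.overlap_dcgs(dcgs, hom)
                joined.to_csv(_track(out / "dcg_overlap.tsv"), sep="\t", index=False)
                manifest["unmapped_dcgs"] = unmapped

        for path in written:
            manifest["outputs"][path.name] = _sha256(path)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        return manifest
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
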