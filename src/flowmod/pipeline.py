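"""End-to-end assay runs: simulate/load -> gate -> score -> evaluate.

A run produces, under one output directory:

* ``gating.csv``     — per-well gate-chain counts, PE threshold, positive
  fraction and quality flags;
* ``results.csv``    — per-serum screening % immunomodulation,
  classification against the mean+3SD limit, endpoint titer;
* ``roc_points.csv`` — the empirical ROC curve;
* ``summary.json``   — decision limit, AUROC, sensitivity/specificity,
  Spearman correlations, group counts, master seed and package version.

Identical configuration and seed reproduce every numeric output exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluate import DiagnosticSummary, assignments_to_frame, evaluate_cohort, pool_groups
from .fcsio import (
    read_fcs,
    read_layout,
    read_metadata,
    write_fcs,
    write_layout,
    write_metadata,
)
from .gating import GatingParams, gate_events, percent_positive, quadrant_threshold
from .scoring import (
    DETECTED,
    NOT_DETECTED,
    SampleResult,
    WellTriplet,
    decision_limit,
    endpoint_titer,
    immunomodulation_percent,
    results_to_frame,
)
from .simulate import (
    DEFAULT_DILUTIONS,
    SCREENING_DILUTION,
    CohortConfig,
    EventTable,
    SerumSample,
    SimParams,
    simulate_cohort,
    simulate_dilution_series,
)

logger = logging.getLogger(__name__)

# seed offset for titration wells so they never collide with screening wells
_TITRATION_SEED_BASE = 10_000_000


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One pipeline run: either simulate a cohort or load FCS files."""

    mode: str = "simulate"  # "simulate" | "files"
    out_dir: str = "flowmod_out"
    seed: int = 0
    k_sigma: float = 3.0
    screening_dilution: int = SCREENING_DILUTION
    titrate: bool = True
    plot_roc: bool = False
    fcs_dir: str | None = None
    layout_path: str | None = None
    metadata_path: str | None = None
    sim_params: SimParams = field(default_factory=SimParams)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gating: GatingParams = field(default_factory=GatingParams)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise PipelineError(f"config: unknown mode {self.mode!r}")
        if self.mode == "files" and not (self.layout_path and self.metadata_path):
            raise PipelineError(
                "config: files mode needs layout_path and metadata_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        for key, typ in (
            ("sim_params", SimParams),
            ("cohort", CohortConfig),
            ("gating", GatingParams),
        ):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)


def well_filename(well_key: str) -> str:
    """FCS filename for a layout well key (``P1:W03`` -> ``P1-W03.fcs``)."""
    return well_key.replace(":", "-") + ".fcs"


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def load_wells(
    config: RunConfig,
) -> tuple[pd.DataFrame, dict[str, EventTable], pd.DataFrame]:
    """Simulate or read the cohort's wells, layout and sample metadata."""
    if config.mode == "simulate":
        return simulate_cohort(config.cohort, config.sim_params, config.seed)
    layout = read_layout(config.layout_path)
    metadata = read_metadata(config.metadata_path)
    fcs_dir = Path(config.fcs_dir or ".")
    wells = {}
    for row in layout.itertuples(index=False):
        table = read_fcs(fcs_dir / well_filename(row.well))
        table.meta.update(
            plate=row.plate, well=row.well, sample_id=row.sample_id, role=row.role
        )
        wells[row.well] = table
    return layout, wells, metadata


def gate_cohort(
    layout: pd.DataFrame,
    wells: dict[str, EventTable],
    gating: GatingParams,
) -> pd.DataFrame:
    """Gate every well plate-by-plate against its unstained control.

    Returns one row per well with the gate-chain counts, the plate's PE
    quadrant threshold and the positive fraction.
    """
    rows = []
    for plate, group in layout.groupby("plate", sort=False):
        unstained_keys = group.loc[group["role"] == "unstained", "well"]
        if len(unstained_keys) != 1:
            raise PipelineError(
                f"gating: plate {plate} needs exactly one unstained control"
            )
        ctrl_gated = gate_events(wells[unstained_keys.iloc[0]], gating)
        threshold = quadrant_threshold(ctrl_gated, gating.quadrant_target_fraction)
        for row in group.itertuples(index=False):
            res = percent_positive(wells[row.well], threshold, gating)
            rows.append(
                {
                    "plate": plate,
                    "well": row.well,
                    "sample_id": row.sample_id,
                    "role": row.role,
                    "reciprocal_dilution": row.reciprocal_dilution,
                    "n_acquired": res.n_acquired,
                    "n_viable": res.n_viable,
                    "n_scatter": res.n_scatter,
                    "n_singlet": res.n_singlet,
                    "pe_threshold": res.pe_threshold,
                    "positive_fraction": res.positive_fraction,
                    "flags": ";".join(res.flags),
                }
            )
    return pd.DataFrame(rows)


def score_screening(gating_report: pd.DataFrame) -> pd.DataFrame:
    """Per-serum % immunomodulation at the screening dilution.

    MIN/MAX are the same plate's unstained and maximally stained control
    positive fractions (each plate is scored against its own controls).
    """
    rows = []
    for plate, group in gating_report.groupby("plate", sort=False):
        try:
            min_pp = float(
                group.loc[group["role"] == "unstained", "positive_fraction"].iloc[0]
            )
            max_pp = float(
                group.loc[group["role"] == "max_stained", "positive_fraction"].iloc[0]
            )
        except IndexError as exc:
            raise PipelineError(f"scoring: plate {plate} lacks control wells") from exc
        for row in group[group["role"] == "test"].itertuples(index=False):
            triplet = WellTriplet(
                test_pp=float(row.positive_fraction), min_pp=min_pp, max_pp=max_pp
            )
            rows.append(
                {
                    "sample_id": row.sample_id,
                    "plate": plate,
                    "screening_im": immunomodulation_percent(triplet),
                    "flags": row.flags,
                }
            )
    return pd.DataFrame(rows)


def _sample_from_row(row) -> SerumSample:
    ria = getattr(row, "ria_pM", None)
    if ria is not None and (isinstance(ria, float) and np.isnan(ria)):
        ria = None
    truth = getattr(row, "blinded_truth", None)
    if isinstance(truth, float) and np.isnan(truth):
        truth = None
    return SerumSample(
        sample_id=row.sample_id,
        category=row.category,
        true_conc_pM=float(getattr(row, "true_conc_pM", 0.0) or 0.0),
        ria_pM=None if ria is None else float(ria),
        blinded_truth=truth,
    )


def titrate_sample(
    sample: SerumSample,
    screening_score: float,
    rule,
    config: RunConfig,
    series_seed: int,
) -> int:
    """Endpoint titer of a detected serum via a simulated two-fold series.

    The screening well provides the 1:20 entry; further dilutions are
    simulated with their own plate controls, gated and scored.
    """
    dilutions = [d for d in config.cohort.dilutions if d > config.screening_dilution]
    series = [(config.screening_dilution, screening_score)]
    if dilutions:
        unst, maxs, tables = simulate_dilution_series(
            sample, dilutions, config.sim_params, series_seed
        )
        ctrl_gated = gate_events(unst, config.gating)
        thr = quadrant_threshold(ctrl_gated, config.gating.quadrant_target_fraction)
        min_pp = percent_positive(unst, thr, config.gating).positive_fraction
        max_pp = percent_positive(maxs, thr, config.gating).positive_fraction
        for dil, table in zip(dilutions, tables):
            pp = percent_positive(table, thr, config.gating).positive_fraction
            series.append(
                (
                    dil,
                    immunomodulation_percent(
                        WellTriplet(test_pp=pp, min_pp=min_pp, max_pp=max_pp)
                    ),
                )
            )
    titer = endpoint_titer(series, rule)
    # the screening score already exceeded the limit, so a titer exists
    assert titer is not None
    return titer


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns the summary dictionary that is also written to
    ``summary.json``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        layout, wells, metadata = load_wells(config)
    except Exception as exc:
        raise PipelineError(f"input stage failed: {exc}") from exc
    if config.mode == "simulate":
        write_layout(layout, out / "plate_layout.csv")
        write_metadata(metadata, out / "sample_metadata.csv")

    try:
        gating_report = gate_cohort(layout, wells, config.gating)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"gating stage failed: {exc}") from exc
    gating_report.to_csv(out / "gating.csv", index=False)

    try:
        screening = layout[
            (layout["role"] != "test")
            | (
                pd.to_numeric(layout["reciprocal_dilution"], errors="coerce")
                == config.screening_dilution
            )
        ]
        scores = score_screening(
            gating_report[gating_report["well"].isin(screening["well"])]
        )
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"scoring stage failed: {exc}") from exc

    assignments = pool_groups(metadata)
    aframe = assignments_to_frame(assignments)
    scored = scores.merge(aframe, on="sample_id", validate="one_to_one")
    control_scores = scored.loc[
        scored["final_group"] == "healthy_control_pooled", "screening_im"
    ]
    rule = decision_limit(control_scores.to_list(), k_sigma=config.k_sigma)
    logger.info(
        "decision limit %.2f%% (control mean %.2f%%, SD %.2f%%, n=%d)",
        rule.limit,
        rule.control_mean,
        rule.control_sd,
        rule.n_controls,
    )

    meta_by_id = {row.sample_id: row for row in metadata.itertuples(index=False)}
    results: list[SampleResult] = []
    for i, row in enumerate(scored.itertuples(index=False)):
        score = float(row.screening_im)
        status = DETECTED if score > rule.limit else NOT_DETECTED
        titer = None
        if status == DETECTED and config.titrate and config.mode == "simulate":
            sample = _sample_from_row(meta_by_id[row.sample_id])
            titer = titrate_sample(
                sample, score, rule, config, _TITRATION_SEED_BASE + i * 100
            )
        elif status == DETECTED:
            titer = config.screening_dilution  # files mode: no titration wells
        results.append(
            SampleResult(
                sample_id=row.sample_id,
                screening_im=score,
                status=status,
                endpoint_titer=titer,
                category=meta_by_id[row.sample_id].category,
                quality_flags=tuple(row.flags.split(";")) if row.flags else (),
            )
        )

    results_frame = results_to_frame(results, rule)
    results_frame.to_csv(out / "results.csv", index=False)

    eval_input = results_frame[["sample_id", "screening_im", "endpoint_titer"]]
    summary_obj: DiagnosticSummary = evaluate_cohort(eval_input, metadata, rule.limit)
    pd.DataFrame(summary_obj.roc_points, columns=["fpr", "tpr"]).to_csv(
        out / "roc_points.csv", index=False
    )
    if config.plot_roc:
        from .evaluate import plot_roc as _plot

        _plot(summary_obj.roc_points, out / "roc.png", auroc=summary_obj.auroc)

    summary = {
        "seed": config.seed,
        "version": __version__,
        "n_samples": int(len(results)),
        "decision_limit": rule.limit,
        "control_mean": rule.control_mean,
        "control_sd": rule.control_sd,
        "n_controls": rule.n_controls,
        "k_sigma": rule.k_sigma,
        "auroc": summary_obj.auroc,
        "sensitivity_at_limit": summary_obj.sensitivity_at_limit,
        "specificity_at_limit": summary_obj.specificity_at_limit,
        "n_pos": summary_obj.n_pos,
        "n_neg": summary_obj.n_neg,
        "spearman_screening_vs_ria": summary_obj.spearman_screening_vs_ria,
        "spearman_titer_vs_ria": summary_obj.spearman_titer_vs_ria,
        "group_counts": {k: int(v) for k, v in sorted(summary_obj.group_counts.items())},
        "n_detected": int(sum(r.status == DETECTED for r in results)),
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary


def export_cohort_fcs(config: RunConfig, out_dir: str | Path) -> pd.DataFrame:
    """Simulate a cohort and write it out as FCS files + layout/metadata CSVs
    (the ``simulate`` CLI subcommand)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    layout, wells, metadata = simulate_cohort(
        config.cohort, config.sim_params, config.seed
    )
    for key, table in wells.items():
        write_fcs(table, out / well_filename(key))
    write_layout(layout, out / "plate_layout.csv")
    write_metadata(metadata, out / "sample_metadata.csv")
    return layout
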