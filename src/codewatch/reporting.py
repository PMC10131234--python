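"""Decile charts, total-count series and the pipeline orchestrator.

The standard display for practice-level variation is the decile chart: for
each month, the 10th-90th percentiles of the rate across practices, median
drawn solid and the other deciles dashed.  For newly introduced codes whose
deciles are mostly zero, the informative view is the monthly total across all
practices instead.

Charts default to SVG (a deterministic text format): with a fixed hash salt
and no embedded creation date, regenerating a chart from the same inputs is
byte-identical.  Rendering is a pure view layer -- it never alters the
numerical outputs, which are written as CSV before any figure is drawn.
"""

from __future__ import annotations

import json
import logging
import shutil
from pathlib import Path

import matplotlib
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__ as _pkg_version  # noqa: E402
from .config import PipelineConfig, config_hash  # noqa: E402
from .counting import aggregate_group_counts, compute_rates, count_events, total_counts  # noqa: E402
from .discovery import selection_table  # noqa: E402
from .measures import (  # noqa: E402
    change_frame,
    classify_recovery,
    decile_table,
    key_month_summary,
    median_series,
    pct_change_yoy,
)
from .synthetic import generate_dataset, generate_toy_terminology  # noqa: E402
from .terminology import build_group, write_terminology  # noqa: E402

__all__ = [
    "render_decile_chart",
    "render_total_counts",
    "run_pipeline",
    "PipelineError",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _finish_axes(ax, months) -> None:
    ax.set_xticks(range(len(months)))
    ax.set_xticklabels([str(m) for m in months], rotation=90, fontsize=6)
    ax.set_ylabel("rate per 1000 patients")
    ax.set_ylim(bottom=0)


def render_decile_chart(
    summaries: pd.DataFrame,
    path=None,
    *,
    hashsalt: str = "codewatch",
):
    """Draw decile charts, one panel per subject.

    ``summaries`` is a tidy decile table (columns subject, month, d10..d90,
    n_practices) as produced by :func:`codewatch.measures.decile_table`.
    The median (d50) is a solid line; other deciles are dashed.  If ``path``
    is given the figure is saved there (byte-deterministic SVG) and the path
    returned; otherwise the matplotlib figure is returned.
    """
    if summaries.empty:
        raise ValueError("no decile summaries to plot")
    subjects = list(dict.fromkeys(summaries["subject"]))
    n = len(subjects)
    ncols = min(3, n)
    nrows = -(-n // ncols)
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(4.0 * ncols, 2.8 * nrows), squeeze=False
    )
    for k, subject in enumerate(subjects):
        ax = axes[k // ncols][k % ncols]
        sub = summaries[summaries["subject"] == subject].sort_values("month")
        months = list(sub["month"])
        x = range(len(months))
        for q in (10, 20, 30, 40, 60, 70, 80, 90):
            ax.plot(x, sub[f"d{q}"], linestyle="--", linewidth=0.7, color="#1f77b4")
        ax.plot(x, sub["d50"], linestyle="-", linewidth=1.6, color="#1f77b4")
        ax.set_title(str(subject), fontsize=8)
        _finish_axes(ax, months)
    for k in range(n, nrows * ncols):
        axes[k // ncols][k % ncols].set_visible(False)
    fig.tight_layout()
    if path is None:
        return fig
    _save_deterministic(fig, path, hashsalt)
    return Path(path)


def render_total_counts(
    counts: pd.DataFrame,
    subject: str,
    out_prefix,
    *,
    hashsalt: str = "codewatch",
) -> tuple[Path, Path]:
    """Monthly totals across all practices for one code/group: CSV + chart.

    Returns (csv_path, image_path).  Raises KeyError for an unknown subject.
    """
    totals = total_counts(counts, subject)
    out_prefix = Path(out_prefix)
    csv_path = out_prefix.with_suffix(".csv")
    frame = totals.rename("total").reset_index()
    frame["month"] = frame["month"].astype(str)
    frame.to_csv(csv_path, index=False)

    fig, ax = plt.subplots(figsize=(5, 3))
    months = list(totals.index)
    ax.plot(range(len(months)), totals.to_numpy(), marker="o", markersize=2)
    ax.set_title(f"Total monthly recording: {subject}", fontsize=9)
    ax.set_xticks(range(len(months)))
    ax.set_xticklabels([str(m) for m in months], rotation=90, fontsize=6)
    ax.set_ylabel("events per month")
    ax.set_ylim(bottom=0)
    fig.tight_layout()
    img_path = out_prefix.with_suffix(".svg")
    _save_deterministic(fig, img_path, hashsalt)
    return csv_path, img_path


def _save_deterministic(fig, path, hashsalt: str) -> None:
    path = Path(path)
    with plt.rc_context({"svg.hashsalt": hashsalt}):
        if path.suffix == ".svg":
            fig.savefig(path, metadata={"Date": None})
        else:
            fig.savefig(path, dpi=150)
    plt.close(fig)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object or str(out[col].dtype).startswith("period"):
            out[col] = out[col].astype(str)
    out.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig | str | Path, out_dir) -> Path:
    """Execute generate -> count -> discover -> measure -> report.

    Outputs land in ``out_dir``: run manifest, generated inputs (practice
    registry, terminology, event table), selection CSV, decile measures CSV,
    year-on-year change CSV, key-month summary CSV, recovery classification
    CSV, and charts.  The run is staged in ``<out_dir>.partial`` and renamed
    into place only on success; on a stage failure the partial tree is
    quarantined as ``<out_dir>.failed-<stage>`` and :class:`PipelineError`
    names the stage.
    """
    from .config import load_config  # local to avoid cycle at import time

    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    out_dir = Path(out_dir)
    if out_dir.exists():
        raise FileExistsError(f"output directory {out_dir} already exists")
    work = out_dir.with_name(out_dir.name + ".partial")
    if work.exists():
        shutil.rmtree(work)
    work.mkdir(parents=True)
    (work / "charts").mkdir()

    stage = "generate"
    try:
        scfg = config.synthetic
        profiles = config.disruption
        if profiles is not None and config.disruption_prefix is not None:
            # terminology generation is deterministic, so resolving the prefix
            # against a pre-generated hierarchy matches the final dataset's
            hierarchy = generate_toy_terminology(scfg)
            profiles = {
                c: config.disruption
                for c in hierarchy.codes_with_prefix(config.disruption_prefix)
            }
        dataset = generate_dataset(scfg, profiles)
        _write_csv(dataset.practices, work / "practices.csv")
        write_terminology(dataset.hierarchy, work / "terminology.csv")
        events = dataset.counts
        _write_csv(events, work / "events.csv")
        logger.info("generate: %d practices, %d codes, %d count rows",
                    len(dataset.practices), len(dataset.hierarchy), len(events))

        stage = "count"
        window = (scfg.study_start, scfg.study_end)
        counts = count_events(events, window)
        logger.info("count: %d cells in window %s..%s", len(counts), *window)

        stage = "discover"
        selection = selection_table(counts, dataset.hierarchy, config.discovery)
        _write_csv(selection, work / "selection.csv")
        selected = list(selection["code"])
        logger.info("discover: %d of %d codes retained at threshold %d",
                    len(selected), counts["code"].nunique(), config.discovery.threshold)

        stage = "measure"
        groups = [build_group(dataset.hierarchy, g) for g in config.groups]
        measured_counts = counts[counts["code"].isin(selected)]
        group_frames = [aggregate_group_counts(counts, g) for g in groups]
        if group_frames:
            measured_counts = pd.concat(
                [measured_counts, *group_frames], ignore_index=True
            )
        subjects = selected + [g.name for g in groups]
        rates = compute_rates(
            measured_counts, dataset.practices, subjects=subjects, window=window
        )
        deciles = decile_table(rates, quantile_rule=config.quantile_rule)
        _write_csv(deciles, work / "measures.csv")
        medians = {s: median_series(rates, s, quantile_rule=config.quantile_rule)
                   for s in subjects}
        changes = {s: pct_change_yoy(medians[s], s) for s in subjects}
        all_changes = [c for cs in changes.values() for c in cs]
        _write_csv(change_frame(all_changes), work / "changes.csv")
        summary = key_month_summary(medians, changes, config.key_months)
        _write_csv(summary, work / "key_months.csv")
        classifications = []
        for s in subjects:
            try:
                r = classify_recovery(
                    changes[s],
                    thresholds=config.recovery_thresholds,
                    disruption_start=config.disruption_start,
                )
                classifications.append(
                    {"subject": s, "drop_pct": r.drop_pct,
                     "terminal_pct": r.terminal_pct, "category": r.category}
                )
            except ValueError:
                classifications.append(
                    {"subject": s, "drop_pct": float("nan"),
                     "terminal_pct": float("nan"), "category": "undefined"}
                )
        _write_csv(
            pd.DataFrame(classifications,
                         columns=["subject", "drop_pct", "terminal_pct", "category"]),
            work / "recovery.csv",
        )
        logger.info("measure: %d subjects measured", len(subjects))

        stage = "report"
        if config.charts and subjects:
            by_volume = (
                measured_counts.groupby("code", observed=True)["count"].sum()
                .sort_values(ascending=False)
            )
            top = [s for s in by_volume.index if s in subjects][: config.max_chart_subjects]
            if top:
                chart_df = deciles[deciles["subject"].isin(top)]
                render_decile_chart(
                    chart_df,
                    work / "charts" / f"deciles.{config.chart_format}",
                    hashsalt=str(scfg.seed),
                )
                render_total_counts(
                    measured_counts, top[0],
                    work / "charts" / "totals_top_subject",
                    hashsalt=str(scfg.seed),
                )
        manifest = {
            "config_hash": config_hash(config),
            "seed": scfg.seed,
            "study_window": [scfg.study_start, scfg.study_end],
            "index_date": scfg.index_date,
            "quantile_rule": config.quantile_rule,
            "threshold": config.discovery.threshold,
            "threshold_year": config.discovery.threshold_year,
            "version": _pkg_version,
        }
        (work / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:
        quarantine = out_dir.with_name(f"{out_dir.name}.failed-{stage}")
        if quarantine.exists():
            shutil.rmtree(quarantine)
        work.rename(quarantine)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    work.rename(out_dir)
    return out_dir
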