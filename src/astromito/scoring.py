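"""Baseline-relative, control-normalized change scores.

For every cell and parameter the raw change score at a post-treatment
timepoint is the natural-log ratio to the cell's own baseline value,

    raw = log(value_t) - log(value_BL),

and the normalized score subtracts the mean raw score of the control group at
the same (parameter, timepoint), so the control group centers at zero by
construction.  These per-cell scores are the substrate of radar-style
condition summaries (mean ± s.e.m. per condition, parameter and timepoint).
The natural log is used throughout; any other base rescales every score by
the same constant and cancels in group contrasts.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_PARAMETERS",
    "build_summary_table",
    "change_score",
    "normalize_to_control",
]

logger = logging.getLogger(__name__)

DEFAULT_PARAMETERS = (
    "redox_ratio",
    "area",
    "length",
    "n_branches",
    "elongation",
    "displacement",
    "speed",
    "event_rate",
)

_SCORE_COLUMNS = ["cell_id", "condition", "timepoint", "parameter",
                  "raw_score", "normalized_score"]


def change_score(value_bl: float, value_t: float) -> float:
    """Natural-log change of a positive measurement relative to baseline."""
    if value_bl <= 0 or value_t <= 0:
        raise ValueError("change score requires positive values")
    return float(np.log(value_t) - np.log(value_bl))


def normalize_to_control(
    scores: pd.DataFrame, control_label: str
) -> pd.DataFrame:
    """Center raw change scores on the control group's mean per stratum.

    ``scores`` needs columns cell_id, condition, timepoint, parameter,
    raw_score.  Returns the same rows with a ``normalized_score`` column;
    after normalization the control group's mean is exactly zero in every
    (parameter, timepoint) stratum.  Raises if a stratum has no control cell.
    """
    required = {"cell_id", "condition", "timepoint", "parameter", "raw_score"}
    missing = required - set(scores.columns)
    if missing:
        raise ValueError(f"scores table lacks columns {sorted(missing)}")
    scores = scores.copy()
    ctrl = scores[scores["condition"] == control_label]
    ctrl_mean = ctrl.groupby(["parameter", "timepoint"])["raw_score"].mean()
    strata = scores[["parameter", "timepoint"]].drop_duplicates()
    for _, row in strata.iterrows():
        key = (row["parameter"], row["timepoint"])
        if key not in ctrl_mean.index:
            raise ValueError(
                f"no control cells for parameter={key[0]!r} timepoint={key[1]!r}"
            )
    idx = pd.MultiIndex.from_frame(scores[["parameter", "timepoint"]])
    scores["normalized_score"] = (
        scores["raw_score"].to_numpy() - ctrl_mean.reindex(idx).to_numpy()
    )
    return scores[_SCORE_COLUMNS]


def build_summary_table(
    cell_values: pd.DataFrame,
    control_label: str,
    parameters: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute per-cell change scores and condition-level aggregates.

    ``cell_values`` is tidy: one row per (cell_id, condition, timepoint,
    parameter) with a positive ``value`` (the cell-level summary of that
    parameter).  Cells lacking a BL row for a parameter are excluded for that
    parameter with a log entry, as are non-positive values.

    Returns ``(change_scores, summary)`` where ``summary`` holds mean, sem
    and n per (condition, parameter, timepoint) — the radar-chart substrate.
    """
    required = {"cell_id", "condition", "timepoint", "parameter", "value"}
    missing = required - set(cell_values.columns)
    if missing:
        raise ValueError(f"cell_values lacks columns {sorted(missing)}")
    if parameters is not None:
        cell_values = cell_values[cell_values["parameter"].isin(parameters)]

    rows = []
    for (cell, cond, param), grp in cell_values.groupby(
        ["cell_id", "condition", "parameter"], sort=True
    ):
        by_tp = grp.set_index("timepoint")["value"]
        if "BL" not in by_tp.index:
            logger.warning("cell %s lacks BL for %s; excluded", cell, param)
            continue
        bl = by_tp["BL"]
        for tp in by_tp.index:
            if tp == "BL":
                continue
            v = by_tp[tp]
            if bl <= 0 or v <= 0 or not np.isfinite(bl) or not np.isfinite(v):
                logger.warning(
                    "cell %s non-positive %s at %s; excluded", cell, param, tp
                )
                continue
            rows.append(
                {
                    "cell_id": cell,
                    "condition": cond,
                    "timepoint": tp,
                    "parameter": param,
                    "raw_score": change_score(bl, v),
                }
            )
    if not rows:
        raise ValueError("no scorable (cell, parameter, timepoint) rows")
    scores = normalize_to_control(pd.DataFrame(rows), control_label)

    g = scores.groupby(["condition", "parameter", "timepoint"])["normalized_score"]
    summary = g.agg(
        mean="mean",
        sem=lambda s: float(np.std(s, ddof=1) / np.sqrt(len(s))) if len(s) > 1 else 0.0,
        n="count",
    ).reset_index()
    return scores, summary


def plot_radar(summary: pd.DataFrame, timepoint: str, ax=None):
    """Radar-style plot of mean normalized scores per condition (optional)."""
    import matplotlib.pyplot as plt

    sub = summary[summary["timepoint"] == timepoint]
    params = sorted(sub["parameter"].unique())
    angles = np.linspace(0, 2 * np.pi, len(params), endpoint=False)
    if ax is None:
        _, ax = plt.subplots(subplot_kw={"projection": "polar"})
    for cond, grp in sub.groupby("condition"):
        vals = grp.set_index("parameter")["mean"].reindex(params).to_numpy()
        ax.plot(np.r_[angles, angles[:1]], np.r_[vals, vals[:1]], label=cond)
    ax.set_xticks(angles)
    ax.set_xticklabels(params)
    ax.legend(loc="upper right", bbox_to_anchor=(1.3, 1.1))
    return ax
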