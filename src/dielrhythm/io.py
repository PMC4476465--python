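"""Readers and writers for the pipeline's plain-text formats.

All tables are TSV/CSV, schedules are YAML, and run summaries are JSON, so
every artifact is diff-able and round-trips through its own reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import ActivityTrace, CohortActivity, Periodogram, RhythmTest
from .schedule import LightSchedule

__all__ = [
    "ValidationError",
    "read_activity_csv",
    "write_activity_csv",
    "read_counts_tsv",
    "write_counts_tsv",
    "read_schedule",
    "write_schedule",
    "write_cohort_profile",
    "read_cohort_profile",
    "write_periodogram",
    "read_periodogram",
    "write_rhythm_test",
]


class ValidationError(ValueError):
    """Malformed input file; the message names the file, row and column."""


# -- activity traces --------------------------------------------------------


def write_activity_csv(path, traces: list[ActivityTrace]) -> None:
    """Write hourly traces as CSV (animal_id, hour_index, distance_cm, condition)."""
    rows = []
    for tr in traces:
        from .behavior import bin_hourly

        hourly = bin_hourly(tr)
        for h, d in enumerate(hourly):
            rows.append((tr.animal_id, h, float(d), tr.condition))
    pd.DataFrame(
        rows, columns=["animal_id", "hour_index", "distance_cm", "condition"]
    ).to_csv(path, index=False)


def read_activity_csv(path) -> list[ActivityTrace]:
    """Read an activity CSV back into per-animal hourly traces.

    Accepts either pre-binned rows (``hour_index``) or raw event rows
    (``time_s``); event rows are kept as events for later binning.
    """
    df = pd.read_csv(path)
    need = {"animal_id", "distance_cm"}
    if not need <= set(df.columns):
        raise ValidationError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    if (df["distance_cm"] < 0).any():
        row = int(df.index[df["distance_cm"] < 0][0]) + 2  # header is line 1
        raise ValidationError(f"{path}: negative distance at line {row}")
    traces: list[ActivityTrace] = []
    has_hours = "hour_index" in df.columns
    has_events = "time_s" in df.columns
    if not (has_hours or has_events):
        raise ValidationError(f"{path}: need an hour_index or time_s column")
    for animal, grp in df.groupby("animal_id", sort=False):
        condition = str(grp["condition"].iloc[0]) if "condition" in grp else "LD"
        if has_hours:
            grp = grp.sort_values("hour_index")
            hours = grp["hour_index"].to_numpy()
            duration = int(hours.max()) + 1
            hourly = np.zeros(duration)
            hourly[hours.astype(int)] = grp["distance_cm"].to_numpy()
            traces.append(
                ActivityTrace(
                    animal_id=str(animal),
                    duration_h=duration,
                    hourly_cm=hourly,
                    condition=condition,
                )
            )
        else:
            events = list(zip(grp["time_s"].astype(float), grp["distance_cm"].astype(float)))
            duration = int(np.ceil(grp["time_s"].max() / 3600.0))
            traces.append(
                ActivityTrace(
                    animal_id=str(animal),
                    duration_h=max(duration, 1),
                    events=events,
                    condition=condition,
                )
            )
    return traces


# -- count matrices ---------------------------------------------------------


def write_counts_tsv(path, counts: pd.DataFrame) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path) -> pd.DataFrame:
    """Read a gene x sample counts TSV, validating integrality cell by cell."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValidationError(f"{path}: empty counts table")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            gene = df.index[bad.argmax()]
            raise ValidationError(
                f"{path}: non-integer count at gene {gene!r}, column {col!r}"
            )
        if (vals < 0).any():
            gene = df.index[(vals < 0).argmax()]
            raise ValidationError(
                f"{path}: negative count at gene {gene!r}, column {col!r}"
            )
    return df.astype(np.int64)


# -- schedules --------------------------------------------------------------


def write_schedule(path, schedule: LightSchedule) -> None:
    doc = {
        "zt0_offset_h": schedule.zt0_offset_h,
        "intervals": [
            {"start_h": a, "end_h": b, "state": s} for a, b, s in schedule.intervals
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schedule(path) -> LightSchedule:
    """Read a light schedule from YAML.

    Two forms are accepted: an explicit ``intervals`` list, or the shorthand
    ``{cycle: "12:12", duration_h: 72}`` for a repeating LD cycle.
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: schedule must be a mapping")
    offset = float(doc.get("zt0_offset_h", 0.0))
    if "cycle" in doc:
        try:
            light_h, dark_h = (float(x) for x in str(doc["cycle"]).split(":"))
        except ValueError as exc:
            raise ValidationError(f"{path}: bad cycle spec {doc['cycle']!r}") from exc
        if "duration_h" not in doc:
            raise ValidationError(f"{path}: cycle shorthand needs duration_h")
        return LightSchedule.ld_cycle(
            float(doc["duration_h"]), light_h, dark_h, zt0_offset_h=offset
        )
    if "intervals" not in doc:
        raise ValidationError(f"{path}: schedule needs 'intervals' or 'cycle'")
    ivs = []
    for i, item in enumerate(doc["intervals"]):
        try:
            ivs.append((float(item["start_h"]), float(item["end_h"]), str(item["state"])))
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: bad interval #{i + 1}: {item!r}") from exc
    try:
        return LightSchedule(tuple(ivs), offset)
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


# -- analysis outputs -------------------------------------------------------


def write_cohort_profile(path, cohort: CohortActivity) -> None:
    pd.DataFrame(
        {
            "hour": np.arange(cohort.mean_pct.size),
            "mean_pct": cohort.mean_pct,
            "se_pct": cohort.se_pct,
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort_profile(path) -> CohortActivity:
    df = pd.read_csv(path, sep="\t")
    return CohortActivity(
        mean_pct=df["mean_pct"].to_numpy(),
        se_pct=df["se_pct"].to_numpy(),
        n_animals=0,
    )


def write_periodogram(path, pg: Periodogram) -> None:
    pd.DataFrame({"period_h": pg.period_grid_h, "power": pg.power}).to_csv(
        path, sep="\t", index=False
    )


def read_periodogram(path) -> Periodogram:
    df = pd.read_csv(path, sep="\t")
    grid = df["period_h"].to_numpy()
    power = df["power"].to_numpy()
    if np.allclose(power, 0.0):
        return Periodogram(grid, power, float("nan"), degenerate=True)
    return Periodogram(grid, power, float(grid[int(np.argmax(power))]))


def write_rhythm_test(path, rt: RhythmTest, dominant_period_h: float) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "dominant_period_h": dominant_period_h,
                "observed_max_power": rt.observed_max_power,
                "p_value": rt.p_value,
                "n_permutations": rt.n_permutations,
                "alpha": rt.alpha,
                "significant": rt.significant,
            },
            indent=2,
        )
        + "\n"
    )
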