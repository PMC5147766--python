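"""Reading and writing the package's plain-text formats.

Formats
-------
Expression TSV
    Header ``gene_id`` followed by CT labels; one row per transcript.
Series TSV (+ sidecar YAML)
    First column ``label``, remaining columns values; the sidecar carries
    ``t0_ct_hr``, ``dt_hr``, ``t0_exp_hr`` and the lighting schedule.
Track CSV
    Columns ``larva_id, time_s, distance_cm`` or ``larva_id, time_s,
    velocity_cm_s``; header required.
Schedule YAML
    ``epochs: [[start_hr, condition], ...]`` plus ``entrainment_phase_hr``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior import LarvaTrack
from .timeseries import CircadianSeries, LightingSchedule
from .transcriptome import ExpressionMatrix


class SchemaError(ValueError):
    """A file does not match its expected column schema."""


def read_expression_tsv(path: str | Path, scale: str = "raw") -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "gene_id":
        raise SchemaError(f"expression TSV must start with column 'gene_id', got {df.columns[0]!r}")
    df = df.set_index("gene_id")
    return ExpressionMatrix.from_frame(df, scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def schedule_to_dict(schedule: LightingSchedule) -> dict:
    return {
        "epochs": [[float(s), c] for s, c in schedule.epochs],
        "entrainment_phase_hr": float(schedule.entrainment_phase_hr),
    }


def schedule_from_dict(d: dict) -> LightingSchedule:
    unknown = set(d) - {"epochs", "entrainment_phase_hr"}
    if unknown:
        raise SchemaError(f"unknown schedule keys: {sorted(unknown)}")
    return LightingSchedule(
        epochs=tuple((float(s), str(c)) for s, c in d["epochs"]),
        entrainment_phase_hr=float(d.get("entrainment_phase_hr", 0.0)),
    )


def read_schedule_yaml(path: str | Path) -> LightingSchedule:
    with open(path) as fh:
        return schedule_from_dict(yaml.safe_load(fh))


def write_schedule_yaml(schedule: LightingSchedule, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule_to_dict(schedule), fh, sort_keys=False)


def write_series_tsv(
    series_list: list[CircadianSeries], path: str | Path, sidecar: str | Path | None = None
) -> None:
    """Series as rows of a TSV; grid metadata in a sidecar YAML."""
    first = series_list[0]
    rows = {s.label or f"series_{i}": s.values for i, s in enumerate(series_list)}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "label"
    df.to_csv(path, sep="\t", float_format="%.6g", header=False)
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".yaml")
    meta = {
        "t0_ct_hr": float(first.t0_ct_hr),
        "dt_hr": float(first.dt_hr),
        "t0_exp_hr": float(first.t0_exp_hr),
        "schedule": schedule_to_dict(first.schedule),
    }
    with open(sidecar, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def read_series_tsv(
    path: str | Path, sidecar: str | Path | None = None
) -> list[CircadianSeries]:
    sidecar = Path(sidecar) if sidecar else Path(path).with_suffix(".yaml")
    with open(sidecar) as fh:
        meta = yaml.safe_load(fh)
    schedule = schedule_from_dict(meta["schedule"])
    df = pd.read_csv(path, sep="\t", header=None, index_col=0)
    return [
        CircadianSeries(
            t0_ct_hr=meta["t0_ct_hr"], dt_hr=meta["dt_hr"],
            values=row.to_numpy(dtype=float), schedule=schedule,
            label=str(label), t0_exp_hr=meta.get("t0_exp_hr", 0.0),
        )
        for label, row in df.iterrows()
    ]


TRACK_COLUMNS = ({"larva_id", "time_s", "distance_cm"}, {"larva_id", "time_s", "velocity_cm_s"})


def read_tracks_csv(
    path: str | Path, schedule: LightingSchedule, t0_ct_hr: float = 0.0
) -> list[LarvaTrack]:
    """Per-larva tracks from a long-format CSV (velocity or distance rows)."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    if cols not in [set(c) for c in TRACK_COLUMNS]:
        missing = TRACK_COLUMNS[0] - cols
        raise SchemaError(
            f"track CSV columns {sorted(cols)} do not match; missing e.g. {sorted(missing)}"
        )
    has_velocity = "velocity_cm_s" in cols
    tracks = []
    for larva_id, grp in df.groupby("larva_id", sort=True):
        times = grp["time_s"].to_numpy(dtype=float)
        if has_velocity:
            tracks.append(
                LarvaTrack(
                    larva_id=str(larva_id), schedule=schedule,
                    frame_times_s=times,
                    frame_velocity_cm_s=grp["velocity_cm_s"].to_numpy(dtype=float),
                    t0_ct_hr=t0_ct_hr,
                )
            )
        else:
            from .timeseries import bin_distance

            series = bin_distance(
                np.column_stack([times, grp["distance_cm"].to_numpy(dtype=float)]),
                bin_minutes=10.0, t0_ct_hr=t0_ct_hr, schedule=schedule,
                label=str(larva_id),
            )
            tracks.append(
                LarvaTrack(
                    larva_id=str(larva_id), schedule=schedule, activity=series,
                    t0_ct_hr=t0_ct_hr,
                )
            )
    return tracks


def write_tracks_csv(tracks: list[LarvaTrack], path: str | Path) -> None:
    frames = []
    for tr in tracks:
        if tr.frame_velocity_cm_s is not None:
            frames.append(
                pd.DataFrame(
                    {
                        "larva_id": tr.larva_id,
                        "time_s": tr.frame_times_s,
                        "velocity_cm_s": tr.frame_velocity_cm_s,
                    }
                )
            )
        elif tr.activity is not None:
            t = tr.activity.t_exp * 3600.0
            frames.append(
                pd.DataFrame(
                    {"larva_id": tr.larva_id, "time_s": t, "distance_cm": tr.activity.values}
                )
            )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6g")
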