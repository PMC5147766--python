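"""Run configuration and end-to-end workflow execution.

A :class:`RunConfig` is a strict YAML document (unknown keys rejected)
naming a workflow's inputs, outputs, seed and stage parameters.
:func:`run_pipeline` executes one of the four workflows — ``simulate``,
``transcriptome``, ``behavior``, ``reporter`` — in its fixed stage order and
writes a manifest of every output file with a content hash, so identical
config + seed yields identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import behavior, io, reporter, rhythm, synth, transcriptome

KNOWN_KEYS = {
    "seed", "out_dir", "workflow", "schedule",
    "tpr_target", "n_permutations", "target_period_hr",
    "n_rhythmic", "n_null", "snr",
    "n_larvae_per_group", "days", "masking_gain", "bin_minutes",
    "trend_linear_per_day", "trend_fast_sd", "n_glands",
    "input_expression", "input_tracks", "input_traces", "assay",
    "t0_ct_hr", "dd_window_hr",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration with defaults echoed into the log."""

    seed: int = 0
    out_dir: str = "results"
    schedule: dict | None = None
    tpr_target: float = 0.9
    n_permutations: int = 100
    target_period_hr: float = 24.0
    n_rhythmic: int = 100
    n_null: int = 900
    snr: float = 2.0
    n_larvae_per_group: int = 24
    days: int = 2
    masking_gain: float = 1.0
    bin_minutes: float = 10.0
    trend_linear_per_day: float = 0.0
    trend_fast_sd: float = 0.0
    n_glands: int = 3
    input_expression: str | None = None
    input_tracks: str | None = None
    input_traces: str | None = None
    assay: str = "biolum"
    t0_ct_hr: float = 0.0
    dd_window_hr: tuple[float, float] = (24.0, 72.0)
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        d.pop("workflow", None)
        if "dd_window_hr" in d:
            d["dd_window_hr"] = tuple(float(x) for x in d["dd_window_hr"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def get_schedule(self):
        if self.schedule is None:
            from .timeseries import LightingSchedule

            return LightingSchedule.constant("dark")
        return io.schedule_from_dict(self.schedule)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_manifest(out_dir: Path, files: list[Path], config: RunConfig, workflow: str) -> Path:
    manifest = {
        "workflow": workflow,
        "seed": config.seed,
        "outputs": {f.name: _sha256(f) for f in sorted(files)},
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def _workflow_simulate(config: RunConfig, out_dir: Path) -> list[Path]:
    matrix, truth = synth.make_expression_matrix(
        n_rhythmic=config.n_rhythmic, n_null=config.n_null,
        snr=config.snr, seed=config.seed,
    )
    expr_path = out_dir / "expression.tsv"
    io.write_expression_tsv(matrix, expr_path)
    truth_path = out_dir / "truth_labels.tsv"
    pd.DataFrame({"gene_id": matrix.genes, "rhythmic": truth.astype(int)}).to_csv(
        truth_path, sep="\t", index=False
    )
    schedule = config.get_schedule()
    tracks = []
    for profile in (synth.control_activity_profile(), synth.dclk_activity_profile()):
        for i in range(config.n_larvae_per_group):
            tracks.append(
                synth.make_locomotor_track(
                    profile, schedule, days=config.days,
                    masking_gain=config.masking_gain,
                    seed=config.seed * 10_000 + i + (0 if profile.name == "control" else 5000),
                    larva_id=f"{profile.name}_{i:03d}", emit_frames=False,
                )
            )
    tracks_path = out_dir / "tracks.csv"
    io.write_tracks_csv(tracks, tracks_path)
    sched_path = out_dir / "schedule.yaml"
    io.write_schedule_yaml(schedule, sched_path)
    return [expr_path, truth_path, tracks_path, sched_path]


def _workflow_transcriptome(config: RunConfig, out_dir: Path) -> list[Path]:
    if config.input_expression is None:
        raise FileNotFoundError("transcriptome workflow needs input_expression")
    matrix = io.read_expression_tsv(config.input_expression, scale="raw")
    kept, removed = transcriptome.preprocess(matrix)
    result = rhythm.detect_circadian(
        kept, tpr_target=config.tpr_target,
        n_permutations=config.n_permutations, seed=config.seed,
        target_period_hr=config.target_period_hr,
    )
    g_path = out_dir / "g_table.tsv"
    pd.DataFrame({"gene_id": result.table.labels, "g": result.table.g}).to_csv(
        g_path, sep="\t", index=False, float_format="%.6g"
    )
    curve_path = out_dir / "calibration_curve.tsv"
    pd.DataFrame({"L": result.curve.L, "tpr_hat": result.curve.tpr_hat}).to_csv(
        curve_path, sep="\t", index=False, float_format="%.6g"
    )
    det_path = out_dir / "detected.tsv"
    pd.DataFrame({"gene_id": result.detected}).to_csv(det_path, sep="\t", index=False)
    rem_path = out_dir / "removed_low_max.tsv"
    pd.DataFrame({"gene_id": removed}).to_csv(rem_path, sep="\t", index=False)
    return [g_path, curve_path, det_path, rem_path]


def _workflow_behavior(config: RunConfig, out_dir: Path) -> list[Path]:
    if config.input_tracks is None:
        raise FileNotFoundError("behavior workflow needs input_tracks")
    schedule = config.get_schedule()
    tracks = io.read_tracks_csv(config.input_tracks, schedule, t0_ct_hr=config.t0_ct_hr)
    rows = []
    g_by_genotype: dict[str, list[float]] = {}
    for tr in tracks:
        series = tr.activity
        if series is None:
            continue
        try:
            g = rhythm.g_factor(series, config.target_period_hr)
        except (ValueError, rhythm.ZeroVarianceError):
            g = float("nan")
        pg = behavior.chi_square_periodogram(series)
        day_mean, night_mean = behavior.day_night_summary(series)
        rows.append(
            {
                "larva_id": tr.larva_id, "g": g,
                "period_hr": pg.best_period_hr if pg.best_period_hr else float("nan"),
                "day_mean": day_mean, "night_mean": night_mean,
            }
        )
        genotype = tr.larva_id.rsplit("_", 1)[0]
        g_by_genotype.setdefault(genotype, []).append(g)
    metrics_path = out_dir / "per_larva_metrics.tsv"
    pd.DataFrame(rows).to_csv(metrics_path, sep="\t", index=False, float_format="%.6g")
    outputs = [metrics_path]
    names = sorted(g_by_genotype)
    if len(names) == 2:
        ks = rhythm.compare_g_distributions(g_by_genotype[names[0]], g_by_genotype[names[1]])
        ks_path = out_dir / "group_comparison.tsv"
        pd.DataFrame(
            [{
                "group_a": names[0], "group_b": names[1],
                "ks_D": ks.statistic, "ks_p": ks.pvalue,
                "median_a": ks.median_a, "median_b": ks.median_b,
            }]
        ).to_csv(ks_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(ks_path)
    return outputs


def _workflow_reporter(config: RunConfig, out_dir: Path) -> list[Path]:
    if config.input_traces is None:
        raise FileNotFoundError("reporter workflow needs input_traces")
    series_list = io.read_series_tsv(config.input_traces)
    if config.assay == "biolum":
        conditioned = [reporter.condition_bioluminescence(s) for s in series_list]
    elif config.assay == "melatonin":
        conditioned = reporter.normalize_melatonin(series_list)
    else:
        raise ValueError(f"unknown assay {config.assay!r}")
    cond_path = out_dir / "conditioned.tsv"
    io.write_series_tsv(conditioned, cond_path)
    traces = [
        reporter.ReporterTrace(
            trace_id=s.label, series=s, genotype=s.label.rsplit("_", 1)[0]
        )
        for s in conditioned
    ]
    report = reporter.score_reporter_rhythms(traces, config.dd_window_hr)
    g_path = out_dir / "g_table.tsv"
    pd.DataFrame({"trace_id": report.table.labels, "g": report.table.g}).to_csv(
        g_path, sep="\t", index=False, float_format="%.6g"
    )
    outputs = [cond_path, cond_path.with_suffix(".yaml"), g_path]
    if report.ks is not None:
        ks_path = out_dir / "ks_report.tsv"
        pd.DataFrame(
            [{
                "group_a": report.groups[0], "group_b": report.groups[1],
                "ks_D": report.ks.statistic, "ks_p": report.ks.pvalue,
                "median_a": report.ks.median_a, "median_b": report.ks.median_b,
            }]
        ).to_csv(ks_path, sep="\t", index=False, float_format="%.6g")
        outputs.append(ks_path)
    return outputs


WORKFLOWS = {
    "simulate": _workflow_simulate,
    "transcriptome": _workflow_transcriptome,
    "behavior": _workflow_behavior,
    "reporter": _workflow_reporter,
}


def run_pipeline(config: RunConfig, workflow: str) -> Path:
    """Execute a named workflow; returns the path of the manifest written."""
    if workflow not in WORKFLOWS:
        raise ValueError(f"unknown workflow {workflow!r}; choose from {sorted(WORKFLOWS)}")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = WORKFLOWS[workflow](config, out_dir)
    return _write_manifest(out_dir, files, config, workflow)
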