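#!/usr/bin/env python
"""Reporter-assay analysis: whole-larva bioluminescence and gland melatonin.

Bioluminescence: each trace is conditioned (3-hr smoothing, 2-day running
mean division, per-trace mean normalization), restricted to the two DD
cycles, scored with the G-factor and compared between genotypes. The two
synthetic groups share identical rhythm parameters, so a non-significant
Kolmogorov-Smirnov result is the expected outcome (the peripheral-clock
null result).

Melatonin: each gland's release series is normalized by its maximal
night-time level, the two DD cycles are scored, and genotypes are compared.
Here the clock-blocked group is generated flat with an elevated
subjective-day baseline, so its G-factors should sit well below control.

Writes conditioned traces, G-tables and KS reports under results/reporter/.
"""

from pathlib import Path

import pandas as pd

from circadia import condition_bioluminescence, normalize_melatonin, score_reporter_rhythms
from circadia import io as cio
from circadia.reporter import ReporterTrace

ROOT = Path(__file__).resolve().parent.parent / "results"
IN, OUT = ROOT / "synthetic", ROOT / "reporter"
OUT.mkdir(parents=True, exist_ok=True)


def report(name, traces, window):
    rep = score_reporter_rhythms(traces, dd_window_hr=window)
    pd.DataFrame({"trace_id": rep.table.labels, "g": rep.table.g}).to_csv(
        OUT / f"g_table_{name}.tsv", sep="\t", index=False, float_format="%.6g")
    ks = rep.ks
    verdict = "significant" if ks.pvalue < 0.05 else "not significant"
    print(f"{name}: KS D = {ks.statistic:.3f}, p = {ks.pvalue:.3g} ({verdict}); "
          f"medians {rep.groups[0]} = {ks.median_a:.3f}, {rep.groups[1]} = {ks.median_b:.3f}")
    pd.DataFrame([{
        "group_a": rep.groups[0], "group_b": rep.groups[1],
        "ks_D": ks.statistic, "ks_p": ks.pvalue,
        "median_a": ks.median_a, "median_b": ks.median_b,
    }]).to_csv(OUT / f"ks_{name}.tsv", sep="\t", index=False, float_format="%.6g")


# --- bioluminescence -------------------------------------------------------
raw = cio.read_series_tsv(IN / "biolum_traces.tsv")
conditioned = [condition_bioluminescence(s) for s in raw]
cio.write_series_tsv(conditioned, OUT / "biolum_conditioned.tsv")
traces = [
    ReporterTrace(trace_id=s.label, series=s, genotype=s.label.rsplit("_", 1)[0])
    for s in conditioned
]
report("biolum", traces, window=(24.0, 72.0))

# --- melatonin -------------------------------------------------------------
traces = []
for genotype in ("control", "dclk"):
    glands = cio.read_series_tsv(IN / f"melatonin_{genotype}.tsv")
    for s in normalize_melatonin(glands):
        traces.append(ReporterTrace(trace_id=s.label, series=s, genotype=genotype))
cio.write_series_tsv([t.series for t in traces], OUT / "melatonin_normalized.tsv")
report("melatonin", traces, window=(24.0, 72.0))
print(f"outputs in {OUT}")
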