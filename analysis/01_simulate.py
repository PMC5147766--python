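#!/usr/bin/env python
"""Generate the synthetic datasets every downstream analysis consumes.

Writes, under results/synthetic/:
  expression_control.tsv / expression_dclk.tsv + truth labels
      1,000-gene matrices on the 12-point, 4-hr, two-cycle DD design. The
      control matrix plants 290 rhythmic genes; the clock-blocked (dclk)
      matrix shares the gene universe and plants 29, of which 18 are also
      rhythmic in the control (maintained) and 11 are not (acquired).
  tracks_dd.csv + schedule_dd.yaml
      24 larvae per genotype, three DD cycles, 10-min activity bins
      (control amplitude 13.4 cm/10 min vs dclk 4.5).
  biolum_traces.tsv
      23 dclk + 55 control whole-larva reporter traces with identical
      rhythm parameters (the pineal mutation leaves peripheral clocks
      untouched), plus drift and jitter.
  melatonin_*.tsv
      20 glands per genotype under one dark-light cycle then two DD cycles.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from circadia import io as cio
from circadia import make_expression_matrix
from circadia.synth import (
    GenotypeProfile,
    RhythmSpec,
    control_activity_profile,
    control_melatonin_profile,
    dclk_activity_profile,
    dclk_melatonin_profile,
    make_bioluminescence_trace,
    make_locomotor_track,
    make_melatonin_profiles,
)
from circadia.timeseries import LightingSchedule

SEED = 424242
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
OUT.mkdir(parents=True, exist_ok=True)

N_GENES = 1000
N_CONTROL_RHYTHMIC = 290
N_DCLK_RHYTHMIC = 29
N_MAINTAINED = 18

rng = np.random.default_rng(SEED)

# --- expression matrices sharing one gene universe -------------------------
genes = [f"gene_{i:04d}" for i in range(N_GENES)]

control, control_truth = make_expression_matrix(
    N_CONTROL_RHYTHMIC, N_GENES - N_CONTROL_RHYTHMIC, snr=2.0, seed=SEED
)
control.genes = genes  # rhythmic rows occupy gene_0000..gene_0289

# dclk: rhythmic at 18 maintained ids (gene_0000..0017) + 11 acquired ids
dclk_raw, _ = make_expression_matrix(
    N_DCLK_RHYTHMIC, N_GENES - N_DCLK_RHYTHMIC, snr=2.0, seed=SEED + 1
)
order = np.empty(N_GENES, dtype=int)
rhythmic_ids = list(range(N_MAINTAINED)) + list(
    range(N_CONTROL_RHYTHMIC, N_CONTROL_RHYTHMIC + (N_DCLK_RHYTHMIC - N_MAINTAINED))
)
null_ids = [i for i in range(N_GENES) if i not in set(rhythmic_ids)]
order[rhythmic_ids] = np.arange(N_DCLK_RHYTHMIC)
order[null_ids] = np.arange(N_DCLK_RHYTHMIC, N_GENES)
dclk = type(dclk_raw)(
    genes=genes, libraries=dclk_raw.libraries, values=dclk_raw.values[order],
    scale=dclk_raw.scale, t0_ct_hr=dclk_raw.t0_ct_hr, dt_hr=dclk_raw.dt_hr,
)
dclk_truth = np.zeros(N_GENES, dtype=bool)
dclk_truth[rhythmic_ids] = True

for name, matrix, truth in (
    ("control", control, control_truth),
    ("dclk", dclk, dclk_truth),
):
    cio.write_expression_tsv(matrix, OUT / f"expression_{name}.tsv")
    pd.DataFrame({"gene_id": matrix.genes, "rhythmic": truth.astype(int)}).to_csv(
        OUT / f"truth_{name}.tsv", sep="\t", index=False
    )
print(f"expression: {N_GENES} genes x 12 libraries per genotype "
      f"({N_CONTROL_RHYTHMIC} vs {N_DCLK_RHYTHMIC} planted rhythmic, "
      f"{N_MAINTAINED} shared)")

# --- locomotor tracks under DD ---------------------------------------------
dd = LightingSchedule.constant("dark")
tracks = []
for profile in (control_activity_profile(), dclk_activity_profile()):
    for i in range(24):
        tracks.append(
            make_locomotor_track(
                profile, dd, days=3,
                seed=SEED + 100 + i + (0 if profile.name == "control" else 50),
                larva_id=f"{profile.name}_{i:03d}", emit_frames=False,
            )
        )
cio.write_tracks_csv(tracks, OUT / "tracks_dd.csv")
cio.write_schedule_yaml(dd, OUT / "schedule_dd.yaml")
print(f"locomotor: {len(tracks)} larvae x 3 DD cycles at 10-min bins")

# --- whole-larva bioluminescence (identical rhythm parameters) -------------
reporter_profile = GenotypeProfile("shared", RhythmSpec(amplitude=50.0, baseline=300.0))
biolum = []
for genotype, n, off in (("dclk", 23, 0), ("control", 55, 200)):
    for i in range(n):
        s, _ = make_bioluminescence_trace(
            reporter_profile, days=3, trend_linear_per_day=30.0, trend_fast_sd=20.0,
            seed=SEED + 300 + off + i, label=f"{genotype}_{i:03d}",
        )
        biolum.append(s)
cio.write_series_tsv(biolum, OUT / "biolum_traces.tsv")
print(f"bioluminescence: {len(biolum)} traces (23 dclk + 55 control), 3 days hourly")

# --- melatonin release from cultured glands --------------------------------
for profile_fn, off in ((control_melatonin_profile, 0), (dclk_melatonin_profile, 20)):
    profile = profile_fn()
    glands = make_melatonin_profiles(profile, n_glands=20, seed=SEED + 400 + off)
    cio.write_series_tsv(glands, OUT / f"melatonin_{profile.name}.tsv")
print("melatonin: 20 glands per genotype, one DL cycle then two DD cycles")
print(f"\nall inputs written to {OUT}")
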