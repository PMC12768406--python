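"""Generate the synthetic study datasets every later analysis step reads.

Writes to results/data/: nightly two-choice cluster counts (nights.csv,
combined playback-vs-silence conditions plus a null condition), gradient-
arena egg clusters (eggs.csv), moth tracks (tracks.csv), and a simulated
deafening response table (deafening.json).
"""

import json
import sys
from pathlib import Path

from ovisound import (
    GradientSimConfig,
    TrajectorySimConfig,
    TwoChoiceSimConfig,
    simulate_deafening,
    simulate_gradient,
    simulate_tracks,
    simulate_two_choice,
)
from ovisound.io import write_eggs, write_nights, write_tracks

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

nights = simulate_two_choice(TwoChoiceSimConfig(seed=SEED))
write_nights(nights, OUT / "nights.csv")
print(
    f"nights.csv: {len(nights)} arena-nights, "
    f"{nights['clusters_treatment'].mean():.2f} vs {nights['clusters_control'].mean():.2f} "
    "clusters/night (playback vs control)"
)

null_nights = simulate_two_choice(
    TwoChoiceSimConfig(beta1=0.0, seed=SEED + 1, experiment_id="null_condition")
)
write_nights(null_nights, OUT / "nights_null.csv")
print(f"nights_null.csv: {len(null_nights)} arena-nights with no treatment effect")

eggs = simulate_gradient(GradientSimConfig(seed=SEED))
write_eggs(eggs, OUT / "eggs.csv")
print(
    f"eggs.csv: {len(eggs)} clusters, {eggs['n_eggs'].sum()} eggs, "
    f"{eggs['n_eggs'].mean():.0f}±{eggs['n_eggs'].std():.0f} eggs/cluster (mean±SD)"
)

tracks = simulate_tracks(TrajectorySimConfig(seed=SEED))
write_tracks(tracks, OUT / "tracks.csv")
print(f"tracks.csv: {len(tracks)} moths, {len(tracks[0].t)} samples each at 12 s")

table = simulate_deafening(n_control=25, n_deaf=20, p_control=0.2, p_deaf=0.0, seed=SEED)
(OUT / "deafening.json").write_text(json.dumps({"table": table.tolist()}))
print(f"deafening.json: responders {table[0, 0]}/25 control vs {table[1, 0]}/20 deafened")
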