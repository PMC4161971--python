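"""Generate a synthetic Track A session and write its data tables.

A session is 40 configuration moves (both arm extents re-drawn during each
reward pause), an alternation trajectory between the two food wells, and
Poisson spike trains from 20 elastically anchored place cells.
"""

import tempfile
from pathlib import Path

import numpy as np

from morphtrack.pipeline import simulate_session_a, write_session

bundle, cells = simulate_session_a(n_cells=20, anchoring="linear_fraction",
                                   n_moves=40, seed=42)

traj = bundle.trajectory
print(f"schedule: {bundle.schedule.n_moves} moves over "
      f"{bundle.schedule.t_end / 60:.1f} min; every vertical section visited "
      f">= 3 times: {bundle.schedule.coverage_ok}")
print(f"trajectory: {traj.n} samples at 25 Hz")

counts = [tr.n for tr in bundle.spikes]
print(f"spikes per cell: median {int(np.median(counts))} "
      f"(range {min(counts)}-{max(counts)})")

out = Path(tempfile.mkdtemp()) / "session"
paths = write_session(bundle, out)
print("\nwritten tables:")
for name, p in paths.items():
    print(f"  {name:9s} {p}")
# positions.tsv holds (t, x, y, x_L, y_L, config_id); spikes.tsv the
# per-cell spike times; schedule.tsv the pose of the track in each epoch.
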