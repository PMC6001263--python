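"""Threshold and normalize a structural connectome, with file round-trips.

Streamline-count matrices carry false positives at low weights; an absolute
threshold (here 5 streamlines) removes them while keeping the network
connected, and dividing by a cohort-wide constant (75,000 = 7.5 M streamlines
per subject / 100) maps all weights into [0, 1] for the dynamic model.
"""

import tempfile
from pathlib import Path

import numpy as np

from brainmass import (
    CohortSpec,
    generate_sc,
    is_connected,
    normalize_sc,
    read_matrix,
    threshold_sc,
    write_matrix,
    write_sidecar,
)

# fabricate a raw streamline-count matrix: scale a synthetic connectome so
# the weakest ~5% of links fall below the threshold of 5
sc, table = generate_sc(CohortSpec(seed=42))
positive = sc.weights[sc.weights > 0]
scale = 5.0 / np.quantile(positive, 0.05)
raw = type(sc)(np.round(sc.weights * scale), sc.lengths, sc.region_ids)

thresholded = threshold_sc(raw, 5.0)
removed = int(((raw.weights > 0) & (thresholded.weights == 0)).sum() / 2)
normalized = normalize_sc(thresholded, 75_000.0)

print(f"raw edges: {int((raw.weights > 0).sum() / 2)}")
print(f"edges removed by threshold 5: {removed}")
print(f"still connected: {is_connected(normalized)}")
print(f"weight range after normalization: "
      f"[{normalized.weights[normalized.weights > 0].min():.2e}, "
      f"{normalized.weights.max():.4f}]")

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "sc_norm.txt"
    write_matrix(normalized.weights, path)
    write_sidecar({"regions": list(normalized.region_ids)}, path.with_suffix(".json"))
    back = read_matrix(path)
    print(f"file round-trip max error: {np.abs(back - normalized.weights).max():.1e}")
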