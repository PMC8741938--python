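"""Render the Gaussian density heatmap for one simulated slide.

Uses the ground-truth cell centres of the first simulated slide as a
detection table, downscales them to thumbnail resolution, convolves with
an isotropic Gaussian and writes the intensity map (TIFF) plus an
RGB overlay (PNG) under results/heatmap/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ringmorph import cli
from ringmorph.heatmap import HeatmapSpec

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    truth = pd.read_csv(ROOT / "cohort" / "truth.csv")
    first = truth[truth["scene_id"] == truth["scene_id"].iloc[0]]
    centers = first[["row", "col"]].to_numpy(float)
    spec = HeatmapSpec(thumbnail_shape=(63, 63), scale_factor=16.0, sigma=2.0)
    intensity = cli.run_heatmap(centers, spec, ROOT / "heatmap")
    peak = np.unravel_index(intensity.argmax(), intensity.shape)
    print(f"{len(centers)} cell centres -> 63x63 map; peak {intensity.max():.2f} at {peak}")
    print(f"intensity TIFF + overlay PNG under {ROOT / 'heatmap'}")
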