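"""Aggregate per-cell features into per-slide summaries.

Each slide gets the mean of SC/SN/EP/NCR plus its SD (the atypia of that
property) and the >=min_cells inclusion flag; also writes histogram data
for the cell-area distribution of the first slide.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ringmorph import cli, slide_stats

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    features = pd.read_csv(ROOT / "features.csv")
    summaries = cli.run_aggregate(features, ROOT / "summaries.csv", min_cells=100)
    print(summaries[["slide_id", "n_cells", "sc_mean", "sc_sd", "ep_mean", "ep_sd",
                     "included"]].round(4).to_string(index=False))

    first = features[features["slide_id"] == features["slide_id"].iloc[0]]
    edges, counts = slide_stats.histogram_data(first, "sc", n_bins=20)
    pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}).to_csv(
        ROOT / "sc_histogram.csv", index=False
    )
    assert counts.sum() == len(first)
    print(f"cell-area histogram ({counts.sum()} cells) -> results/sc_histogram.csv")
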