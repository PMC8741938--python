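"""Extract per-cell morphometry from the simulated cohort masks.

Reads each slide's cell/nucleus mask pair, measures SC (cell area, px),
SN (nucleus area, px), EP (min-area-rect aspect ratio) and NCR (SN/SC),
and writes one row per cell to results/features.csv.
"""

from pathlib import Path

from ringmorph import cli

ROOT = Path(__file__).resolve().parents[1] / "results"

if __name__ == "__main__":
    features = cli.run_extract(ROOT / "cohort", ROOT / "features.csv")
    print(f"{len(features)} cells from {features['slide_id'].nunique()} slides")
    print(features[["sc", "sn", "ep", "ncr"]].describe().round(3).to_string())
    assert features["ncr"].between(0, 1).all(), "NCR must lie in (0,1)"
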